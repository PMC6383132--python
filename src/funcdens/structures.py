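"""Structural model I/O, residue centers of mass, and inter-residue distances.

A :class:`StructureModel` is a flat list of residue sites (chain, 1-based
sequence position, amino acid, heavy-atom center of mass).  PDB and mmCIF
files are parsed with gemmi; a plain-text ``xyz_table`` format (one residue
per row, tab-delimited) is supported so that fixtures and synthetic
structures round-trip without any binary format.

Distances are Euclidean distances between residue centers of mass.  For
homomultimers each sequence position occurs once per chain; the
:func:`distance_map` ``collapse`` convention records how the chain copies
were reduced to a single per-position distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueSite",
    "StructureModel",
    "DistanceMap",
    "StructureFormatError",
    "StructureError",
    "load_structure",
    "write_xyz_table",
    "write_pdb",
    "distance_map",
    "map_variants",
    "MappingResult",
]


class StructureFormatError(ValueError):
    """The file could not be parsed in the requested format."""


class StructureError(ValueError):
    """The parsed structure violates a structural precondition."""


@dataclass(frozen=True)
class ResidueSite:
    """One residue in one chain, reduced to its heavy-atom center of mass.

    ``center_of_mass`` is the unweighted mean of the residue's heavy-atom
    coordinates in Å; hydrogens are ignored.
    """

    chain_id: str
    seq_position: int
    amino_acid: str
    center_of_mass: tuple[float, float, float]
    n_atoms: int = 1

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise StructureError(f"residue {self.chain_id}/{self.seq_position}: n_atoms < 1")
        if not all(math.isfinite(c) for c in self.center_of_mass):
            raise StructureError(
                f"residue {self.chain_id}/{self.seq_position}: non-finite coordinates"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center_of_mass, dtype=float)


@dataclass
class StructureModel:
    """A named set of residue sites, possibly spanning several chains."""

    name: str
    sites: list[ResidueSite]

    def __post_init__(self) -> None:
        if not self.sites:
            raise StructureError(f"structure {self.name!r} has no residue sites")
        seen: set[tuple[str, int]] = set()
        for s in self.sites:
            key = (s.chain_id, s.seq_position)
            if key in seen:
                raise StructureError(f"duplicate site {key} in structure {self.name!r}")
            seen.add(key)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            if s.chain_id not in out:
                out.append(s.chain_id)
        return out

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    @property
    def positions(self) -> np.ndarray:
        """Sorted unique sequence positions present in any chain."""
        return np.unique([s.seq_position for s in self.sites])

    def chain_sites(self, chain_id: str) -> list[ResidueSite]:
        return [s for s in self.sites if s.chain_id == chain_id]

    def amino_acid_at(self, seq_position: int) -> str | None:
        """Amino acid modeled at a position (first chain carrying it)."""
        for s in self.sites:
            if s.seq_position == seq_position:
                return s.amino_acid
        return None


# ---------------------------------------------------------------------------
# parsing

_XYZ_COLUMNS = ("seq_position", "chain", "aa", "x", "y", "z")


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".tsv", ".txt", ".xyz"):
        return "xyz_table"
    raise StructureFormatError(f"cannot infer structure format from {path.name!r}")


def load_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Parse a structural model into per-residue center-of-mass sites.

    Parameters
    ----------
    path : str or Path
        File to read.
    format : {"pdb", "mmcif", "xyz_table"}, optional
        Parsed from the file suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _sniff_format(path)
    if fmt in ("pdb", "mmcif"):
        sites = _load_gemmi(path, fmt)
    elif fmt == "xyz_table":
        sites = _load_xyz_table(path)
    else:
        raise StructureFormatError(f"unknown structure format {fmt!r}")
    if not sites:
        raise StructureError(f"{path.name}: no polymer residues found")
    return StructureModel(name=path.stem, sites=sites)


def _load_gemmi(path: Path, fmt: str) -> list[ResidueSite]:
    import gemmi

    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path.name}: no models")
    model = st[0]
    sites: list[ResidueSite] = []
    for chain in model:
        chain_sites = 0
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            coords = [
                (a.pos.x, a.pos.y, a.pos.z)
                for a in res
                if not a.is_hydrogen()
            ]
            if not coords:
                continue
            com = np.mean(np.asarray(coords, dtype=float), axis=0)
            one = info.one_letter_code.upper()
            sites.append(
                ResidueSite(
                    chain_id=chain.name,
                    seq_position=res.seqid.num,
                    amino_acid=one if one.isalpha() else "X",
                    center_of_mass=tuple(com.tolist()),
                    n_atoms=len(coords),
                )
            )
            chain_sites += 1
        if chain_sites == 0 and len(chain) > 0:
            logger.warning("%s: chain %s has no amino-acid residues", path.name, chain.name)
    return sites


def _load_xyz_table(path: Path) -> list[ResidueSite]:
    sites: list[ResidueSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:6]) != _XYZ_COLUMNS:
            raise StructureFormatError(
                f"{path.name}: xyz_table header must start with {_XYZ_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise StructureFormatError(f"{path.name}:{lineno}: expected 6 columns")
            try:
                pos = int(parts[0])
                xyz = (float(parts[3]), float(parts[4]), float(parts[5]))
            except ValueError as exc:
                raise StructureFormatError(f"{path.name}:{lineno}: {exc}") from exc
            sites.append(
                ResidueSite(
                    chain_id=parts[1],
                    seq_position=pos,
                    amino_acid=parts[2],
                    center_of_mass=xyz,
                )
            )
    return sites


def write_xyz_table(structure: StructureModel, path: str | Path) -> None:
    """Write the plain-text residue-center table.

    Coordinates are written with ``repr`` precision so that a write/read
    round trip reproduces centers of mass bit-for-bit.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_XYZ_COLUMNS) + "\n")
        for s in structure.sites:
            x, y, z = s.center_of_mass
            fh.write(f"{s.seq_position}\t{s.chain_id}\t{s.amino_acid}\t{x!r}\t{y!r}\t{z!r}\n")


_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB with one pseudo-atom (CA) per residue center."""
    path = Path(path)
    with open(path, "w") as fh:
        serial = 1
        for s in structure.sites:
            x, y, z = s.center_of_mass
            res3 = _AA1TO3.get(s.amino_acid.upper(), "UNK")
            fh.write(
                f"ATOM  {serial:5d}  CA  {res3} {s.chain_id[:1]}{s.seq_position:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
            serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMap:
    """Symmetric per-position distance matrix with its collapse convention.

    ``collapse`` records how multi-chain copies of a sequence position were
    reduced: ``min_over_chains`` takes the minimum center-of-mass distance
    over all chain pairs (the nearest spatial copy), ``first_chain`` uses
    only the first chain.  After min-over-chains collapsing the triangle
    inequality is not guaranteed; the diagonal is zero by convention.
    """

    positions: np.ndarray
    matrix: np.ndarray
    collapse: str
    excluded_positions: tuple[int, ...] = ()
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {int(p): i for i, p in enumerate(self.positions)}

    def __contains__(self, seq_position: int) -> bool:
        return int(seq_position) in self._index

    def distance(self, p: int, q: int) -> float:
        return float(self.matrix[self._index[int(p)], self._index[int(q)]])

    def row(self, p: int) -> np.ndarray:
        """Distances from position ``p`` to all positions, in ``positions`` order."""
        return self.matrix[self._index[int(p)]]

    def indices_of(self, seq_positions: Iterable[int]) -> np.ndarray:
        return np.asarray([self._index[int(p)] for p in seq_positions], dtype=int)


def distance_map(structure: StructureModel, collapse: str = "min_over_chains") -> DistanceMap:
    """Euclidean center-of-mass distances between all pairs of positions."""
    if collapse not in ("min_over_chains", "first_chain"):
        raise ValueError(f"unknown collapse convention {collapse!r}")
    chains = structure.chain_ids
    if collapse == "first_chain":
        chains = chains[:1]

    per_chain: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cid in chains:
        sites = structure.chain_sites(cid)
        pos = np.asarray([s.seq_position for s in sites], dtype=int)
        coords = np.asarray([s.center_of_mass for s in sites], dtype=float)
        per_chain[cid] = (pos, coords)

    all_positions = np.unique(np.concatenate([p for p, _ in per_chain.values()]))
    n = len(all_positions)
    index = {int(p): i for i, p in enumerate(all_positions)}
    D = np.full((n, n), np.inf)
    for ca, (pos_a, xyz_a) in per_chain.items():
        ia = np.asarray([index[int(p)] for p in pos_a])
        for cb, (pos_b, xyz_b) in per_chain.items():
            d = cdist(xyz_a, xyz_b)
            block = D[np.ix_(ia, np.asarray([index[int(p)] for p in pos_b]))]
            np.minimum(block, d, out=block)
            D[np.ix_(ia, np.asarray([index[int(p)] for p in pos_b]))] = block
    D = np.minimum(D, D.T)
    np.fill_diagonal(D, 0.0)

    excluded = tuple(
        int(p) for p in structure.positions if int(p) not in index
    )
    if excluded:
        logger.warning("positions with no coordinates excluded from distance map: %s", excluded)
    return DistanceMap(positions=all_positions, matrix=D, collapse=collapse,
                       excluded_positions=excluded)


# ---------------------------------------------------------------------------
# variant → structure mapping


@dataclass
class MappingResult:
    """Outcome of projecting sequence-level variants onto a structure."""

    mapped: list
    unmapped: list
    mismatched: list  # (variant, structure_amino_acid) pairs, subset of mapped


def map_variants(variants: Sequence, structure: StructureModel) -> MappingResult:
    """Split variants by whether their position is resolved in the model.

    Variants whose ``seq_position`` has no residue in any chain go to
    ``unmapped`` (they stay available for sequence-feature-only models).
    A reference amino acid disagreeing with the modeled residue is flagged
    in ``mismatched`` but the variant stays mapped.
    """
    resolved = {int(p) for p in structure.positions}
    mapped: list = []
    unmapped: list = []
    mismatched: list = []
    for v in variants:
        if int(v.seq_position) in resolved:
            mapped.append(v)
            model_aa = structure.amino_acid_at(int(v.seq_position))
            ref = getattr(v, "ref_aa", None)
            if ref is not None and model_aa is not None and ref != model_aa:
                mismatched.append((v, model_aa))
        else:
            unmapped.append(v)
    if mismatched:
        logger.info("%d variants have ref_aa differing from the modeled residue", len(mismatched))
    return MappingResult(mapped=mapped, unmapped=unmapped, mismatched=mismatched)
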