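"""Synthetic structures, effect fields, and variant measurement tables.

The generator emulates the statistical shape of curated ion-channel
electrophysiology datasets so the whole pipeline is testable without any
external download:

* residue centers on an ideal helix, a confined self-avoiding coil with a
  realistic contact shell, or a 4-fold symmetric homotetramer;
* a spatially clustered ("hotspot") ground-truth perturbation field on
  residues — variants inside a hotspot share a strongly perturbed mean
  (e.g. 10 %WT) against a wild-type-like background (100 %WT), which also
  produces the characteristic bimodal 0%/100% response histogram;
* raw measurement reports with publication-specific wild-type values
  (lognormal), replicate reports, configurable cell systems, and an
  optional mixture component of spatially unstructured complete-LOF
  variants;
* predictor columns correlated with the true effect at configurable
  strengths, plus pure-noise decoys.

Ground truth is stored alongside every dataset and is never consumed by
the pipeline under test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import ResidueSite, StructureModel, write_xyz_table
from .variants import (
    REQUIRED_COLUMNS,
    RATIO_PARAMETERS,
    VariantMeasurement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenerativeConfig",
    "GroundTruth",
    "GenerationError",
    "make_structure",
    "plant_effect_field",
    "simulate_variant_table",
    "end_to_end_fixture",
    "SyntheticBundle",
]

_AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GenerativeConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference condition used throughout the test
    suite: a 120-residue compact coil carrying one 12 Å hotspot in which
    peak current collapses to ~10 %WT against a 100 %WT background, 150
    characterized variants with 20 %WT measurement noise, and four
    effect-correlated predictor columns plus two decoys.
    """

    n_residues: int = 120
    geometry: str = "random_coil"          # {"helix", "random_coil", "tetramer"}
    n_hotspots: int = 1
    hotspot_radius: float = 12.0           # Å
    hotspot_effect: float = 10.0           # mean Δfunction inside hotspots (%WT or mV)
    background_effect: float = 100.0       # mean outside
    effect_sd: float = 5.0                 # residue-to-residue spread of the field
    noise_sd: float = 20.0                 # per-report measurement noise (%WT or mV)
    n_variants: int = 150
    replicate_rate: float = 0.3            # extra reports per variant ~ Poisson(rate)
    predictor_correlations: tuple[tuple[str, float], ...] = (
        ("provean", -0.5),
        ("polyphen2", -0.4),
        ("pssm", 0.45),
        ("rate_evol", -0.35),
        ("decoy_a", 0.0),
        ("decoy_b", 0.0),
    )
    bimodal_mixture_weight: float = 0.0    # fraction forced to ~0 %WT regardless of position
    parameter: str = "peak_current"
    gene: str = "SCN5A"  # the emulated dataset: LOF rule and cell preference apply
    cell_systems: tuple[tuple[str, float], ...] = (
        ("HEK293", 0.7),
        ("CHO", 0.2),
        ("oocyte", 0.1),
    )
    wt_mean: float = 5.0                   # gene-level WT measurement scale (arbitrary units)
    wt_sigma: float = 0.4                  # lognormal sigma of publication WT values
    tetramer_ring_radius: float = 18.0     # Å, center-to-center for 4-fold symmetry
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hotspot_radius <= 0:
            raise ValueError("hotspot_radius must be positive")
        if not 0.0 <= self.bimodal_mixture_weight <= 1.0:
            raise ValueError("bimodal_mixture_weight must lie in [0, 1]")
        for name, rho in self.predictor_correlations:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"predictor correlation {name}={rho} outside [-1, 1]")
        if self.geometry not in ("helix", "random_coil", "tetramer"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass
class GroundTruth:
    """Planted truth for one dataset; diagnostic only, never a pipeline input."""

    effects: pd.Series                      # per-residue true Δfunction
    hotspot: pd.Series                      # per-residue membership
    centers: tuple[int, ...]
    variant_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    realized_correlations: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry

_HELIX_RISE = 1.5       # Å per residue
_HELIX_TWIST = 100.0    # degrees per residue
_HELIX_RADIUS = 2.3     # Å
_COIL_STEP = 3.8        # Å, pseudo-bond length
_COIL_MIN_SEP = 3.5     # Å, excluded-volume floor
_RESIDUE_VOLUME = 134.0  # Å³, typical mean residue volume (sets coil confinement)


def _helix_coords(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(_HELIX_TWIST) * i
    return np.column_stack(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
    )


def _coil_coords(n: int, rng: np.random.Generator,
                 max_step_tries: int = 300, max_restarts: int = 50) -> np.ndarray:
    """Self-avoiding walk confined to a protein-density sphere."""
    radius = (3.0 * _RESIDUE_VOLUME * n / (4.0 * np.pi)) ** (1.0 / 3.0)
    for _ in range(max_restarts):
        coords = [np.zeros(3)]
        failed = False
        for _ in range(n - 1):
            placed = False
            for _ in range(max_step_tries):
                v = rng.normal(size=3)
                v *= _COIL_STEP / np.linalg.norm(v)
                cand = coords[-1] + v
                if np.linalg.norm(cand) > radius:
                    continue
                prev = np.asarray(coords[:-1])
                if len(prev) and np.min(np.linalg.norm(prev - cand, axis=1)) < _COIL_MIN_SEP:
                    continue
                coords.append(cand)
                placed = True
                break
            if not placed:
                failed = True
                break
        if not failed:
            arr = np.asarray(coords)
            return arr - arr.mean(axis=0)
    raise GenerationError(
        f"self-avoiding coil of {n} residues unsatisfiable after {max_restarts} restarts"
    )


def make_structure(config: GenerativeConfig, rng: np.random.Generator | None = None) -> StructureModel:
    """Generate residue centers for the configured geometry.

    Helix: ideal α-helical curve (1.5 Å rise, 100°/residue, 2.3 Å radius).
    Random coil: seeded self-avoiding walk with 3.8 Å steps, 3.5 Å minimum
    separation, confined to a sphere of typical protein density.
    Tetramer: a coil monomer replicated by 4-fold rotation about z at the
    configured ring radius (chains A–D share residue numbering).
    """
    if config.n_residues < 10:
        raise ValueError("n_residues must be at least 10")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    aa = rng.choice(_AA20, size=config.n_residues)

    if config.geometry == "helix":
        coords = _helix_coords(config.n_residues)
        chains = {"A": coords}
    elif config.geometry == "random_coil":
        chains = {"A": _coil_coords(config.n_residues, rng)}
    else:  # tetramer
        mono = _coil_coords(config.n_residues, rng)
        mono = mono + np.array([config.tetramer_ring_radius, 0.0, 0.0])
        chains = {}
        for k, cid in enumerate("ABCD"):
            phi = np.pi / 2.0 * k
            rot = np.array(
                [[np.cos(phi), -np.sin(phi), 0.0],
                 [np.sin(phi), np.cos(phi), 0.0],
                 [0.0, 0.0, 1.0]]
            )
            chains[cid] = mono @ rot.T

    sites = [
        ResidueSite(
            chain_id=cid,
            seq_position=i + 1,
            amino_acid=str(aa[i]),
            center_of_mass=tuple(float(c) for c in xyz[i]),
        )
        for cid, xyz in chains.items()
        for i in range(config.n_residues)
    ]
    return StructureModel(name=f"synthetic_{config.geometry}", sites=sites)


# ---------------------------------------------------------------------------
# ground truth


def plant_effect_field(
    structure: StructureModel,
    config: GenerativeConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Plant a spatially clustered true-effect field on the residues.

    Hotspot centers are drawn uniformly among residues; every residue
    within ``hotspot_radius`` of any center (first-chain coordinates)
    draws its effect from Normal(hotspot_effect, effect_sd), all others
    from Normal(background_effect, effect_sd).  Percent-scale fields are
    clipped at 0, mirroring the physical floor of current measurements.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    first = structure.chain_ids[0]
    sites = structure.chain_sites(first)
    positions = np.asarray([s.seq_position for s in sites], dtype=int)
    coords = np.asarray([s.center_of_mass for s in sites], dtype=float)

    member = np.zeros(len(positions), dtype=bool)
    centers: tuple[int, ...] = ()
    if config.n_hotspots > 0:
        centers_idx = rng.choice(len(positions), size=config.n_hotspots, replace=False)
        centers = tuple(int(positions[i]) for i in centers_idx)
        for ci in centers_idx:
            member |= np.linalg.norm(coords - coords[ci], axis=1) <= config.hotspot_radius

    effects = np.where(
        member,
        rng.normal(config.hotspot_effect, config.effect_sd, size=len(positions)),
        rng.normal(config.background_effect, config.effect_sd, size=len(positions)),
    )
    if config.parameter in RATIO_PARAMETERS:
        effects = np.clip(effects, 0.0, None)
    idx = pd.Index(positions, name="seq_position")
    return GroundTruth(
        effects=pd.Series(effects, index=idx, name="true_effect"),
        hotspot=pd.Series(member, index=idx, name="hotspot"),
        centers=centers,
    )


# ---------------------------------------------------------------------------
# variant tables


def _draw_cell_system(rng: np.random.Generator, config: GenerativeConfig) -> str:
    names = [n for n, _ in config.cell_systems]
    probs = np.asarray([p for _, p in config.cell_systems], dtype=float)
    probs = probs / probs.sum()
    return str(rng.choice(names, p=probs))


def simulate_variant_table(
    structure: StructureModel,
    truth: GroundTruth,
    config: GenerativeConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantMeasurement], GroundTruth]:
    """Draw raw measurement reports plus predictor columns.

    Distinct (position, substitution) pairs are sampled with replacement
    over positions; each variant receives 1 + Poisson(replicate_rate)
    reports, each with its own publication wild-type value (lognormal
    around the gene-level mean).  For percent parameters the reported
    mutant value is WT × (effect + noise)/100 clipped at 0; shift
    parameters are additive in mV.  A ``bimodal_mixture_weight`` fraction
    of variants is forced to a near-zero %WT effect regardless of
    position.  Predictor columns are correlated Gaussian transforms of the
    variant-level true effect; realized correlations are recorded on the
    returned ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    positions = truth.effects.index.to_numpy()
    is_percent = config.parameter in RATIO_PARAMETERS

    chosen: list[tuple[int, str, str]] = []
    seen: set[tuple[int, str]] = set()
    guard = 0
    while len(chosen) < config.n_variants:
        guard += 1
        if guard > 100 * config.n_variants + 1000:
            raise GenerationError("cannot draw the requested number of distinct variants")
        pos = int(rng.choice(positions))
        ref = structure.amino_acid_at(pos) or "A"
        alt = str(rng.choice([a for a in _AA20 if a != ref]))
        if (pos, alt) in seen:
            continue
        seen.add((pos, alt))
        chosen.append((pos, ref, alt))

    if not chosen:  # an empty table is a valid (if useless) dataset
        empty_idx = pd.MultiIndex.from_tuples([], names=["gene", "seq_position", "alt_aa"])
        truth = dataclasses.replace(
            truth,
            variant_effects=pd.Series(dtype=float, index=empty_idx),
            realized_correlations={name: 0.0 for name, _ in config.predictor_correlations},
        )
        return [], truth

    n = len(chosen)
    base_effects = np.asarray([truth.effects.loc[p] for p, _, _ in chosen])
    forced = rng.random(n) < config.bimodal_mixture_weight
    variant_effects = base_effects.copy()
    if forced.any():
        variant_effects[forced] = np.abs(rng.normal(0.0, 2.0, size=int(forced.sum())))

    # predictor columns: correlated Gaussian transforms of the true effect
    z = (variant_effects - variant_effects.mean())
    sd = z.std()
    z = z / sd if sd > 0 else np.zeros(n)
    predictors: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    for name, rho in config.predictor_correlations:
        col = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=n)
        predictors[name] = col
        realized[name] = float(np.corrcoef(col, variant_effects)[0, 1]) if sd > 0 else 0.0

    records: list[VariantMeasurement] = []
    for i, (pos, ref, alt) in enumerate(chosen):
        n_reports = 1 + int(rng.poisson(config.replicate_rate))
        for r in range(n_reports):
            wt = float(rng.lognormal(np.log(config.wt_mean), config.wt_sigma)) if is_percent \
                else float(rng.normal(-25.0, 3.0))
            noisy = variant_effects[i] + float(rng.normal(0.0, config.noise_sd))
            if is_percent:
                mutant = wt * max(noisy, 0.0) / 100.0
            else:
                mutant = wt + noisy
            extra = {name: float(col[i]) for name, col in predictors.items()}
            records.append(
                VariantMeasurement(
                    gene=config.gene,
                    seq_position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    parameter=config.parameter,
                    mutant_value=mutant,
                    wt_value=wt,
                    cell_system=_draw_cell_system(rng, config),
                    source_id=f"pub{i:04d}r{r}",
                    extra=extra,
                )
            )

    idx = pd.MultiIndex.from_tuples(
        [(config.gene, p, a) for p, _, a in chosen], names=["gene", "seq_position", "alt_aa"]
    )
    truth = dataclasses.replace(
        truth,
        variant_effects=pd.Series(variant_effects, index=idx, name="true_effect"),
        realized_correlations=realized,
    )
    return records, truth


# ---------------------------------------------------------------------------
# end-to-end bundle


@dataclass(frozen=True)
class SyntheticBundle:
    structure_path: Path
    variants_path: Path
    truth_path: Path
    config: GenerativeConfig


def _records_to_frame(records: list[VariantMeasurement]) -> pd.DataFrame:
    extra_cols: list[str] = []
    for r in records:
        for k in r.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in REQUIRED_COLUMNS}
        for c in extra_cols:
            row[c] = r.extra.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + extra_cols)


def end_to_end_fixture(config: GenerativeConfig, out_dir: str | Path) -> SyntheticBundle:
    """Write a complete bundle: structure, variant table, and truth file.

    All files are plain text and bit-reproducible for a given config
    (floats serialized with shortest-round-trip formatting, no
    timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    structure = make_structure(config, rng)
    truth = plant_effect_field(structure, config, rng)
    records, truth = simulate_variant_table(structure, truth, config, rng)

    structure_path = out_dir / "structure.tsv"
    write_xyz_table(structure, structure_path)

    variants_path = out_dir / "variants.tsv"
    _records_to_frame(records).to_csv(variants_path, sep="\t", index=False)

    truth_path = out_dir / "truth.json"
    payload = {
        "config": {
            k: (list(map(list, v)) if isinstance(v, tuple) and v and isinstance(v[0], tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "hotspot_centers": list(truth.centers),
        "residue_effects": {str(k): float(v) for k, v in truth.effects.items()},
        "hotspot_membership": {str(k): bool(v) for k, v in truth.hotspot.items()},
        "variant_effects": {
            f"{g}:{p}:{a}": float(v) for (g, p, a), v in truth.variant_effects.items()
        },
        "realized_correlations": truth.realized_correlations,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return SyntheticBundle(structure_path, variants_path, truth_path, config)
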