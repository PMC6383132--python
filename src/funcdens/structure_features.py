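"""Residue burial and neighborhood descriptors.

NeighborCount is a smooth, distance-weighted count of residues around a
site; NeighborVector measures how anisotropically those neighbors surround
it (1 = all on one side, as on a surface; 0 = perfectly balanced, as in a
buried core).  Both use a cosine switching function that is 1 inside a
contact bound and decays to 0 at an outer cutoff of 11.4 Å, a burial
cutoff long established for structure scoring.  ``aaneigh`` and
``aaneighvector`` re-express the raw values as per-amino-acid standardized
scores, accounting for each residue type's intrinsic burial propensity
(leucines are expected to be buried; aspartates are not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "neighbor_weight",
    "neighbor_features",
    "propensity_from_features",
    "aa_adjust",
    "neighbor_feature_table",
    "DEFAULT_LOWER",
    "DEFAULT_UPPER",
]

DEFAULT_LOWER = 4.0   # Å: full weight at or below contact distance
DEFAULT_UPPER = 11.4  # Å: zero weight at or beyond the burial cutoff


def neighbor_weight(d, lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER):
    """Smooth switching weight for a neighbor at distance ``d`` (Å).

    1 for ``d <= lower``, 0 for ``d >= upper``, and the half-cosine
    ``0.5 * (cos(pi * (d - lower) / (upper - lower)) + 1)`` between, so the
    weight is continuous and monotone non-increasing.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if not (0 <= lower < upper):
        raise ValueError(f"need 0 <= lower < upper, got ({lower}, {upper})")
    t = np.clip((d - lower) / (upper - lower), 0.0, 1.0)
    w = 0.5 * (np.cos(np.pi * t) + 1.0)
    return w if w.ndim else float(w)


def neighbor_features(
    structure: StructureModel,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
) -> pd.DataFrame:
    """Raw NeighborCount and NeighborVector for every site.

    Returns a DataFrame with one row per (chain, seq_position) and columns
    ``neighbor_count`` and ``neighbor_vector``.  All sites in all chains
    act as potential neighbors, so interfaces in multimers are counted.
    """
    coords = np.asarray([s.center_of_mass for s in structure.sites], dtype=float)
    n = len(coords)
    diff = coords[None, :, :] - coords[:, None, :]          # i -> j displacement
    dist = np.linalg.norm(diff, axis=-1)
    w = neighbor_weight(dist, lower, upper)
    np.fill_diagonal(w, 0.0)

    counts = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        units = np.where(dist[..., None] > 0, diff / np.where(dist[..., None] > 0, dist[..., None], 1.0), 0.0)
    vec = (w[..., None] * units).sum(axis=1)
    norm = np.linalg.norm(vec, axis=1)
    nv = np.divide(norm, counts, out=np.zeros(n), where=counts > 0)

    return pd.DataFrame(
        {
            "chain_id": [s.chain_id for s in structure.sites],
            "seq_position": [s.seq_position for s in structure.sites],
            "amino_acid": [s.amino_acid for s in structure.sites],
            "neighbor_count": counts,
            "neighbor_vector": nv,
        }
    )


def propensity_from_features(features: pd.DataFrame) -> pd.DataFrame:
    """Per-amino-acid mean and spread of the raw burial features.

    Computed from the structure's own sites (structure-local statistics).
    Spread is the population standard deviation; amino acids observed fewer
    than twice, or with zero spread, fall back to the global statistics at
    adjustment time.
    """
    rows = {}
    for aa, grp in features.groupby("amino_acid"):
        rows[aa] = {
            "nc_mean": grp["neighbor_count"].mean(),
            "nc_sd": grp["neighbor_count"].std(ddof=0),
            "nv_mean": grp["neighbor_vector"].mean(),
            "nv_sd": grp["neighbor_vector"].std(ddof=0),
            "n": len(grp),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def aa_adjust(features: pd.DataFrame, propensity: pd.DataFrame) -> pd.DataFrame:
    """Standardize burial features by amino-acid propensity.

    ``aaneigh = (neighbor_count − mean_aa) / sd_aa`` and likewise for
    ``aaneighvector``; a residue type missing from the table (or with a
    degenerate spread) uses the global mean/sd, with a log note.
    """
    out = features.copy()
    g_nc_mean = features["neighbor_count"].mean()
    g_nc_sd = features["neighbor_count"].std(ddof=0) or 1.0
    g_nv_mean = features["neighbor_vector"].mean()
    g_nv_sd = features["neighbor_vector"].std(ddof=0) or 1.0

    aaneigh = np.empty(len(features))
    aaneighvector = np.empty(len(features))
    fell_back: set[str] = set()
    for i, (aa, nc, nv) in enumerate(
        zip(features["amino_acid"], features["neighbor_count"], features["neighbor_vector"])
    ):
        if aa in propensity.index and propensity.loc[aa, "nc_sd"] > 0 and propensity.loc[aa].get("n", 2) >= 2:
            p = propensity.loc[aa]
            aaneigh[i] = (nc - p["nc_mean"]) / p["nc_sd"]
            sd_nv = p["nv_sd"] if p["nv_sd"] > 0 else g_nv_sd
            aaneighvector[i] = (nv - p["nv_mean"]) / sd_nv
        else:
            fell_back.add(aa)
            aaneigh[i] = (nc - g_nc_mean) / g_nc_sd
            aaneighvector[i] = (nv - g_nv_mean) / g_nv_sd
    if fell_back:
        logger.info("amino acids using global propensity fallback: %s", sorted(fell_back))
    out["aaneigh"] = aaneigh
    out["aaneighvector"] = aaneighvector
    return out


def neighbor_feature_table(
    structure: StructureModel,
    propensity: pd.DataFrame | None = None,
    lower: float = DEFAULT_LOWER,
    upper: float = DEFAULT_UPPER,
) -> pd.DataFrame:
    """Per-seq-position burial feature table (chains averaged).

    Computes raw features on every site, applies the amino-acid
    adjustment (structure-local propensities unless a table is supplied),
    and averages chain copies so the table is keyed by ``seq_position``
    alone — for symmetric homomultimers the copies are identical anyway.
    """
    raw = neighbor_features(structure, lower, upper)
    if propensity is None:
        propensity = propensity_from_features(raw)
    adjusted = aa_adjust(raw, propensity)
    cols = ["neighbor_count", "neighbor_vector", "aaneigh", "aaneighvector"]
    table = adjusted.groupby("seq_position")[cols].mean()
    return table


def read_propensity_table(path) -> pd.DataFrame:
    """Read a user-supplied propensity table (TSV, indexed by amino acid)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"nc_mean", "nc_sd", "nv_mean", "nv_sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"propensity table missing columns {sorted(missing)}")
    if "n" not in df.columns:
        df["n"] = 2
    return df
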