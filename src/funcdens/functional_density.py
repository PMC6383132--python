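"""Functional density: distance-weighted smoothing of variant perturbations.

The functional density of residue *j* for functional parameter *x* is a
k-nearest-neighbors-style convex average of the measured perturbations of
all characterized variants *i*, weighted by a logistic function of the
center-of-mass distance d_ij:

    rho_jx = sum_i  Δfunction_xi * w(d_ij)  /  sum_i w(d_ij),
    w(d)   = 1 / (1 + exp(d / scale)),      scale = 2 Å by default.

No distance cutoff is applied — every characterized variant contributes,
with weight decaying smoothly from 0.5 at contact.  A variant at the same
residue as the target contributes at d = 0 **provided the substitution
differs**; the target's own identical mutation is always excluded, so the
in-sample feature never contains the value it is meant to predict.

The weight-only density drops Δfunction (sets it to 1) and reports the
unnormalized weight sum: a measure of how densely characterized the
target's spatial neighborhood is, used to control for literature sampling
bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import DistanceMap
from .variants import NormalizedVariant

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SCALE",
    "DensityResult",
    "density_weight",
    "functional_density",
    "weight_only_density",
    "density_at_positions",
    "build_density_features",
]

DEFAULT_SCALE = 2.0  # Å; gives half-weight at d = 0 and ~0.27 at 2 Å


@dataclass(frozen=True)
class DensityResult:
    """Functional density at one target variant for one parameter.

    When no contributor survives the same-mutation exclusion, ``rho`` is
    NaN and ``missing`` is True — never silently zero.
    """

    gene: str
    seq_position: int
    alt_aa: str | None
    parameter: str
    rho: float
    weight_sum: float
    n_contributors: int

    @property
    def missing(self) -> bool:
        return self.n_contributors == 0


def density_weight(d, scale: float = DEFAULT_SCALE):
    """Logistic distance weight w(d) = 1 / (1 + exp(d / scale)).

    Strictly decreasing, w(0) = 0.5, w → 0 as d → ∞.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    w = 1.0 / (1.0 + np.exp(d / scale))
    return w if w.ndim else float(w)


def _contributor_arrays(
    target_position: int,
    target_alt: str | None,
    contributors: Sequence[NormalizedVariant],
    distances: DistanceMap,
    parameter: str | None,
    scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Weights and Δfunction values of the contributors that count.

    Excluded: the target's own mutation (same position, same alt_aa), any
    contributor for a different parameter, and contributors at positions
    absent from the distance map (logged).
    """
    kept = []
    n_off_structure = 0
    for c in contributors:
        if parameter is not None and c.parameter != parameter:
            continue
        if target_alt is not None and c.seq_position == target_position and c.alt_aa == target_alt:
            continue  # identical mutation: never a contributor to itself
        if c.seq_position not in distances:
            n_off_structure += 1
            continue
        kept.append(c)
    if n_off_structure:
        logger.debug("%d contributors outside the structural model skipped", n_off_structure)
    if not kept:
        return np.empty(0), np.empty(0)
    # canonical order so the summed result is bitwise permutation-invariant
    kept.sort(key=lambda c: (c.seq_position, c.alt_aa, c.delta_function))
    dists = np.asarray([distances.distance(target_position, c.seq_position) for c in kept])
    deltas = np.asarray([c.delta_function for c in kept], dtype=float)
    return density_weight(dists, scale), deltas


def functional_density(
    target: NormalizedVariant,
    contributors: Sequence[NormalizedVariant],
    distances: DistanceMap,
    parameter: str | None = None,
    scale: float = DEFAULT_SCALE,
) -> DensityResult:
    """Functional density rho at ``target`` from the contributor set."""
    parameter = parameter or target.parameter
    if target.seq_position not in distances:
        raise KeyError(
            f"target position {target.seq_position} not present in the distance map"
        )
    w, deltas = _contributor_arrays(
        target.seq_position, target.alt_aa, contributors, distances, parameter, scale
    )
    if len(w) == 0:
        return DensityResult(target.gene, target.seq_position, target.alt_aa,
                             parameter, float("nan"), 0.0, 0)
    # normalized weights: a lone contributor's Δf is returned exactly
    rho = float(np.dot(deltas, w / w.sum()))
    return DensityResult(target.gene, target.seq_position, target.alt_aa,
                         parameter, rho, float(w.sum()), len(w))


def weight_only_density(
    target: NormalizedVariant,
    contributors: Sequence[NormalizedVariant],
    distances: DistanceMap,
    parameter: str | None = None,
    scale: float = DEFAULT_SCALE,
) -> float:
    """Unnormalized weight sum: local coverage of characterized variants.

    Same exclusion rule as :func:`functional_density` with Δfunction = 1;
    reported unnormalized because the normalized form is identically 1.
    Empty contributor set → 0 (a coverage of zero is meaningful).
    """
    parameter = parameter or target.parameter
    w, _ = _contributor_arrays(
        target.seq_position, target.alt_aa, contributors, distances, parameter, scale
    )
    return float(w.sum())


def density_at_positions(
    positions: Sequence[int],
    contributors: Sequence[NormalizedVariant],
    distances: DistanceMap,
    parameter: str,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Residue-level density field: rho and weight sum at bare positions.

    Targets are residues, not variants, so no mutation-identity exclusion
    applies; used for hotspot mapping and diagnostics.  Vectorized over the
    distance matrix.
    """
    contrib = [c for c in contributors if c.parameter == parameter and c.seq_position in distances]
    out = pd.DataFrame(index=pd.Index(positions, name="seq_position"),
                       columns=["rho", "weight_sum", "n_contributors"], dtype=float)
    if not contrib:
        out["rho"] = np.nan
        out[["weight_sum", "n_contributors"]] = 0.0
        return out
    cidx = distances.indices_of([c.seq_position for c in contrib])
    deltas = np.asarray([c.delta_function for c in contrib])
    for p in positions:
        d = distances.row(int(p))[cidx]
        w = density_weight(d, scale)
        s = w.sum()
        out.loc[p, "rho"] = float(np.dot(deltas, w / s))
        out.loc[p, "weight_sum"] = float(s)
        out.loc[p, "n_contributors"] = len(w)
    return out


def build_density_features(
    train: Sequence[NormalizedVariant],
    evaluate: Sequence[NormalizedVariant],
    distances: DistanceMap,
    parameter: str,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Density feature columns for ``evaluate``, built from ``train`` only.

    The contributor pool is always the training set; for every evaluated
    variant the same-mutation exclusion is applied against *that* variant,
    so in-sample mode (evaluate is the training set itself) never leaks a
    variant's own measurement into its feature, and out-of-sample mode
    depends on the training data alone.

    Returns a DataFrame indexed by (gene, seq_position, alt_aa) with
    columns ``rho`` (NaN when no contributor survives or the position is
    off-structure), ``weight_only`` and ``n_contributors``.
    """
    train = [c for c in train if c.parameter == parameter]
    rows = []
    index = []
    n_off = 0
    for v in evaluate:
        index.append((v.gene, v.seq_position, v.alt_aa))
        if v.seq_position not in distances:
            n_off += 1
            rows.append({"rho": np.nan, "weight_only": np.nan, "n_contributors": 0})
            continue
        res = functional_density(v, train, distances, parameter, scale)
        rows.append(
            {
                "rho": res.rho,
                "weight_only": res.weight_sum,
                "n_contributors": res.n_contributors,
            }
        )
    if n_off:
        logger.warning(
            "%d evaluated variants have no structural coordinates; density left missing", n_off
        )
    idx = pd.MultiIndex.from_tuples(index, names=["gene", "seq_position", "alt_aa"])
    return pd.DataFrame(rows, index=idx)
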