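"""Loss-of-function labeling, logistic classifiers, and paired ROC comparison.

A variant is loss-of-function (LOF) when its aggregated peak current falls
strictly below 50% of wild-type; for the KCNQ1/KCNE1 potassium channel a
positive shift of V_1/2 of activation strictly greater than +10 mV also
qualifies (either rule suffices).  Feature subsets are compared by fitting
one logistic model per subset on the same variant rows and contrasting the
ROC AUCs with DeLong's nonparametric test for paired (correlated) AUCs,
with stratified-bootstrap percentile intervals on each AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "LofLabel",
    "MissingParameterError",
    "LOF_PEAK_THRESHOLD",
    "LOF_VSHIFT_THRESHOLD",
    "lof_label",
    "label_variants",
    "LogisticScorer",
    "logistic_fit",
    "auc",
    "auc_bootstrap_ci",
    "delong_variance",
    "delong_test",
    "compare_feature_sets",
    "RocComparison",
    "roc_points",
]

LOF_PEAK_THRESHOLD = 50.0    # %WT, strict "<"
LOF_VSHIFT_THRESHOLD = 10.0  # mV positive shift, strict ">"

#: Which rules apply per gene: peak-current only, or peak OR V1/2-activation.
_GENE_RULES: dict[str, tuple[str, ...]] = {
    "SCN5A": ("peak_current",),
    "KCNQ1": ("peak_current", "v_half_act"),
}


class MissingParameterError(KeyError):
    """A parameter required by the gene's LOF rule is absent."""


@dataclass(frozen=True)
class LofLabel:
    gene: str
    seq_position: int
    alt_aa: str
    is_lof: bool
    basis: str  # {"peak_rule", "vhalf_rule", "both"} — rules applied


def lof_label(
    gene: str,
    seq_position: int,
    alt_aa: str,
    params: Mapping[str, float],
    rules: Sequence[str] | None = None,
) -> LofLabel:
    """Apply the gene's LOF threshold rules to aggregated parameter values.

    ``params`` maps parameter name → aggregated Δfunction.  Thresholds are
    strict: a peak current of exactly 50 %WT or a shift of exactly +10 mV
    is not LOF.  SCN5A requires peak current; KCNQ1 accepts peak current
    and/or the activation-V_1/2 shift, but at least one must be present.
    """
    if rules is None:
        try:
            rules = _GENE_RULES[gene]
        except KeyError:
            raise ValueError(f"no LOF rule defined for gene {gene!r}") from None
    applied = []
    is_lof = False
    if "peak_current" in rules and "peak_current" in params:
        applied.append("peak_rule")
        is_lof = is_lof or params["peak_current"] < LOF_PEAK_THRESHOLD
    if "v_half_act" in rules and "v_half_act" in params:
        applied.append("vhalf_rule")
        is_lof = is_lof or params["v_half_act"] > LOF_VSHIFT_THRESHOLD
    if gene in _GENE_RULES and "peak_current" in _GENE_RULES[gene] and len(_GENE_RULES[gene]) == 1:
        if "peak_rule" not in applied:
            raise MissingParameterError(f"{gene} {seq_position}{alt_aa}: peak_current required")
    if not applied:
        raise MissingParameterError(
            f"{gene} {seq_position}{alt_aa}: none of {rules} present"
        )
    basis = "both" if len(applied) == 2 else applied[0]
    return LofLabel(gene, seq_position, alt_aa, bool(is_lof), basis)


def label_variants(variants) -> tuple[list[LofLabel], list[tuple[tuple, str]]]:
    """Label aggregated variants, collecting exclusions with reasons.

    ``variants`` is an iterable of NormalizedVariant records (one per
    parameter); they are grouped by (gene, seq_position, alt_aa) first.
    """
    grouped: dict[tuple, dict[str, float]] = {}
    for v in variants:
        grouped.setdefault((v.gene, v.seq_position, v.alt_aa), {})[v.parameter] = v.delta_function
    labels: list[LofLabel] = []
    excluded: list[tuple[tuple, str]] = []
    for key, params in sorted(grouped.items()):
        try:
            labels.append(lof_label(key[0], key[1], key[2], params))
        except (MissingParameterError, ValueError) as exc:
            excluded.append((key, str(exc)))
    if excluded:
        logger.info("%d variants excluded from LOF labeling", len(excluded))
    return labels, excluded


# ---------------------------------------------------------------------------
# logistic scorer


@dataclass
class LogisticScorer:
    feature_names: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    stabilized: bool

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Z = np.column_stack([np.ones(len(X)), X[list(self.feature_names)].to_numpy(dtype=float)])
        eta = Z @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def logistic_fit(features: pd.DataFrame, labels) -> LogisticScorer:
    """Maximum-likelihood logistic regression returning a probability scorer.

    Separable or ill-conditioned data fall back to a small L2 (ridge)
    stabilizer, recorded on the scorer and logged.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if len(y) < 20:
        raise ValueError(f"n={len(y)} below the minimum of 20 for a logistic fit")
    import statsmodels.api as sm

    X = features.to_numpy(dtype=float)
    Z = sm.add_constant(X, has_constant="add")
    stabilized = False
    params = None
    with np.errstate(all="ignore"):
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                res = sm.Logit(y, Z).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.params)) \
                    and np.max(np.abs(res.params)) < 1e3:
                params = np.asarray(res.params)
        except Exception:  # perfect separation, singular Hessian, ...
            params = None
    if params is None:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000)
        Xs = features.to_numpy(dtype=float)
        lr.fit(Xs, y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        stabilized = True
        logger.info("logistic fit stabilized with a small ridge penalty")
    return LogisticScorer(tuple(features.columns), params, stabilized)


# ---------------------------------------------------------------------------
# AUC and DeLong


def auc(scores, labels) -> float:
    """ROC area via the rank statistic: U/(n₁·n₀), ties half-credited.

    Identical to the trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(scores)
    u = r[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_bootstrap_ci(scores, labels, B: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Stratified case-resampling percentile interval for the AUC.

    Positives and negatives are resampled separately so every replicate
    keeps both classes at their observed counts.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos = scores[y]
    neg = scores[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    ones = np.ones(len(pos), dtype=bool)
    zeros = np.zeros(len(neg), dtype=bool)
    lab = np.concatenate([ones, zeros])
    for b in range(B):
        s = np.concatenate(
            [pos[rng.integers(0, len(pos), len(pos))], neg[rng.integers(0, len(neg), len(neg))]]
        )
        out[b] = auc(s, lab)
    lower, upper = np.percentile(out, [2.5, 97.5])
    return float(lower), float(upper)


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-observation placement values (DeLong components)."""
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    v01 = (tz[:m] - tx) / n          # per-positive placement
    v10 = 1.0 - (tz[m:] - ty) / m    # per-negative placement
    a = float(v01.mean())
    return a, v01, v10


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    _, v01, v10 = _placements(scores, y)
    return float(np.var(v01, ddof=1) / len(v01) + np.var(v10, ddof=1) / len(v10))


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for a difference of paired ROC AUCs.

    Both score vectors must be computed on the same observations and
    labels.  Returns (z, p).  A zero-variance difference (e.g. identical
    scores) yields z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != y.shape:
        raise ValueError("DeLong test requires paired scores on identical labels")
    auc_a, v01_a, v10_a = _placements(scores_a, y)
    auc_b, v01_b, v10_b = _placements(scores_b, y)
    m, n = len(v01_a), len(v10_a)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    S = s01 / m + s10 / n
    var_diff = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    if var_diff <= 0:
        logger.info("DeLong variance of the AUC difference is zero; returning p = 1")
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve as (fpr, tpr, threshold) rows for text export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class RocComparison:
    """AUCs with bootstrap CIs per feature set, plus paired DeLong contrasts."""

    n_variants: int
    aucs: dict[str, float]
    cis: dict[str, tuple[float, float]]
    contrasts: list[tuple[str, str, float, float]]  # (a, b, z, p)
    scores: pd.DataFrame


def compare_feature_sets(
    table: pd.DataFrame,
    labels: pd.Series,
    model_specs: Mapping[str, Sequence[str]],
    contrasts: Sequence[tuple[str, str]] | None = None,
    B: int = 2000,
    seed: int = 0,
) -> RocComparison:
    """Fit one logistic model per feature subset and compare ROC AUCs.

    All models are fit and scored on the intersection of rows complete for
    *every* spec's columns, so AUCs are paired as the DeLong test requires.
    ``contrasts`` defaults to (first spec, last spec).
    """
    for name, cols in model_specs.items():
        if not cols:
            raise ValueError(f"feature set {name!r} is empty")
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"feature set {name!r}: columns {missing} absent from table")
    all_cols = sorted({c for cols in model_specs.values() for c in cols})
    labels = labels.loc[table.index]
    mask = table[all_cols].notna().all(axis=1) & labels.notna()
    sub = table.loc[mask]
    y = labels.loc[mask].astype(bool)
    logger.info("comparing %d feature sets on %d complete-case variants", len(model_specs), len(sub))

    scores = pd.DataFrame(index=sub.index)
    aucs: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    for i, (name, cols) in enumerate(model_specs.items()):
        scorer = logistic_fit(sub[list(cols)], y.to_numpy())
        s = scorer.predict_proba(sub[list(cols)])
        scores[name] = s
        aucs[name] = auc(s, y.to_numpy())
        cis[name] = auc_bootstrap_ci(s, y.to_numpy(), B=B, seed=seed + i)

    if contrasts is None:
        names = list(model_specs)
        contrasts = [(names[0], names[-1])] if len(names) >= 2 else []
    results = []
    for a, b in contrasts:
        z, p = delong_test(scores[a].to_numpy(), scores[b].to_numpy(), y.to_numpy())
        results.append((a, b, float(z), float(p)))
    scores["is_lof"] = y
    return RocComparison(n_variants=len(sub), aucs=aucs, cis=cis,
                         contrasts=results, scores=scores)
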