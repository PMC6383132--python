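"""Fully relaxed LASSO models of continuous functional perturbations.

The predictor set (sequence classifiers, evolutionary scores, burial
features, functional densities) is large relative to the number of
characterized variants, so feature selection is regularized: a LASSO path
selects the support and an unpenalized least-squares refit on that support
("fully relaxed") provides the reported coefficients, significance tests
and adjusted R².  The penalty is chosen by 10-fold cross-validation of the
*relaxed* fit along the path (minimum mean squared error; plain-LASSO and
one-standard-error rules are available).  Uncertainty on adjusted R² comes
from a case-resampling bootstrap of the relaxed refit with the selection
held fixed.

Because the functional-density features are themselves computed from the
training data, an honest out-of-sample estimate needs a higher-level CV in
which the density columns are rebuilt inside every training fold
(:func:`nested_cv_r2`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .functional_density import DEFAULT_SCALE, build_density_features
from .structures import DistanceMap
from .variants import NormalizedVariant, variant_key

logger = logging.getLogger(__name__)

__all__ = [
    "standardize",
    "adjusted_r2",
    "relaxed_lasso_fit",
    "bootstrap_adj_r2_ci",
    "nested_cv_r2",
    "model_accepted",
    "predict",
    "RelaxedLassoResult",
    "ModelError",
]


class ModelError(ValueError):
    pass


@dataclass
class Standardization:
    mean: pd.Series
    scale: pd.Series
    dropped_constant: tuple[str, ...]


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardization]:
    """Center each predictor and scale to unit variance (denominator n).

    Constant columns carry no information for a penalized fit and are
    dropped with a warning; the scaling record allows back-transformation.
    """
    mean = table.mean()
    sd = table.std(ddof=0)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if len(constant) == len(table.columns):
        raise ModelError("all predictor columns are constant")
    if constant:
        warnings.warn(f"dropping constant predictor columns: {constant}", stacklevel=2)
    keep = [c for c in table.columns if c not in constant]
    out = (table[keep] - mean[keep]) / sd[keep]
    return out, Standardization(mean=mean[keep], scale=sd[keep], dropped_constant=tuple(constant))


def adjusted_r2(y, y_hat, p_selected: int) -> float:
    """R² penalized for model size: 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = len(y)
    if n <= p_selected + 1:
        raise ModelError(f"adjusted R² undefined for n={n}, p={p_selected}")
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p_selected - 1)


@dataclass
class RelaxedLassoResult:
    """Two-stage fit: LASSO-selected support + unpenalized refit on it."""

    selected: tuple[str, ...]
    coefficients: pd.Series          # includes "const"; natural (unstandardized) units
    pvalues: pd.Series               # t-tests from the relaxed refit, excludes "const"
    r2: float
    adj_r2: float
    cv_r2: float                     # inner-CV R² of the relaxed fit at the chosen penalty
    adj_r2_ci: tuple[float, float] | None
    alpha: float
    n: int
    p_selected: int
    intercept_only: bool
    lambda_rule: str
    seed: int
    feature_names: tuple[str, ...] = ()
    n_dropped_rows: int = 0


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 100, eps: float = 1e-3) -> np.ndarray:
    n = len(y)
    alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.geomspace(alpha_max, alpha_max * eps, n_alphas)


def _ols_refit(X: np.ndarray, y: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Least-squares coefficients (intercept first) on the support columns."""
    A = np.column_stack([np.ones(len(y)), X[:, support]])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def relaxed_lasso_fit(
    table: pd.DataFrame,
    response: str | pd.Series | np.ndarray,
    folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "1se",
    min_rows: int = 30,
    n_alphas: int = 100,
) -> RelaxedLassoResult:
    """Fit a fully relaxed LASSO with cross-validated penalty choice.

    Parameters
    ----------
    table : DataFrame
        Predictor columns (and optionally the response column named by
        ``response``).  Rows with any missing value are dropped
        (complete-case) with a log note.
    response : str, Series or array
        Response column name, or the response values aligned with ``table``.
    lambda_rule : {"1se", "relaxed_min", "lasso_min"}
        How the penalty is picked from the 10-fold CV curve of the relaxed
        (OLS-refit) path: the largest penalty within one standard error of
        the minimum (default — the CV curve is flat near its minimum, so
        the exact argmin admits spurious features), the exact minimum, or
        the minimum of the penalized path.
    """
    if isinstance(response, str):
        y_all = table[response]
        X_all = table.drop(columns=[response])
    else:
        y_all = pd.Series(np.asarray(response, dtype=float), index=table.index)
        X_all = table
    mask = X_all.notna().all(axis=1) & y_all.notna()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d rows", n_dropped, len(mask))
    X_df = X_all.loc[mask]
    y = y_all.loc[mask].to_numpy(dtype=float)
    n = len(y)
    if n < min_rows:
        raise ModelError(f"n={n} rows below the configured floor of {min_rows}")
    if n < folds:
        raise ModelError(f"n={n} rows is fewer than {folds} folds")
    if lambda_rule not in ("relaxed_min", "lasso_min", "1se"):
        raise ModelError(f"unknown lambda_rule {lambda_rule!r}")
    if np.std(y) == 0:
        raise ModelError("constant response")

    Xs_df, scaling = standardize(X_df)
    names = tuple(Xs_df.columns)
    Xs = Xs_df.to_numpy(dtype=float)
    alphas = _lambda_grid(Xs, y, n_alphas=n_alphas)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = np.zeros((folds, len(alphas)))      # summed squared error per fold/alpha
    fold_sizes = np.zeros(folds)
    for k, (tr, te) in enumerate(kf.split(Xs)):
        Xtr, ytr = Xs[tr], y[tr]
        Xte, yte = Xs[te], y[te]
        _, coefs, _ = lasso_path(Xtr - Xtr.mean(0), ytr - ytr.mean(), alphas=alphas)
        if lambda_rule == "lasso_min":
            pred = (Xte - Xtr.mean(0)) @ coefs + ytr.mean()
            sq_err[k] = ((pred - yte[:, None]) ** 2).sum(axis=0)
        else:
            cache: dict[tuple, np.ndarray] = {}
            for a in range(len(alphas)):
                support = np.flatnonzero(np.abs(coefs[:, a]) > 0)
                key = tuple(support)
                if key not in cache:
                    beta = _ols_refit(Xtr, ytr, support)
                    cache[key] = beta
                beta = cache[key]
                pred = beta[0] + Xte[:, support] @ beta[1:]
                sq_err[k, a] = float(((pred - yte) ** 2).sum())
        fold_sizes[k] = len(te)
    cv_mse = sq_err.sum(axis=0) / n
    i_min = int(np.argmin(cv_mse))
    if lambda_rule == "1se":
        fold_mse = sq_err / fold_sizes[:, None]
        se = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds)
        threshold = cv_mse[i_min] + se[i_min]
        i_star = int(np.flatnonzero(cv_mse <= threshold)[0])  # alphas descend: first = largest
    else:
        i_star = i_min
    alpha_star = float(alphas[i_star])

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    cv_r2 = 1.0 - sq_err.sum(axis=0)[i_star] / ss_tot

    # final selection on the full data at the chosen penalty
    _, coefs_full, _ = lasso_path(Xs - Xs.mean(0), y - y.mean(), alphas=alphas)
    support = np.flatnonzero(np.abs(coefs_full[:, i_star]) > 0)
    selected = tuple(names[j] for j in support)

    if len(support) == 0:
        logger.info("all coefficients shrunk to zero; intercept-only model")
        coeff = pd.Series({"const": float(y.mean())})
        return RelaxedLassoResult(
            selected=(), coefficients=coeff, pvalues=pd.Series(dtype=float),
            r2=0.0, adj_r2=0.0, cv_r2=cv_r2, adj_r2_ci=None, alpha=alpha_star,
            n=n, p_selected=0, intercept_only=True, lambda_rule=lambda_rule,
            seed=seed, feature_names=names, n_dropped_rows=n_dropped,
        )

    # relaxed refit in natural units, with t-tests
    import statsmodels.api as sm

    X_sel = sm.add_constant(X_df[list(selected)], has_constant="add")
    ols = sm.OLS(y, X_sel).fit()
    coeff = pd.Series(ols.params, index=X_sel.columns)
    pvals = pd.Series(ols.pvalues, index=X_sel.columns).drop("const")
    y_hat = np.asarray(ols.fittedvalues)
    r2 = float(ols.rsquared)
    adj = adjusted_r2(y, y_hat, len(selected))

    return RelaxedLassoResult(
        selected=selected, coefficients=coeff, pvalues=pvals,
        r2=r2, adj_r2=adj, cv_r2=cv_r2, adj_r2_ci=None, alpha=alpha_star,
        n=n, p_selected=len(selected), intercept_only=False,
        lambda_rule=lambda_rule, seed=seed, feature_names=names,
        n_dropped_rows=n_dropped,
    )


def predict(result: RelaxedLassoResult, table: pd.DataFrame) -> pd.Series:
    """Predictions of the relaxed refit on new rows (natural units)."""
    yhat = pd.Series(result.coefficients.get("const", 0.0), index=table.index, dtype=float)
    for name in result.selected:
        yhat = yhat + result.coefficients[name] * table[name]
    return yhat


def bootstrap_adj_r2_ci(
    table: pd.DataFrame,
    response,
    result: RelaxedLassoResult,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for adjusted R² of the relaxed refit.

    Cases are resampled with replacement and the unpenalized refit is
    repeated on the support selected from the full data (selection held
    fixed); the 2.5/97.5 percentiles of the resampled adjusted R² form the
    interval.  Resamples with fewer than two distinct rows are redrawn.
    """
    if result.intercept_only:
        raise ModelError("bootstrap CI requires a nonempty support")
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small; intervals will be unstable",
                      stacklevel=2)
    if isinstance(response, str):
        y_all = table[response]
        X_all = table.drop(columns=[response])
    else:
        y_all = pd.Series(np.asarray(response, dtype=float), index=table.index)
        X_all = table
    mask = X_all[list(result.selected)].notna().all(axis=1) & y_all.notna()
    X = X_all.loc[mask, list(result.selected)].to_numpy(dtype=float)
    y = y_all.loc[mask].to_numpy(dtype=float)
    n = len(y)
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    stats_out = np.empty(B)
    support = np.arange(p)
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < 2:
            continue
        Xb, yb = X[idx], y[idx]
        if np.std(yb) == 0:
            stats_out[b] = 0.0
            b += 1
            continue
        beta = _ols_refit(Xb, yb, support)
        yhat = beta[0] + Xb @ beta[1:]
        stats_out[b] = adjusted_r2(yb, yhat, p)
        b += 1
    lower, upper = np.percentile(stats_out, [2.5, 97.5])
    return float(lower), float(upper)


def model_accepted(result: RelaxedLassoResult) -> bool:
    """Acceptance rule for a fitted model.

    True iff the support is nonempty, at least one refit coefficient is
    significant at 0.05 (t-test on the relaxed fit), and the lower bound
    of the 95% adjusted-R² interval exceeds 0.10.
    """
    if result.intercept_only or not result.selected:
        return False
    if result.adj_r2_ci is None:
        raise ModelError("model_accepted requires a bootstrap CI on the result")
    if not (len(result.pvalues) and float(result.pvalues.min()) < 0.05):
        return False
    return result.adj_r2_ci[0] > 0.10


def _keys_frame(variants: Sequence[NormalizedVariant]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [(v.gene, v.seq_position, v.alt_aa) for v in variants],
        names=["gene", "seq_position", "alt_aa"],
    )


def nested_cv_r2(
    variants: Sequence[NormalizedVariant],
    distances: DistanceMap,
    parameter: str,
    predictors: pd.DataFrame | None = None,
    outer_folds: int = 10,
    seed: int = 0,
    scale: float = DEFAULT_SCALE,
    include_weight_only: bool = True,
    lasso_folds: int = 10,
    lambda_rule: str = "1se",
    min_rows: int = 30,
) -> float:
    """Higher-level CV with a density construction step in every fold.

    The variants are split into ``outer_folds`` folds; within each training
    fold the functional-density (and weight-only) columns are rebuilt from
    the training variants alone, the relaxed LASSO is fitted, and held-out
    variants — whose densities are computed against the training set —
    are predicted.  Pooled out-of-fold predictions give
    cv_R² = 1 − SS_res/SS_tot.  Held-out variants with no surviving
    density contributor are dropped per the complete-case policy.

    ``predictors`` is an optional DataFrame of external feature columns
    indexed by (gene, seq_position, alt_aa).
    """
    variants = sorted(
        (v for v in variants if v.parameter == parameter), key=variant_key
    )
    if len(variants) < outer_folds:
        raise ModelError(f"{len(variants)} variants is fewer than {outer_folds} outer folds")
    y = pd.Series([v.delta_function for v in variants], index=_keys_frame(variants))

    kf = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    pooled_pred: list[pd.Series] = []
    pooled_obs: list[pd.Series] = []
    n_missing = 0
    order = np.arange(len(variants))
    for k, (tr, te) in enumerate(kf.split(order)):
        train = [variants[i] for i in tr]
        test = [variants[i] for i in te]
        feat_tr = build_density_features(train, train, distances, parameter, scale)
        feat_te = build_density_features(train, test, distances, parameter, scale)
        cols = ["rho"] + (["weight_only"] if include_weight_only else [])
        Xtr = feat_tr[cols].copy()
        Xte = feat_te[cols].copy()
        if predictors is not None:
            Xtr = Xtr.join(predictors, how="left")
            Xte = Xte.join(predictors, how="left")
        ytr = y.iloc[tr]
        fit = relaxed_lasso_fit(
            Xtr, ytr.to_numpy(), folds=lasso_folds, seed=seed + 1000 + k,
            lambda_rule=lambda_rule, min_rows=min(min_rows, len(tr)),
        )
        need = list(fit.selected)
        ok = Xte[need].notna().all(axis=1) if need else pd.Series(True, index=Xte.index)
        n_missing += int((~ok).sum())
        yhat = predict(fit, Xte.loc[ok])
        pooled_pred.append(yhat)
        pooled_obs.append(y.iloc[te].loc[ok])
    if n_missing:
        logger.info("%d held-out variants dropped for missing selected features", n_missing)
    pred = pd.concat(pooled_pred)
    obs = pd.concat(pooled_obs)
    ss_res = float(np.sum((obs.to_numpy() - pred.to_numpy()) ** 2))
    ss_tot = float(np.sum((obs.to_numpy() - obs.mean()) ** 2))
    return 1.0 - ss_res / ss_tot
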