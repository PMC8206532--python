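"""Refitting selected supports on the original scale and validating them.

Once the combinatorial search has ranked candidate supports, each support of
interest is refit by ordinary least squares with an intercept on the
untransformed data, giving coefficients in the units a clinician reads
(score points per unit predictor), their standard errors, t ratios and
p-values, the residual SD, the overall F statistic and the adjusted R^2.
Cross-validation follows the cohort protocol: subjects are randomly split
into folds of stated sizes (six folds of 20 and one of 19 for the 139-child
cohort), the support is refit leaving each fold out in turn, and held-out
RMSE is averaged unweighted over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .data_model import ModelRecord, PredictorMatrix, ResponseVector

__all__ = [
    "FittedModel",
    "CVResult",
    "refit_original_scale",
    "cross_validate",
    "null_model_sd",
    "predictor_frequency",
    "correlation_census",
]


@dataclass
class FittedModel:
    """OLS summary of one support refit on the original measurement scale."""

    support: tuple[int, ...]
    intercept: float
    coefficients: dict[int, float]
    std_errors: dict[int, float]
    t_ratios: dict[int, float]
    p_values: dict[int, float]
    intercept_se: float
    residual_sd: float
    df_resid: int
    F_value: float
    adj_R2: float
    rss: float
    _sm_results: object = field(default=None, repr=False)

    def summary(self):
        """statsmodels summary table for the underlying OLS fit."""
        return self._sm_results.summary()


@dataclass
class CVResult:
    """Held-out performance of one support under a seeded fold partition."""

    fold_sizes: list[int]
    rmse_per_fold: list[float]
    rmse_mean: float
    coefficient_mean_sd: dict[int, tuple[float, float]]
    seed: int


def _design_columns(X: PredictorMatrix, support) -> tuple[list[int], np.ndarray]:
    ids = sorted(support)
    cols = [X.predictor_ids.index(i) for i in ids]
    return ids, X.values[:, cols]


def refit_original_scale(
    X: PredictorMatrix, y: ResponseVector, support
) -> FittedModel:
    """OLS with intercept on the original units for one support.

    Standard errors use the unbiased residual variance; ``adj_R2`` is
    1 - (1 - R^2)(N - 1)/(N - |support| - 1).  Rank deficiency raises with
    the collinear IDs named.
    """
    ids, A = _design_columns(X, support)
    n = X.n_subjects
    if len(ids) + 1 > n:
        raise ValueError("support larger than N - 1")
    design = sm.add_constant(A, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"rank-deficient design for support {ids}: collinear columns")
    res = sm.OLS(y.values, design).fit()
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    tvals = np.asarray(res.tvalues)
    pvals = np.asarray(res.pvalues)
    return FittedModel(
        support=tuple(ids),
        intercept=float(params[0]),
        coefficients=dict(zip(ids, params[1:].tolist())),
        std_errors=dict(zip(ids, bse[1:].tolist())),
        t_ratios=dict(zip(ids, tvals[1:].tolist())),
        p_values=dict(zip(ids, pvals[1:].tolist())),
        intercept_se=float(bse[0]),
        residual_sd=float(np.sqrt(res.mse_resid)),
        df_resid=int(res.df_resid),
        F_value=float(res.fvalue) if ids else float("nan"),
        adj_R2=float(res.rsquared_adj),
        rss=float(res.ssr),
        _sm_results=res,
    )


def cross_validate(
    X: PredictorMatrix,
    y: ResponseVector,
    support,
    fold_sizes: list[int],
    seed: int = 0,
) -> CVResult:
    """Leave-fold-out cross-validation of one support.

    Subjects are randomly partitioned (seeded) into folds of the given sizes;
    for each fold the model is refit on the remainder and held-out predictions
    are scored by RMSE.  ``rmse_mean`` is the unweighted mean across folds and
    ``coefficient_mean_sd`` the mean and SD of each coefficient over the fold
    fits.
    """
    n = X.n_subjects
    if sum(fold_sizes) != n:
        raise ValueError(f"fold sizes sum to {sum(fold_sizes)}, expected N = {n}")
    ids, A = _design_columns(X, support)
    if max(fold_sizes) > n - len(ids) - 1:
        raise ValueError("a fold is too large to leave out and still fit the model")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = []
    start = 0
    for size in fold_sizes:
        folds.append(perm[start : start + size])
        start += size
    rmse = []
    coefs = []
    yv = y.values
    for hold in folds:
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        design = sm.add_constant(A[mask], has_constant="add")
        res = sm.OLS(yv[mask], design).fit()
        pred = sm.add_constant(A[hold], has_constant="add") @ np.asarray(res.params)
        rmse.append(float(np.sqrt(np.mean((yv[hold] - pred) ** 2))))
        coefs.append(np.asarray(res.params)[1:])
    coefs = np.array(coefs)
    mean_sd = {
        pid: (float(coefs[:, j].mean()), float(coefs[:, j].std(ddof=1)))
        for j, pid in enumerate(ids)
    }
    return CVResult(
        fold_sizes=list(fold_sizes),
        rmse_per_fold=rmse,
        rmse_mean=float(np.mean(rmse)),
        coefficient_mean_sd=mean_sd,
        seed=seed,
    )


def null_model_sd(y: ResponseVector) -> float:
    """Sample SD (n-1 denominator) of the response: the intercept-only RMSE."""
    if len(y) < 2:
        raise ValueError("need at least two observations")
    return float(np.std(y.values, ddof=1))


def predictor_frequency(
    models: list[ModelRecord], sizes=None, pairs=()
) -> tuple[dict[int, int], dict[tuple[int, int], int]]:
    """How often each predictor (and requested pairs) occurs in the ensemble.

    Counts models restricted to ``sizes`` (all sizes when None) whose support
    contains the ID, mirroring statements like "included in 52 of the 60
    models with 2-4 parameters".
    """
    if not models:
        raise ValueError("model list is empty")
    if sizes is not None:
        sizes = set(sizes)
        models = [m for m in models if m.n_terms in sizes]
    counts: dict[int, int] = {}
    for m in models:
        for pid in m.support:
            counts[pid] = counts.get(pid, 0) + 1
    pair_counts = {
        (a, b): sum(1 for m in models if a in m.support and b in m.support)
        for a, b in pairs
    }
    return counts, pair_counts


def correlation_census(
    X: PredictorMatrix, threshold: float = 0.5, column_subset=None
) -> int:
    """Number of unordered column pairs with Pearson correlation > threshold.

    Zero-variance columns are skipped.  Used to quantify the collinearity
    regime of the predictor pool.
    """
    if column_subset is not None:
        idx = [X.predictor_ids.index(i) for i in column_subset]
        vals = X.values[:, idx]
    else:
        vals = X.values
    sd = vals.std(axis=0)
    vals = vals[:, sd > 0]
    if vals.shape[1] < 2:
        raise ValueError("need at least two non-constant columns")
    corr = np.corrcoef(vals, rowvar=False)
    upper = corr[np.triu_indices_from(corr, k=1)]
    return int(np.sum(upper > threshold))
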