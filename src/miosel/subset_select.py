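"""k-best best-subset linear regression by exact mixed-integer search.

Best-subset selection asks, for each size p, for the support S (|S| <= p) of
predictors minimizing the residual sum of squares of an ordinary least-squares
fit.  Written as an optimization over binary inclusion indicators z_u and
coefficients beta_u, the objective is

    min  eta' eta - 2 (X'y)' beta + y'y        ( = ||y - X beta||^2 )
    s.t. z_u in {0, 1};  (1 - z_u) beta_u = 0;  sum_u z_u <= p;  eta = X beta.

The second-best through k-th-best supports of each size are obtained by
re-solving after adding, for each support S already found, the exclusion
constraint sum_{u in S} z_u <= |S| - 1 (the direct generalization of
"z_1 + z_2 < 2" for a found pair).

Two exact backends implement the search:

``branch_and_bound``
    Depth-first branching on the inclusion indicators with a valid lower
    bound: at a node with committed set I and candidate pool C the RSS of any
    completion is at least the RSS of the unrestricted fit on I u C (adding
    predictors never increases RSS).  The bound is informative when
    |I u C| < N and makes the search practical for pools up to a few dozen
    predictors; the indicator constraint is enforced combinatorially, so no
    big-M linearization (and no big-M truncation) is involved.

``enumeration``
    Chunked, vectorized evaluation of every size-p support through the Gram
    matrix (batched p x p solves).  This is the workhorse for the t > N
    regime, where no polynomial-time relaxation bound is informative, and is
    exact by construction.

``exhaustive_best_subsets`` is an independent verification oracle: it ranks
all supports by recursive Gram-Schmidt orthogonalization (sequential
projection, never touching the Gram-matrix route) and polishes coefficients
with ``numpy.linalg.lstsq``.
"""

from __future__ import annotations

import itertools
import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import ModelRecord, PredictorMatrix, ResponseVector

__all__ = [
    "StandardizedDesign",
    "SelectionConfig",
    "EnumerationCapError",
    "EnumerationExhausted",
    "standardize",
    "fit_support",
    "solve_best",
    "k_best_subsets",
    "exhaustive_best_subsets",
    "count_candidate_models",
]

_TIE_EPS = 1e-9


class EnumerationCapError(RuntimeError):
    """Raised when an exhaustive enumeration would exceed the candidate cap."""


class EnumerationExhausted(RuntimeError):
    """Raised when exclusion constraints leave no feasible support."""


@dataclass
class StandardizedDesign:
    """Predictors and response centered to mean 0 and scaled to SD 1.

    Coefficients on this scale express the change in the response, in
    response-SD units, per one-SD increase of a predictor.  The transform is
    invertible through the stored centers and scales.
    """

    Xs: np.ndarray
    ys: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    response_center: float
    response_scale: float
    predictor_ids: list[int]
    dropped_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._id_to_col = {pid: j for j, pid in enumerate(self.predictor_ids)}
        self._gram: np.ndarray | None = None
        self._xty: np.ndarray | None = None
        self._rank_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def n(self) -> int:
        return self.Xs.shape[0]

    @property
    def t(self) -> int:
        return self.Xs.shape[1]

    def columns_of(self, support) -> list[int]:
        return [self._id_to_col[i] for i in support]

    @property
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.Xs.T @ self.Xs
        return self._gram

    @property
    def xty(self) -> np.ndarray:
        if self._xty is None:
            self._xty = self.Xs.T @ self.ys
        return self._xty

    @property
    def yty(self) -> float:
        return float(self.ys @ self.ys)


@dataclass(frozen=True)
class SelectionConfig:
    """Search parameters for :func:`k_best_subsets`.

    ``backend`` is ``"auto"`` (branch-and-bound when the pool fits under the
    sample size, else enumeration), ``"branch_and_bound"`` or
    ``"enumeration"``.  ``solver_gap_tol`` is the pruning slack on RSS;
    ``solver_time_limit_s`` marks records non-certified instead of failing
    when exceeded.
    """

    p_max: int = 4
    k: int = 20
    backend: str = "auto"
    solver_gap_tol: float = 1e-9
    solver_time_limit_s: float = 600.0
    enum_cap: int = 2_000_000
    tie_break: str = "lexicographic"


def standardize(X: PredictorMatrix, y: ResponseVector) -> StandardizedDesign:
    """Center and scale predictors and response to mean 0, sample SD 1.

    Zero-variance columns cannot be scaled and are removed first; their IDs
    are reported on ``dropped_ids``.  All columns constant is fatal.
    """
    if len(y) != X.n_subjects:
        raise ValueError("response length does not match predictor rows")
    vals = X.values
    centers = vals.mean(axis=0)
    scales = vals.std(axis=0, ddof=1)
    keep = scales > 0
    if not keep.any():
        raise ValueError("all predictor columns are constant")
    dropped = [pid for pid, ok in zip(X.predictor_ids, keep) if not ok]
    Xs = (vals[:, keep] - centers[keep]) / scales[keep]
    yc = float(np.mean(y.values))
    ysd = float(np.std(y.values, ddof=1))
    if ysd == 0:
        raise ValueError("response is constant; nothing to model")
    return StandardizedDesign(
        Xs=Xs,
        ys=(y.values - yc) / ysd,
        centers=centers[keep],
        scales=scales[keep],
        response_center=yc,
        response_scale=ysd,
        predictor_ids=[pid for pid, ok in zip(X.predictor_ids, keep) if ok],
        dropped_ids=dropped,
    )


def fit_support(design: StandardizedDesign, support) -> tuple[dict[int, float], float, bool]:
    """OLS restricted to ``support`` on the standardized scale.

    Returns ``(coefficients, rss, degenerate)``; a rank-deficient submatrix
    yields the minimum-norm solution with ``degenerate=True``.
    """
    support = sorted(support)
    if len(support) > design.n - 1:
        raise ValueError("support larger than N - 1")
    if not support:
        return {}, design.yty, False
    cols = design.columns_of(support)
    G = design.gram[np.ix_(cols, cols)]
    c = design.xty[cols]
    degenerate = False
    try:
        beta = np.linalg.solve(G, c)
        # reject solutions from numerically singular systems
        if not np.isfinite(beta).all() or np.abs(G @ beta - c).max() > 1e-6 * max(
            1.0, np.abs(c).max()
        ):
            raise np.linalg.LinAlgError
        rss = design.yty - float(c @ beta)
    except np.linalg.LinAlgError:
        degenerate = True
        beta, *_ = np.linalg.lstsq(design.Xs[:, cols], design.ys, rcond=None)
        resid = design.ys - design.Xs[:, cols] @ beta
        rss = float(resid @ resid)
    return dict(zip(support, beta.tolist())), max(rss, 0.0), degenerate


def count_candidate_models(t: int, p: int) -> int:
    """Exact number of size-p supports among t predictors (binomial coefficient)."""
    if p < 0 or t < 0:
        raise ValueError("t and p must be non-negative")
    if p > t:
        raise ValueError(f"cannot choose {p} predictors out of {t}")
    return math.comb(t, p)


# ---------------------------------------------------------------------------
# enumeration backend (Gram route)


def _enumerate_rss(design: StandardizedDesign, p: int, chunk: int = 131_072):
    """Yield (supports, rss) chunks over all size-p column index tuples."""
    t = design.t
    G, c, yty = design.gram, design.xty, design.yty
    combos = itertools.combinations(range(t), p)
    while True:
        block = list(itertools.islice(combos, chunk))
        if not block:
            return
        S = np.array(block, dtype=np.int32)
        Gs = G[S[:, :, None], S[:, None, :]]
        cs = c[S]
        try:
            beta = np.linalg.solve(Gs, cs[..., None])[..., 0]
            rss = yty - np.einsum("bi,bi->b", cs, beta)
        except np.linalg.LinAlgError:
            rss = np.empty(len(S))
            for i, sup in enumerate(block):
                _, rss[i], _ = fit_support(
                    design, [design.predictor_ids[j] for j in sup]
                )
        bad = ~np.isfinite(rss)
        if bad.any():
            for i in np.flatnonzero(bad):
                _, rss[i], _ = fit_support(
                    design, [design.predictor_ids[j] for j in S[i]]
                )
        yield S, np.maximum(rss, 0.0)


def _tie_key(rss: float, support: tuple[int, ...]):
    """Ordering key: RSS quantized to the tie tolerance, then sorted support IDs."""
    return (round(rss / _TIE_EPS) * _TIE_EPS, support)


def _ranked_enumeration(design: StandardizedDesign, p: int, top: int):
    """Top supports of size p by RSS (lexicographic tie-break), cached on the design."""
    total = count_candidate_models(design.t, p)
    top = min(top, total)
    cache = design._rank_cache
    if p in cache and len(cache[p][0]) >= top:
        return cache[p]
    chunks_S, chunks_rss = [], []
    for S, rss in _enumerate_rss(design, p):
        chunks_S.append(S)
        chunks_rss.append(rss)
    S = np.vstack(chunks_S)
    rss = np.concatenate(chunks_rss)
    if top < len(rss):
        thresh = np.partition(rss, top - 1)[top - 1]
        keep = np.flatnonzero(rss <= thresh + _TIE_EPS)
    else:
        keep = np.arange(len(rss))
    items = sorted(
        ((float(rss[i]), tuple(int(j) for j in S[i])) for i in keep),
        key=lambda x: _tie_key(*x),
    )[:top]
    cache[p] = (np.array([r for r, _ in items]), [s for _, s in items])
    return cache[p]


def _is_feasible(support_ids: frozenset, exclusions) -> bool:
    return not any(S <= support_ids for S in exclusions)


def _solve_enumeration(design, p, exclusions, config):
    top = max(4 * config.k, len(exclusions) + 8, 64)
    total = count_candidate_models(design.t, p)
    while True:
        rss_arr, supports = _ranked_enumeration(design, p, top)
        for rss, sup in zip(rss_arr, supports):
            ids = frozenset(design.predictor_ids[j] for j in sup)
            if _is_feasible(ids, exclusions):
                return ids, float(rss), True
        if len(supports) >= total:
            raise EnumerationExhausted(
                f"no feasible size-{p} support remains under {len(exclusions)} exclusions"
            )
        top *= 4
        design._rank_cache.pop(p, None)


# ---------------------------------------------------------------------------
# branch-and-bound backend (MIO route)


def _solve_branch_and_bound(design, p, exclusions, config):
    t = design.t
    Xs, ys = design.Xs, design.ys
    order = np.argsort(-np.abs(design.xty))  # strongest marginal correlation first
    excl_cols = [frozenset(design.columns_of(S)) for S in exclusions]
    deadline = time.monotonic() + config.solver_time_limit_s
    best = {"rss": np.inf, "support": None, "certified": True}
    gap = config.solver_gap_tol

    def leaf(chosen: tuple[int, ...]) -> None:
        ids = [design.predictor_ids[j] for j in chosen]
        _, rss, _ = fit_support(design, ids)
        sup = tuple(sorted(chosen))
        if rss < best["rss"] - _TIE_EPS or (
            abs(rss - best["rss"]) <= _TIE_EPS
            and (best["support"] is None or sup < best["support"])
        ):
            best["rss"], best["support"] = rss, sup

    def lower_bound(chosen: frozenset, pos: int) -> float:
        avail = [j for j in order[pos:]]
        pool = sorted(chosen) + avail
        if len(pool) >= design.n:
            return 0.0
        A = Xs[:, pool]
        coef, residual, *_ = np.linalg.lstsq(A, ys, rcond=None)
        if residual.size:
            return float(residual[0])
        r = ys - A @ coef
        return float(r @ r)

    def greedy_seed() -> None:
        # forward-selection incumbent: a feasible warm start so a time-limit
        # expiry still returns a best-found-so-far support
        chosen: list[int] = []
        for _ in range(p):
            gains = []
            for j in range(t):
                if j in chosen:
                    continue
                cand = chosen + [j]
                cand_ids = frozenset(cand)
                if any(S <= cand_ids for S in excl_cols):
                    continue
                _, rss, _ = fit_support(design, [design.predictor_ids[i] for i in cand])
                gains.append((rss, j))
            if not gains:
                return
            chosen.append(min(gains)[1])
        leaf(tuple(chosen))

    def dfs(chosen: tuple[int, ...], pos: int) -> None:
        if time.monotonic() > deadline:
            best["certified"] = False
            return
        chosen_set = frozenset(chosen)
        if any(S <= chosen_set for S in excl_cols):
            return
        if len(chosen) == p:
            leaf(chosen)
            return
        remaining = t - pos
        if remaining < p - len(chosen):
            return
        if np.isfinite(best["rss"]) and lower_bound(chosen_set, pos) > best["rss"] * (
            1 + gap
        ) + _TIE_EPS:
            # prune only strictly worse subtrees so exact RSS ties stay
            # reachable for the lexicographic tie-break
            return
        j = int(order[pos])
        dfs(chosen + (j,), pos + 1)  # include branch first: good incumbents early
        dfs(chosen, pos + 1)

    greedy_seed()
    dfs((), 0)
    if best["support"] is None:
        raise EnumerationExhausted(
            f"no feasible size-{p} support remains under {len(exclusions)} exclusions"
        )
    ids = frozenset(design.predictor_ids[j] for j in best["support"])
    return ids, best["rss"], best["certified"]


# ---------------------------------------------------------------------------
# public solver API


def _pick_backend(design: StandardizedDesign, p: int, config: SelectionConfig) -> str:
    if config.backend != "auto":
        return config.backend
    if design.t < design.n and design.t <= 40:
        return "branch_and_bound"
    return "enumeration"


def solve_best(
    design: StandardizedDesign,
    p: int,
    exclusions=(),
    config: SelectionConfig | None = None,
) -> ModelRecord:
    """Best size-p support minimizing RSS subject to the exclusion constraints.

    Each exclusion set S adds the constraint sum_{u in S} z_u <= |S| - 1, so
    the returned support never contains any S.  Coefficients are re-solved by
    :func:`fit_support` on the returned support (OLS polish).
    """
    config = config or SelectionConfig(p_max=p)
    if p < 1 or p > design.t:
        raise ValueError(f"p must lie in [1, t={design.t}]")
    if p > design.n - 1:
        raise ValueError("p must be smaller than the number of subjects")
    exclusions = [frozenset(S) for S in exclusions]
    if any(len(S) > p for S in exclusions):
        raise ValueError("exclusion sets larger than p are vacuous; refusing")
    backend = _pick_backend(design, p, config)
    if backend == "enumeration":
        if count_candidate_models(design.t, p) > config.enum_cap:
            raise EnumerationCapError(
                f"C({design.t},{p}) = {count_candidate_models(design.t, p)} exceeds "
                f"the enumeration cap {config.enum_cap}; use branch_and_bound or raise enum_cap"
            )
        ids, rss, certified = _solve_enumeration(design, p, exclusions, config)
    elif backend == "branch_and_bound":
        ids, rss, certified = _solve_branch_and_bound(design, p, exclusions, config)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    coefs, rss_polished, degenerate = fit_support(design, ids)
    return ModelRecord(
        support=ids,
        coefficients_std=coefs,
        rss=rss_polished,
        n_terms=len(ids),
        certified=certified,
        degenerate=degenerate,
    )


def k_best_subsets(
    design: StandardizedDesign, config: SelectionConfig | None = None
) -> list[ModelRecord]:
    """For each size p = 1..p_max, the k best distinct supports by RSS.

    After each solution its support is appended to the exclusion list for that
    size and the solver is re-run, so successive solutions are forced to be
    distinct.  Records carry ``rank_within_size`` in nondecreasing-RSS order.
    """
    config = config or SelectionConfig()
    out: list[ModelRecord] = []
    for p in range(1, config.p_max + 1):
        exclusions: list[frozenset] = []
        for rank in range(1, config.k + 1):
            try:
                rec = solve_best(design, p, exclusions, config)
            except EnumerationExhausted:
                warnings.warn(
                    f"only {rank - 1} feasible size-{p} supports exist; list truncated",
                    stacklevel=2,
                )
                break
            rec = ModelRecord(
                support=rec.support,
                coefficients_std=rec.coefficients_std,
                rss=rec.rss,
                n_terms=rec.n_terms,
                rank_within_size=rank,
                certified=rec.certified,
                degenerate=rec.degenerate,
            )
            out.append(rec)
            exclusions.append(rec.support)
    return out


# ---------------------------------------------------------------------------
# independent oracle: orthogonalization route


def _ortho_all_rss(X: np.ndarray, y: np.ndarray, p: int):
    """RSS of every size-p support via recursive sequential orthogonalization.

    At each recursion level the chosen column is normalized and projected out
    of the response and of all later columns; at the last level the gain of
    each remaining column is a vectorized squared correlation.  Linearly
    dependent columns (residual norm ~ 0) contribute zero gain, which is the
    exact minimum-norm behaviour.
    """
    t = X.shape[1]
    supports: list[tuple[int, ...]] = []
    rss_out: list[float] = []

    def recurse(Xr, yr, cols, prefix, depth):
        if depth == p - 1:
            norms2 = np.einsum("ij,ij->j", Xr, Xr)
            proj = Xr.T @ yr
            gains = np.where(norms2 > 1e-12, proj**2 / np.where(norms2 > 1e-12, norms2, 1.0), 0.0)
            base = float(yr @ yr)
            for i, col in enumerate(cols):
                supports.append(prefix + (col,))
                rss_out.append(max(base - float(gains[i]), 0.0))
            return
        m = len(cols)
        for i in range(m - (p - depth - 1)):
            u = Xr[:, i]
            n2 = float(u @ u)
            rest = Xr[:, i + 1 :]
            if n2 > 1e-12:
                un = u / math.sqrt(n2)
                rest = rest - np.outer(un, un @ rest)
                ynew = yr - un * float(un @ yr)
            else:
                ynew = yr
            recurse(rest, ynew, cols[i + 1 :], prefix + (cols[i],), depth + 1)

    if p == 0:
        return [()], [float(y @ y)]
    recurse(X.copy(), y.copy(), tuple(range(t)), (), 0)
    return supports, rss_out


def exhaustive_best_subsets(
    design: StandardizedDesign, p: int, k: int, cap: int = 2_000_000
) -> list[ModelRecord]:
    """Rank every size-p support by RSS; verification oracle for the solver.

    Refuses when C(t, p) exceeds ``cap``, stating the exact count.  Ties in
    RSS are broken lexicographically by sorted support IDs.
    """
    n_candidates = count_candidate_models(design.t, p)
    if n_candidates > cap:
        raise EnumerationCapError(
            f"exhaustive search over C({design.t},{p}) = {n_candidates} candidates "
            f"exceeds the cap of {cap}; raise `cap` explicitly to proceed"
        )
    supports, rss = _ortho_all_rss(design.Xs, design.ys, p)
    ids_of = [tuple(sorted(design.predictor_ids[j] for j in sup)) for sup in supports]
    order = sorted(range(len(supports)), key=lambda i: _tie_key(rss[i], ids_of[i]))
    out = []
    for rank, i in enumerate(order[:k], start=1):
        ids = sorted(design.predictor_ids[j] for j in supports[i])
        beta, *_ = np.linalg.lstsq(design.Xs[:, list(supports[i])], design.ys, rcond=None)
        coefs = dict(
            zip(ids, beta[np.argsort([design.predictor_ids[j] for j in supports[i]])].tolist())
        )
        resid = design.ys - design.Xs[:, list(supports[i])] @ beta
        out.append(
            ModelRecord(
                support=frozenset(ids),
                coefficients_std=coefs,
                rss=float(resid @ resid),
                n_terms=p,
                rank_within_size=rank,
            )
        )
    return out
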