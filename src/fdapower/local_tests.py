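"""Six local inferential methods for the two-sample functional hypothesis.

All methods address the local hypothesis

    H0: mu_1(t) = mu_2(t) for all t in D   vs.   H1: mu_1(t) != mu_2(t) somewhere,

and report *where* the null is rejected (a union of closed domain intervals),
not just whether.  The shared statistic family is the pointwise pooled
two-sample t statistic; methods needing a nonnegative statistic square it
(F = t^2, identical to the one-way two-group F).

Methods
-------
spm    Parametric random-field-theory inference (statistical parametric
       mapping): the domain-wide threshold solves expected Euler
       characteristic = alpha for a 1D t-field whose smoothness is estimated
       from the pooled residuals.
fmax   Permutation distribution of the domain-wide maximum F statistic
       (a.k.a. SnPM).
iwt    Interval-wise testing: permutation tests of the summed F statistic on
       every contiguous grid interval, aggregated to pointwise adjusted
       p-values by maximisation over covering intervals.
twt    Threshold-wise testing: permutation tests on data-driven subsets
       obtained by thresholding the unadjusted pointwise p-value function.
erl    Global envelope test ordering the pooled statistic functions by
       extreme rank length; rejection where the observed function exits the
       envelope of the most central functions.
iatse  Iterative adaptive two-stage envelope controlling the false discovery
       rate via an adaptive estimate of the proportion of true null points.

spm, fmax, iwt, twt and erl control the family-wise error rate; iatse
controls the FDR (and is conservative in the FWER sense under a full null).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import optimize, stats

from .curves_io import Curve, DomainGrid
from .exceptions import DegenerateDataError, ParameterError
from .noise_signal import FunctionalSample

__all__ = [
    "TestConfig",
    "StatFunction",
    "PermutationNull",
    "TestResult",
    "pointwise_stat",
    "permutation_null",
    "estimate_fwhm",
    "spm_test",
    "fmax_test",
    "iwt_test",
    "twt_test",
    "erl_test",
    "iatse_test",
    "run_test",
    "METHODS",
    "mask_to_intervals",
]

_VAR_EPS = 1e-300  # pooled variance at or below this is treated as degenerate


@dataclass(frozen=True)
class TestConfig:
    """Shared test configuration.

    Parameters
    ----------
    alpha
        Significance level for the omnibus decision and adjusted p-values.
    n_perm
        Number of random label permutations B; exhaustive enumeration is used
        instead whenever the number of distinct assignments is <= B.
    seed
        Seed for the permutation stream (int or numpy SeedSequence).
    max_iter
        Iteration cap for the adaptive envelope (iatse) fixed point.
    """

    alpha: float = 0.05
    n_perm: int = 1000
    seed: object = None
    max_iter: int = 20

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_perm < 1:
            raise ParameterError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.n_perm < 1.0 / self.alpha - 1.0:
            raise ParameterError(
                f"n_perm={self.n_perm} cannot resolve p-values at alpha={self.alpha}"
            )


@dataclass(frozen=True)
class StatFunction:
    """A pointwise test-statistic function on the grid."""

    grid: DomainGrid
    values: np.ndarray
    kind: str  # "t" or "F"


@dataclass(frozen=True)
class PermutationNull:
    """B permuted statistic functions (rows) plus bookkeeping."""

    stats: np.ndarray  # (B, p)
    kind: str
    exhaustive: bool
    scheme: str
    seed: object = None

    @property
    def n_perm(self) -> int:
        return int(self.stats.shape[0])


@dataclass(frozen=True)
class TestResult:
    """Outcome of one local test.

    ``rejection_set`` is a tuple of closed ``(low, high)`` position intervals
    in domain units (degenerate intervals mark single rejected points); it is
    nonempty exactly when ``rejected`` is true.
    """

    method: str
    rejected: bool
    rejection_set: tuple
    alpha: float
    pvalue: float | None = None
    pvalue_function: Curve | None = None
    envelope: tuple | None = None  # (lower Curve, upper Curve)
    threshold: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# statistics and the permutation engine
# ---------------------------------------------------------------------------


def _stack(g1: FunctionalSample, g2: FunctionalSample):
    if g1.grid != g2.grid:
        raise ParameterError("the two samples must share one grid")
    if g1.n < 2 or g2.n < 2:
        raise ParameterError("each group needs at least 2 curves")
    return np.vstack([g1.values, g2.values]), g1.n, g2.n


def _pooled_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pointwise pooled two-sample t for (n1,p) and (n2,p) arrays."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss1 = ((x1 - m1) ** 2).sum(axis=0)
    ss2 = ((x2 - m2) ** 2).sum(axis=0)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    if np.any(sp2 <= _VAR_EPS):
        raise DegenerateDataError("zero pooled variance at some grid point")
    return (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def pointwise_stat(
    g1: FunctionalSample, g2: FunctionalSample, kind: str = "t"
) -> StatFunction:
    """Pointwise pooled two-sample statistic: t, or its square F."""
    if kind not in ("t", "F"):
        raise ParameterError(f"kind must be 't' or 'F', got {kind!r}")
    x, _, _ = _stack(g1, g2)
    t = _pooled_t(g1.values, g2.values)
    return StatFunction(g1.grid, t if kind == "t" else t**2, kind)


def _assignment_matrix(n: int, n1: int, B: int, rng: np.random.Generator):
    """0/1 group-1 membership rows; exhaustive when C(n, n1) <= B."""
    total = comb(n, n1)
    if total <= B:
        G = np.zeros((total, n))
        for b, idx in enumerate(combinations(range(n), n1)):
            G[b, list(idx)] = 1.0
        return G, True
    G = np.zeros((B, n))
    cols = np.argsort(rng.random((B, n)), axis=1)[:, :n1]
    np.put_along_axis(G, cols, 1.0, axis=1)
    return G, False


def _perm_t(x: np.ndarray, G: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """t statistics for every assignment row of G, vectorised via BLAS."""
    n = n1 + n2
    S = x.sum(axis=0)
    SS = (x**2).sum(axis=0)
    sum1 = G @ x
    sumsq1 = G @ (x**2)
    m1 = sum1 / n1
    m2 = (S - sum1) / n2
    ss1 = np.clip(sumsq1 - sum1**2 / n1, 0.0, None)
    ss2 = np.clip((SS - sumsq1) - (S - sum1) ** 2 / n2, 0.0, None)
    sp2 = (ss1 + ss2) / (n - 2)
    if np.any(sp2 <= _VAR_EPS):
        raise DegenerateDataError("zero pooled variance under some permutation")
    return (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def permutation_null(
    g1: FunctionalSample,
    g2: FunctionalSample,
    kind: str = "F",
    B: int = 1000,
    seed=None,
) -> PermutationNull:
    """Null statistic functions from random (or exhaustive) label shuffles.

    Curves are pooled and reassigned to groups of the original sizes; if the
    number of distinct assignments is at most B, all of them (including the
    identity) are enumerated and permutation p-values are exact.
    """
    if kind not in ("t", "F"):
        raise ParameterError(f"kind must be 't' or 'F', got {kind!r}")
    x, n1, n2 = _stack(g1, g2)
    rng = np.random.default_rng(seed)
    G, exhaustive = _assignment_matrix(n1 + n2, n1, B, rng)
    t = _perm_t(x, G, n1, n2)
    scheme = (
        f"exhaustive({G.shape[0]} assignments)"
        if exhaustive
        else f"random({G.shape[0]} of {comb(n1 + n2, n1)} assignments)"
    )
    return PermutationNull(t if kind == "t" else t**2, kind, exhaustive, scheme, seed)


def _perm_pvalue(count_ge, null: PermutationNull):
    """Permutation p-value from exceedance counts.

    Exhaustive mode: exact p = count/total (the identity assignment is in the
    enumeration, so p > 0).  Random mode: add-one convention (1+count)/(B+1).
    """
    count_ge = np.asarray(count_ge, dtype=float)
    B = null.n_perm
    if null.exhaustive:
        return count_ge / B
    return (count_ge + 1.0) / (B + 1.0)


def _ge_tol(ref):
    """Tolerance for exceedance comparisons against the observed statistic.

    Permuted statistics equal to the observed one in exact arithmetic (e.g.
    the identity assignment in exhaustive mode) must count as ties even if
    the two were computed along different floating-point paths.
    """
    return 1e-9 * (1.0 + np.abs(ref))


def _count_ge(perm_values: np.ndarray, ref, axis=0):
    """#{permuted >= observed}, tie-tolerant (see :func:`_ge_tol`)."""
    return (perm_values >= ref - _ge_tol(ref)).sum(axis=axis)


def mask_to_intervals(grid: DomainGrid, mask: np.ndarray) -> tuple:
    """Merge a boolean grid mask into closed position intervals."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((float(grid.points[start]), float(grid.points[i - 1])))
            start = None
    if start is not None:
        out.append((float(grid.points[start]), float(grid.points[-1])))
    return tuple(out)


def _result_from_pfunction(
    method: str, grid: DomainGrid, pfun: np.ndarray, alpha: float, **kw
) -> TestResult:
    pfun = np.minimum(np.asarray(pfun, dtype=float), 1.0)
    mask = pfun <= alpha
    return TestResult(
        method=method,
        rejected=bool(mask.any()),
        rejection_set=mask_to_intervals(grid, mask),
        alpha=alpha,
        pvalue=float(pfun.min()),
        pvalue_function=Curve(grid, pfun),
        **kw,
    )


# ---------------------------------------------------------------------------
# smoothness estimation and SPM
# ---------------------------------------------------------------------------

_4LOG2 = 4.0 * math.log(2.0)


def estimate_fwhm(residuals, grid: DomainGrid | None = None) -> float:
    """Estimate the smoothness FWHM of residual curves in domain units.

    Uses the gradient-variance estimator of the random-field literature:
    residuals are normalised pointwise by their root sum of squares, and the
    per-point resel density is sqrt(v(t)/(4 ln 2)) where v(t) is the sum of
    squared gradients of the normalised residuals; the FWHM estimate is the
    reciprocal of the mean resel density.
    """
    if isinstance(residuals, FunctionalSample):
        grid = residuals.grid
        values = residuals.values
    else:
        values = np.asarray(residuals, dtype=float)
        if grid is None:
            raise ParameterError("grid required when residuals given as array")
    if values.shape[0] < 2:
        raise ParameterError("need at least 2 residual curves")
    if grid.length < 2:
        raise DegenerateDataError("smoothness undefined on a single-point grid")
    ssq = (values**2).sum(axis=0)
    if np.any(ssq <= 0):
        raise DegenerateDataError("constant (zero) residuals at some grid point")
    u = values / np.sqrt(ssq)
    grad = np.gradient(u, grid.points, axis=1)
    v = (grad**2).sum(axis=0)
    resel_density = np.sqrt(v / _4LOG2)
    mean_density = resel_density.mean()
    if not np.isfinite(mean_density) or mean_density <= 0:
        raise DegenerateDataError("non-finite smoothness estimate")
    return float(1.0 / mean_density)


def _rft_pmax_tfield(u: float, df: int, resels: float) -> float:
    """Expected-EC approximation to P(max |t field| > u).

    Sum of the tail probability (EC density of order 0) and the resel-scaled
    1D EC density of the t field, doubled for two-sided inference.
    """
    if u <= 0:
        return 1.0
    p0 = stats.t.sf(u, df)
    p1 = (
        math.sqrt(_4LOG2)
        / (2.0 * math.pi)
        * (1.0 + u**2 / df) ** (-(df - 1) / 2.0)
    )
    return min(1.0, 2.0 * (p0 + resels * p1))


def spm_test(
    g1: FunctionalSample, g2: FunctionalSample, cfg: TestConfig = TestConfig()
) -> TestResult:
    """Random-field-theory (SPM) inference on the |t| field.

    Residual smoothness is estimated from the pooled within-group residuals;
    the resel count is the domain span divided by the FWHM estimate; the
    critical threshold solves expected EC = alpha.  On a single-point domain
    the resel count is 0 and the procedure reduces to the two-sided pooled
    two-sample t test.
    """
    x, n1, n2 = _stack(g1, g2)
    df = n1 + n2 - 2
    t_obs = _pooled_t(g1.values, g2.values)
    grid = g1.grid
    if grid.length < 2 or grid.span == 0:
        resels = 0.0
        fwhm_hat = math.inf
    else:
        residuals = np.vstack(
            [g1.values - g1.values.mean(axis=0), g2.values - g2.values.mean(axis=0)]
        )
        fwhm_hat = estimate_fwhm(residuals, grid)
        resels = grid.span / fwhm_hat
    # critical |t| threshold: expected EC equals alpha
    f = lambda u: _rft_pmax_tfield(u, df, resels) - cfg.alpha
    hi = 10.0
    while f(hi) > 0 and hi < 1e6:
        hi *= 2.0
    u_star = float(optimize.brentq(f, 1e-12, hi, xtol=1e-10))
    pfun = np.array([_rft_pmax_tfield(abs(t), df, resels) for t in t_obs])
    return _result_from_pfunction(
        "spm",
        grid,
        pfun,
        cfg.alpha,
        threshold=u_star,
        extras={"fwhm_hat": fwhm_hat, "resels": resels, "df": df},
    )


# ---------------------------------------------------------------------------
# permutation-based methods
# ---------------------------------------------------------------------------


def fmax_test(
    g1: FunctionalSample, g2: FunctionalSample, cfg: TestConfig = TestConfig()
) -> TestResult:
    """Permutation test on the domain-wide maximum F statistic (SnPM)."""
    f_obs = pointwise_stat(g1, g2, "F").values
    null = permutation_null(g1, g2, "F", cfg.n_perm, cfg.seed)
    maxima = np.sort(null.stats.max(axis=1))
    # exceedance counts via binary search in the sorted permuted maxima
    count = maxima.size - np.searchsorted(maxima, f_obs - _ge_tol(f_obs), side="left")
    pfun = _perm_pvalue(count, null)
    return _result_from_pfunction(
        "fmax", g1.grid, pfun, cfg.alpha, extras={"scheme": null.scheme}
    )


def iwt_test(
    g1: FunctionalSample, g2: FunctionalSample, cfg: TestConfig = TestConfig()
) -> TestResult:
    """Interval-wise testing: summed-F permutation tests on every interval.

    All contiguous non-wrap-around intervals (including single points) are
    tested; the adjusted p-value at t is the maximum of the interval p-values
    over all intervals containing t, giving interval-wise FWER control.
    """
    f_obs = pointwise_stat(g1, g2, "F").values
    null = permutation_null(g1, g2, "F", cfg.n_perm, cfg.seed)
    p = f_obs.size
    cs_obs = np.concatenate([[0.0], np.cumsum(f_obs)])
    cs_perm = np.concatenate(
        [np.zeros((null.n_perm, 1)), np.cumsum(null.stats, axis=1)], axis=1
    )
    # interval p-values P[s, e], filled one interval length at a time so the
    # inner comparisons are contiguous slices (no large gathers)
    P = np.full((p, p), -np.inf)
    s_all = np.arange(p)
    for length in range(1, p + 1):
        seg_obs = cs_obs[length:] - cs_obs[: p - length + 1]
        seg_perm = cs_perm[:, length:] - cs_perm[:, : p - length + 1]
        counts = _count_ge(seg_perm, seg_obs)
        starts = s_all[: p - length + 1]
        P[starts, starts + length - 1] = _perm_pvalue(counts, null)
    # adjusted p at t: max over covering intervals, via two cumulative maxima
    right = np.maximum.accumulate(P[:, ::-1], axis=1)[:, ::-1]
    both = np.maximum.accumulate(right, axis=0)
    pfun = np.diagonal(both).copy()
    return _result_from_pfunction(
        "iwt", g1.grid, pfun, cfg.alpha, extras={"scheme": null.scheme}
    )


def twt_test(
    g1: FunctionalSample, g2: FunctionalSample, cfg: TestConfig = TestConfig()
) -> TestResult:
    """Threshold-wise testing on data-driven p-value level sets.

    Thresholds are the sorted unique values of the unadjusted pointwise
    permutation p-values; each level set S_c = {t : p_unadj(t) <= c} (possibly
    disconnected) is tested with the summed-F permutation test, and the
    adjusted p-value at t is the maximum subset p-value over all level sets
    containing t.
    """
    f_obs = pointwise_stat(g1, g2, "F").values
    null = permutation_null(g1, g2, "F", cfg.n_perm, cfg.seed)
    p_unadj = _perm_pvalue(_count_ge(null.stats, f_obs), null)
    thresholds = np.unique(p_unadj)  # ascending
    subset_p = np.empty(thresholds.size)
    for i, c in enumerate(thresholds):
        sel = p_unadj <= c
        obs_sum = f_obs[sel].sum()
        subset_p[i] = _perm_pvalue(_count_ge(null.stats[:, sel].sum(axis=1), obs_sum), null)
    # adjusted p at t = max over thresholds c >= p_unadj(t) (suffix maximum),
    # never below the point's own unadjusted p (the degenerate finest subset)
    suffix_max = np.maximum.accumulate(subset_p[::-1])[::-1]
    pfun = np.maximum(suffix_max[np.searchsorted(thresholds, p_unadj)], p_unadj)
    return _result_from_pfunction(
        "twt", g1.grid, pfun, cfg.alpha, extras={"scheme": null.scheme}
    )


# ---------------------------------------------------------------------------
# envelope methods (on the pooled t-statistic functions, two-sided ranks)
# ---------------------------------------------------------------------------


def _pooled_t_functions(g1, g2, cfg):
    t_obs = pointwise_stat(g1, g2, "t").values
    null = permutation_null(g1, g2, "t", cfg.n_perm, cfg.seed)
    pooled = np.vstack([t_obs[None, :], null.stats])
    return t_obs, null, pooled


def _extreme_ranks(pooled: np.ndarray) -> np.ndarray:
    """Two-sided pointwise extreme ranks (1 = most extreme); ties share ranks."""
    below = stats.rankdata(pooled, method="min", axis=0)
    above = stats.rankdata(-pooled, method="min", axis=0)
    return np.minimum(below, above)


def erl_test(
    g1: FunctionalSample, g2: FunctionalSample, cfg: TestConfig = TestConfig()
) -> TestResult:
    """Extreme-rank-length global envelope test.

    The observed and permuted t functions are pooled and ordered
    lexicographically by their increasingly sorted vectors of two-sided
    pointwise extreme ranks (functions with longer runs of extreme pointwise
    ranks are more extreme).  The level-alpha envelope is the pointwise
    min/max of the ceil((1-alpha)(B+1)) most central functions; the null is
    rejected wherever the observed function falls strictly outside it.
    """
    t_obs, null, pooled = _pooled_t_functions(g1, g2, cfg)
    k_tot = pooled.shape[0]
    ranks = _extreme_ranks(pooled)
    M = np.sort(ranks, axis=1)  # each row ascending: the ERL measure
    # ERL p-value: share of pooled functions at least as extreme as observed
    diff = M - M[0]
    nonzero = diff != 0
    first = np.argmax(nonzero, axis=1)
    lead = diff[np.arange(k_tot), first]
    is_tie = ~nonzero.any(axis=1)
    n_extreme_or_tied = int(np.sum((lead < 0) & ~is_tie) + np.sum(is_tie))
    p_erl = n_extreme_or_tied / k_tot
    # central envelope
    n_central = math.ceil((1.0 - cfg.alpha) * k_tot)
    order = np.lexsort(M.T[::-1])  # ascending lexicographic: extreme first
    n_drop = k_tot - n_central
    if n_drop > 0:
        boundary = M[order[n_drop]]
        dropped = [j for j in order[:n_drop] if not np.array_equal(M[j], boundary)]
    else:
        dropped = []
    central = np.setdiff1d(np.arange(k_tot), np.array(dropped, dtype=int))
    low = pooled[central].min(axis=0)
    up = pooled[central].max(axis=0)
    mask = (t_obs < low) | (t_obs > up)
    grid = g1.grid
    return TestResult(
        method="erl",
        rejected=bool(mask.any()),
        rejection_set=mask_to_intervals(grid, mask),
        alpha=cfg.alpha,
        pvalue=float(p_erl),
        envelope=(Curve(grid, low), Curve(grid, up)),
        extras={"scheme": null.scheme, "n_central": int(central.size)},
    )


def iatse_test(
    g1: FunctionalSample, g2: FunctionalSample, cfg: TestConfig = TestConfig()
) -> TestResult:
    """Iterative adaptive two-stage FDR envelope test.

    For an envelope width index k the pointwise envelope spans the k-th
    smallest to the k-th largest of the pooled t functions; under
    exchangeability a true-null point exits with probability 2(k-1)/(B+1),
    so the estimated false rejections are pi0 * p * 2(k-1)/(B+1).  The widest
    rejection set whose estimated FDR is at most alpha is selected; the
    proportion of true nulls pi0 is re-estimated from the rejected set
    (Storey-style) and the selection iterated to a fixed point in the
    rejected-set size.
    """
    t_obs, null, pooled = _pooled_t_functions(g1, g2, cfg)
    k_tot = pooled.shape[0]
    p = t_obs.size
    grid = g1.grid
    cnt_le = (pooled <= t_obs).sum(axis=0)
    cnt_ge = (pooled >= t_obs).sum(axis=0)
    c = np.minimum(cnt_le, cnt_ge)  # observed exits E_k at t iff c(t) <= k-1
    k_max = max(1, k_tot // 2)
    ks = np.arange(1, k_max + 1)
    R = np.array([(c <= k - 1).sum() for k in ks])
    exit_prob = 2.0 * (ks - 1) / k_tot

    def select_k(pi0: float) -> int:
        vhat = pi0 * p * exit_prob
        ok = vhat <= cfg.alpha * np.maximum(R, 1)
        return int(ks[np.nonzero(ok)[0][-1]])

    pi0 = 1.0
    k_star = select_k(pi0)
    n_rej = int((c <= k_star - 1).sum())
    converged = False
    iterations = 1
    for _ in range(cfg.max_iter - 1):
        pi0 = (p - n_rej) / p
        k_new = select_k(pi0)
        n_new = int((c <= k_new - 1).sum())
        iterations += 1
        if n_new == n_rej:
            k_star, n_rej, converged = k_new, n_new, True
            break
        k_star, n_rej = k_new, n_new
    if not converged and cfg.max_iter > 1:
        warnings.warn(
            "iatse envelope did not reach a fixed point; returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    sorted_pooled = np.sort(pooled, axis=0)
    low = sorted_pooled[k_star - 1]
    up = sorted_pooled[k_tot - k_star]
    mask = c <= k_star - 1
    return TestResult(
        method="iatse",
        rejected=bool(mask.any()),
        rejection_set=mask_to_intervals(grid, mask),
        alpha=cfg.alpha,
        envelope=(Curve(grid, low), Curve(grid, up)),
        extras={
            "scheme": null.scheme,
            "k": k_star,
            "pi0": pi0,
            "iterations": iterations,
            "converged": converged or cfg.max_iter == 1,
        },
    )


METHODS = {
    "spm": spm_test,
    "fmax": fmax_test,
    "iwt": iwt_test,
    "twt": twt_test,
    "erl": erl_test,
    "iatse": iatse_test,
}


def run_test(
    method: str,
    g1: FunctionalSample,
    g2: FunctionalSample,
    cfg: TestConfig = TestConfig(),
) -> TestResult:
    """Dispatch to one of the six local tests by name."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ParameterError(
            f"unknown method {method!r}; expected one of {sorted(METHODS)}"
        ) from None
    return fn(g1, g2, cfg)
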