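"""Monte-Carlo omnibus power, per-group sample-size search and FWER.

Omnibus power is the probability that a method rejects the local null at
least once anywhere in the domain when the data come from an alternative
(unequal mean functions).  It is estimated by simulating two-group samples,
running the chosen test, and counting omnibus rejections; a Clopper-Pearson
binomial interval quantifies the Monte-Carlo uncertainty.

The per-group sample size for a target power (default 0.80) is the smallest
n whose power confidence interval contains the target.  If the power jumps
over the target between consecutive n (the interval lower bound exceeds the
target before any interval contains it), that overshooting n is returned and
flagged.  Searches are capped at ``n_max``; a study where no n qualifies by
the cap is reported censored.

Reproducibility: every replicate draws its data and permutation streams from
seeds derived deterministically from the study root seed and the replicate's
(n, index) coordinates, so results are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .curves_io import MeanFunctionPair
from .exceptions import DegenerateDataError, ParameterError
from .local_tests import METHODS, TestConfig
from .noise_signal import NoiseSpec, simulate_two_sample

__all__ = [
    "StudyConfig",
    "PowerEstimate",
    "SampleSizeResult",
    "FwerEstimate",
    "binomial_ci",
    "estimate_power",
    "find_sample_size",
    "estimate_fwer",
]


@dataclass(frozen=True)
class StudyConfig:
    """One simulation study: mean pair, noise model, method and budgets."""

    pair: MeanFunctionPair
    noise: NoiseSpec
    method: str
    test_cfg: TestConfig = TestConfig()
    reps: int = 2500
    ci_level: float = 0.95
    target_power: float = 0.80
    n_min: int = 2
    n_max: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ParameterError(
                f"unknown method {self.method!r}; expected one of {sorted(METHODS)}"
            )
        if not 0 < self.target_power < 1:
            raise ParameterError("target_power must be in (0,1)")
        if self.n_min < 2:
            raise ParameterError("n_min must be >= 2")
        if self.n_max < self.n_min:
            raise ParameterError("n_max must be >= n_min")
        if self.reps < 1:
            raise ParameterError("reps must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ParameterError("ci_level must be in (0,1)")


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection proportion with a binomial confidence interval."""

    p_hat: float
    successes: int
    reps: int
    ci: tuple

    def contains_target(self, target: float) -> bool:
        return self.ci[0] <= target <= self.ci[1]


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of the per-group sample-size search."""

    n: int | None
    censored: bool
    overshoot: bool
    power_at_n: PowerEstimate | None
    trace: tuple  # ((n, PowerEstimate), ...) in scan order

    def n_label(self, n_max: int) -> str:
        """Serialised size; censored results are reported as '>cap'."""
        return f">{n_max}" if self.censored else str(self.n)


@dataclass(frozen=True)
class FwerEstimate:
    """Empirical family-wise error rate under the identical-means null."""

    fwer_hat: float
    successes: int
    reps: int
    ci: tuple


def binomial_ci(successes: int, reps: int, level: float = 0.95) -> tuple:
    """Exact Clopper-Pearson interval from beta quantiles, clamped to [0,1]."""
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    if not 0 <= successes <= reps:
        raise ParameterError(f"successes must be in [0, {reps}], got {successes}")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0,1)")
    tail = (1.0 - level) / 2.0
    low = 0.0 if successes == 0 else float(stats.beta.ppf(tail, successes, reps - successes + 1))
    high = (
        1.0
        if successes == reps
        else float(stats.beta.ppf(1.0 - tail, successes + 1, reps - successes))
    )
    return (max(0.0, low), min(1.0, high))


def _replicate_seeds(root_seed: int, n: int, rep: int) -> tuple:
    """Deterministic, order-insensitive per-replicate seed pair.

    The spawn key encodes the candidate sample size and the replicate index,
    so every (study, n, replicate) cell has its own independent stream no
    matter how the replicates are scheduled.
    """
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(n, rep))
    return tuple(ss.spawn(2))


def _run_replicates(cfg: StudyConfig, n: int, pair: MeanFunctionPair, reps: int) -> int:
    test_fn = METHODS[cfg.method]
    successes = 0
    for rep in range(reps):
        data_seed, perm_seed = _replicate_seeds(cfg.seed, n, rep)
        g1, g2 = simulate_two_sample(pair, cfg.noise, n, seed=data_seed)
        try:
            result = test_fn(g1, g2, replace(cfg.test_cfg, seed=perm_seed))
        except DegenerateDataError as exc:
            raise DegenerateDataError(
                f"replicate {rep} (n={n}, method={cfg.method}): {exc}"
            ) from exc
        successes += int(result.rejected)
    return successes


def estimate_power(cfg: StudyConfig, n: int, *, null: bool = False) -> PowerEstimate:
    """Monte-Carlo omnibus power at per-group size n under cfg's mean pair.

    With ``null=True`` both groups use mu1 (pure-noise difference), turning
    the estimate into an empirical FWER.
    """
    if n < 2:
        raise ParameterError("per-group n must be >= 2")
    pair = cfg.pair.as_null() if null else cfg.pair
    successes = _run_replicates(cfg, n, pair, cfg.reps)
    return PowerEstimate(
        p_hat=successes / cfg.reps,
        successes=successes,
        reps=cfg.reps,
        ci=binomial_ci(successes, cfg.reps, cfg.ci_level),
    )


def _classify(est: PowerEstimate, target: float) -> str:
    if est.ci[1] < target:
        return "below"
    if est.ci[0] > target:
        return "above"
    return "contains"


def find_sample_size(cfg: StudyConfig, strategy: str = "linear") -> SampleSizeResult:
    """Smallest per-group n whose power CI contains the target power.

    The default linear scan evaluates n = n_min, n_min+1, ... with fresh
    replicates per candidate and stops at the first n whose CI contains the
    target, or — if the CI lower bound exceeds the target before any CI
    contains it — returns that overshooting n flagged.  If neither occurs by
    n_max the result is censored.

    ``strategy="bisect"`` is an accelerator that binary-searches for the
    smallest n whose CI is not entirely below the target; because candidate
    estimates are seeded per (n, replicate) it reproduces the linear-scan
    answer whenever the estimated power is monotone in n.
    """
    if strategy not in ("linear", "bisect"):
        raise ParameterError(f"unknown search strategy {strategy!r}")
    cache: dict[int, PowerEstimate] = {}

    def power_at(n: int) -> PowerEstimate:
        if n not in cache:
            cache[n] = estimate_power(cfg, n)
        return cache[n]

    def finish(n: int | None, censored: bool, overshoot: bool) -> SampleSizeResult:
        trace = tuple(sorted(cache.items()))
        return SampleSizeResult(
            n=n,
            censored=censored,
            overshoot=overshoot,
            power_at_n=None if n is None else cache[n],
            trace=trace,
        )

    if strategy == "linear":
        for n in range(cfg.n_min, cfg.n_max + 1):
            kind = _classify(power_at(n), cfg.target_power)
            if kind == "contains":
                return finish(n, False, False)
            if kind == "above":
                return finish(n, False, True)
        return finish(None, True, False)

    # bisect: smallest n with CI not entirely below the target
    lo, hi = cfg.n_min, cfg.n_max
    if _classify(power_at(hi), cfg.target_power) == "below":
        return finish(None, True, False)
    while lo < hi:
        mid = (lo + hi) // 2
        if _classify(power_at(mid), cfg.target_power) == "below":
            lo = mid + 1
        else:
            hi = mid
    kind = _classify(power_at(lo), cfg.target_power)
    return finish(lo, False, kind == "above")


def estimate_fwer(cfg: StudyConfig, n: int) -> FwerEstimate:
    """Empirical FWER: rejection rate under the identical-means null at n."""
    est = estimate_power(cfg, n, null=True)
    return FwerEstimate(
        fwer_hat=est.p_hat, successes=est.successes, reps=est.reps, ci=est.ci
    )
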