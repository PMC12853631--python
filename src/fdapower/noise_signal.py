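"""Stationary smoothed Gaussian noise, Gaussian-pulse signals and two-group
sampling.

The simulation model for an individual curve in group ``i`` is

    y_iq(t) = mu_i(t) + eps_iq(t),      t in D,

where the noise eps_iq is a stationary Gaussian process with pointwise
standard deviation ``sd`` at every t and smoothness parameterised by the
full-width-at-half-maximum (FWHM) of the Gaussian kernel used to smooth
white noise, FWHM = 2*sigma*sqrt(2 ln 2).

Construction: draw iid N(0,1) deviates on a grid extended past each boundary
by the kernel half-support, convolve with a truncated (±4 sigma, renormalised)
Gaussian kernel, crop back to the domain, and rescale by 1/sqrt(sum w_k^2) so
the pointwise variance is exactly restored after smoothing.  Because every
domain point then sees a full kernel's worth of white noise, the process is
stationary all the way to the boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .curves_io import Curve, DomainGrid, MeanFunctionPair
from .exceptions import ParameterError

__all__ = [
    "FWHM_TO_SIGMA",
    "NoiseSpec",
    "SignalPulse",
    "FunctionalSample",
    "sigma_from_fwhm",
    "fwhm_from_sigma",
    "gaussian_kernel",
    "generate_noise",
    "gaussian_pulse",
    "stance_template",
    "make_fixture_pair",
    "simulate_two_sample",
]

#: FWHM = 2 * sqrt(2 ln 2) * sigma for a Gaussian kernel.
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Kernel truncation half-width in units of sigma (< 1e-4 mass loss).
KERNEL_SUPPORT_SIGMAS = 4.0


def sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian-kernel SD corresponding to a full width at half maximum."""
    if fwhm < 0:
        raise ParameterError(f"fwhm must be >= 0, got {fwhm}")
    return fwhm / FWHM_TO_SIGMA


def fwhm_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_fwhm`."""
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    return sigma * FWHM_TO_SIGMA


@dataclass(frozen=True)
class NoiseSpec:
    """Stationary noise model: pointwise SD and smoothness FWHM.

    Parameters
    ----------
    sd
        Pointwise standard deviation in response units; the marginal law of
        the noise at every grid point is N(0, sd^2).
    fwhm
        Smoothness in domain units; 0 means iid (unsmoothed) noise.
    """

    sd: float
    fwhm: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ParameterError(f"noise sd must be > 0, got {self.sd}")
        if self.fwhm < 0:
            raise ParameterError(f"noise fwhm must be >= 0, got {self.fwhm}")

    @property
    def kernel_sigma(self) -> float:
        """Gaussian smoothing-kernel SD in domain units."""
        return sigma_from_fwhm(self.fwhm)


@dataclass(frozen=True)
class SignalPulse:
    """A Gaussian pulse: peak ``amplitude`` at ``centre``, half the amplitude
    at ``centre +- fwhm/2``."""

    centre: float
    amplitude: float
    fwhm: float

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ParameterError(f"signal fwhm must be > 0, got {self.fwhm}")


@dataclass(frozen=True)
class FunctionalSample:
    """n curves observed on a shared grid, one group's worth of data."""

    grid: DomainGrid
    values: np.ndarray  # shape (n, grid.length)
    group_label: str = "group"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != self.grid.length:
            raise ParameterError(
                f"values must have shape (n, {self.grid.length}), got {vals.shape}"
            )
        if vals.shape[0] < 1:
            raise ParameterError("a sample needs at least one curve")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("sample values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.shape[0])

    def curves(self) -> list[Curve]:
        return [Curve(self.grid, row) for row in self.values]


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def gaussian_kernel(sigma_points: float) -> np.ndarray:
    """Discrete Gaussian weights on integer offsets, truncated at ±4 sigma and
    renormalised to sum to 1."""
    half = int(math.ceil(KERNEL_SUPPORT_SIGMAS * sigma_points))
    offsets = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (offsets / sigma_points) ** 2)
    return w / w.sum()


def _check_fwhm_for_grid(fwhm: float, grid: DomainGrid) -> None:
    if grid.length > 1 and fwhm > grid.span / 2.0:
        raise ParameterError(
            f"noise fwhm {fwhm} exceeds half the domain span "
            f"({grid.span / 2.0}); smoothing would exceed the domain"
        )


def generate_noise(
    n: int, grid: DomainGrid, spec: NoiseSpec, seed=None, group_label: str = "noise"
) -> FunctionalSample:
    """Draw ``n`` stationary smoothed Gaussian noise curves on ``grid``.

    Every grid point has marginal distribution N(0, spec.sd^2); the
    autocorrelation is Gaussian with scale set by ``spec.kernel_sigma``.
    Identical seeds give identical output.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    _check_fwhm_for_grid(spec.fwhm, grid)
    rng = np.random.default_rng(_as_seed_sequence(seed))
    p = grid.length
    sigma = spec.kernel_sigma
    if sigma == 0 or p == 1:
        values = spec.sd * rng.standard_normal((n, p))
        return FunctionalSample(grid, values, group_label)
    sigma_pts = sigma / grid.spacing
    kernel = gaussian_kernel(sigma_pts)
    pad = (kernel.size - 1) // 2
    white = rng.standard_normal((n, p + 2 * pad))
    smooth = convolve1d(white, kernel, axis=1, mode="constant", cval=0.0)
    smooth = smooth[:, pad : pad + p]
    # restore unit pointwise variance, then scale to the requested SD
    values = smooth * (spec.sd / math.sqrt(float(np.sum(kernel**2))))
    return FunctionalSample(grid, values, group_label)


def gaussian_pulse(grid: DomainGrid, pulse: SignalPulse) -> Curve:
    """Evaluate a Gaussian pulse on the grid."""
    sigma = sigma_from_fwhm(pulse.fwhm)
    z = (grid.points - pulse.centre) / sigma
    return Curve(grid, pulse.amplitude * np.exp(-0.5 * z**2))


# -- bundled fixture mean pairs ------------------------------------------------

# mu1 template: two fixed Gaussian bumps giving a smooth double-peaked curve
# reminiscent of a stance-phase loading pattern (a synthetic stand-in, not the
# published force or moment data).
_TEMPLATE_BUMPS = (
    SignalPulse(centre=30.0, amplitude=1.6, fwhm=40.0),
    SignalPulse(centre=72.0, amplitude=1.5, fwhm=36.0),
)

#: Default pulses producing the two canonical difference patterns: a narrow
#: high pulse confined to a small part of the domain ("localized") versus a
#: broad low pulse covering most of it ("widespread").
FIXTURE_PULSES = {
    "localized": SignalPulse(centre=75.0, amplitude=1.0, fwhm=10.0),
    "widespread": SignalPulse(centre=50.0, amplitude=1.0, fwhm=60.0),
}


def stance_template(grid: DomainGrid | None = None) -> Curve:
    """The fixed double-peaked baseline mean curve used by the fixtures."""
    grid = grid if grid is not None else DomainGrid()
    values = np.zeros(grid.length)
    for bump in _TEMPLATE_BUMPS:
        values = values + gaussian_pulse(grid, bump).values
    return Curve(grid, values)


def make_fixture_pair(
    pattern: str,
    grid: DomainGrid | None = None,
    *,
    amplitude: float | None = None,
    centre: float | None = None,
    signal_fwhm: float | None = None,
) -> MeanFunctionPair:
    """Build a synthetic mean pair with a localized or widespread difference.

    ``mu1`` is the fixed stance-like template; ``mu2 = mu1 + pulse`` where the
    pulse defaults depend on the pattern (narrow for ``localized``, broad for
    ``widespread``).  ``amplitude=0`` yields the identical-means null pair.
    """
    if pattern not in FIXTURE_PULSES:
        raise ParameterError(
            f"unknown pattern {pattern!r}; expected one of {sorted(FIXTURE_PULSES)}"
        )
    grid = grid if grid is not None else DomainGrid()
    default = FIXTURE_PULSES[pattern]
    pulse = SignalPulse(
        centre=default.centre if centre is None else centre,
        amplitude=default.amplitude if amplitude is None else amplitude,
        fwhm=default.fwhm if signal_fwhm is None else signal_fwhm,
    )
    mu1 = stance_template(grid)
    if pulse.amplitude == 0:
        return MeanFunctionPair(mu1, mu1)
    mu2 = mu1 + gaussian_pulse(grid, pulse)
    return MeanFunctionPair(mu1, mu2)


def simulate_two_sample(
    pair: MeanFunctionPair, spec: NoiseSpec, n: int, seed=None
) -> tuple[FunctionalSample, FunctionalSample]:
    """Simulate equal-size two-group samples y_iq = mu_i + eps_iq.

    The two groups share the noise spec but use independent noise streams
    derived from the same seed; n is the per-group size.
    """
    if n < 2:
        raise ParameterError(f"per-group n must be >= 2, got {n}")
    ss = _as_seed_sequence(seed)
    child1, child2 = ss.spawn(2)
    eps1 = generate_noise(n, pair.grid, spec, seed=child1)
    eps2 = generate_noise(n, pair.grid, spec, seed=child2)
    g1 = FunctionalSample(pair.grid, pair.mu1.values + eps1.values, "group1")
    g2 = FunctionalSample(pair.grid, pair.mu2.values + eps2.values, "group2")
    return g1, g2
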