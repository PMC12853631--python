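# Methods

## The problem

Medical and biomechanical studies increasingly analyse *functional data* —
curves such as vertical ground reaction forces (vGRF) or knee joint moments
(KJM) observed over a normalised time axis (percent of the stance phase,
`D = [0, 100]`).  Local two-sample hypothesis tests ask *where* in the
domain two population mean functions differ:

    H0: mu1(t) = mu2(t)  for all t in T ⊆ D
    H1: mu1(t) ≠ mu2(t)  for some t in T.

A priori sample-size planning for such tests is rarely done with functional
methods, even though scalar power formulas can badly underestimate the
required group sizes.  This package estimates, by Monte-Carlo simulation,
the per-group sample size needed for a target *omnibus power* — the
probability of rejecting the null at least once anywhere in the domain —
and the family-wise error rate (FWER) attained under the null, for six
widely used local inferential methods.

## Data-generating model

Individual curves are simulated as

    y_iq(t) = mu_i(t) + eps_iq(t),   i = 1, 2,  q = 1..n,

on a 101-point equally spaced grid over [0, 100].  The noise `eps` is a
stationary Gaussian process with

- **Noise SD** — the pointwise standard deviation; the marginal law at every
  grid point is `N(0, SD^2)`;
- **Noise FWHM** — the smoothness, expressed as the full width at half
  maximum of the Gaussian kernel used to smooth white noise,
  `FWHM = 2 * sigma * sqrt(2 ln 2)`.

Construction: iid `N(0,1)` deviates are drawn on a grid extended beyond each
boundary by the kernel half-support (4 sigma), convolved with the truncated,
renormalised Gaussian kernel, cropped to the domain, and rescaled by
`1 / sqrt(sum w_k^2)` so the pointwise variance is restored *exactly* after
smoothing.  Because every retained point sees a full kernel's worth of white
noise, the process is stationary up to the boundaries (no edge variance
dip).  `FWHM = 0` bypasses the convolution (iid noise).  On the [0, 100]
domain the FWHM is capped at 50 — half the span — since wider kernels exceed
what the domain can support.

This generator reproduces two properties that the tests verify: empirical
pointwise SD within 2% of nominal at every grid point (checked with 40000
curves so the Monte-Carlo standard error is small against the 2% band), and
nominal FWHM recovered within 10% by the gradient-variance estimator at
n = 10000.  What
it deliberately does **not** emulate: non-stationary (heteroscedastic)
noise, non-Gaussian marginals, between-group correlation, and unbalanced
designs.  Passing tests therefore speak to the stationary-Gaussian regime
only; real gait data may deviate from all of these.

## Bundled mean-function fixtures

Reproducing published per-dataset sample sizes requires the original vGRF
and KJM group mean curves, which users can supply as CSV (`t, mu1, mu2`).
For self-contained builds the package bundles a synthetic baseline: `mu1` is
a fixed sum of two Gaussian bumps (centres 30 and 72, amplitudes 1.6 and
1.5, FWHMs 40 and 36) giving a smooth double-peaked stance-like template —
a synthetic stand-in, not the published data.  `mu2 = mu1 + pulse`, with two
canonical difference patterns:

- **localized** — a narrow pulse (amplitude 1.0, FWHM 10, centre 75):
  a substantial difference confined to a small part of the domain;
- **widespread** — a broad low pulse (amplitude 1.0, FWHM 60, centre 50):
  a difference spread over most of the domain.

The pulse amplitudes were chosen once so that, at the moderate noise levels
used in the studies (SD 0.5 for the localized pattern, SD 1.0 for the
widespread one), the required per-group sizes fall well inside the
searchable range (roughly 7–25) — comparable in effect size to the
published baselines — and were not revisited afterwards.

## The six local tests

All methods share one statistic family: the pointwise pooled two-sample
t statistic, squared to `F = t^2` where a nonnegative statistic is needed.
Permutation nulls shuffle group labels of the pooled curves; when the number
of distinct assignments is at most B the full assignment space is enumerated
(exact p-values, identity included, `p = count/total`); otherwise B random
assignments are drawn with replacement and the add-one convention
`p = (1 + count)/(B + 1)` guarantees validity and `p > 0`.

- **SPM** — parametric random-field theory on the `|t|` field.  Residual
  smoothness is estimated by the gradient-variance estimator
  (`FWHM_hat = sqrt(4 ln 2 / mean gradient variance of the pointwise
  normalised residuals)`), the resel count is `span / FWHM_hat`, and the
  domain-wide threshold `u*` solves `2 (P(T > u) + resels * rho1(u)) =
  alpha`, with `rho1` the 1D Euler-characteristic density of the t field
  with `n1 + n2 - 2` degrees of freedom.  With 0 resels (single-point
  domain) this is exactly the two-sided pooled t test.
- **F-max** — permutation distribution of the domain-wide maximum F; the
  adjusted p-value at t compares `F(t)` with the permuted maxima.
- **IWT** — permutation tests of the *summed* F statistic on every
  contiguous grid interval (including single points; no wrap-around, since
  the stance phase is not periodic); adjusted p at t is the maximum interval
  p-value over all intervals containing t.
- **TWT** — the unadjusted pointwise permutation p-value function is
  thresholded at each of its sorted unique values; each (possibly
  disconnected) level set is tested with the summed-F permutation test, and
  the adjusted p at t is the maximum subset p-value over level sets
  containing t, floored at the point's own unadjusted p-value (the
  degenerate finest subset) so adjusted never falls below unadjusted.
- **ERL** — global envelope test: observed and permuted t functions are
  pooled; each function's two-sided pointwise extreme ranks, sorted
  increasingly, give its extreme-rank-length measure; functions are ordered
  lexicographically (ties count as equally extreme).  The level-alpha
  envelope is the pointwise min/max of the `ceil((1 - alpha)(B + 1))` most
  central functions — when the cut falls inside a tie group the whole group
  is kept central, which can only widen the envelope.  Rejection wherever
  the observed function exits strictly.
- **IATSE** — FDR-controlling iterative adaptive two-stage envelope.  For
  width index k the envelope spans the k-th smallest to k-th largest pooled
  value pointwise; a true-null point exits with probability
  `2(k - 1)/(B + 1)` under exchangeability, so the estimated false
  rejections are `pi0 * p * 2(k - 1)/(B + 1)`.  The largest k whose
  estimated FDR (estimate / max(#rejections, 1)) is at most alpha is
  selected; `pi0` (the proportion of true-null points) starts at 1, is
  re-estimated Storey-style as `(p - #rejected)/p`, and the selection
  iterates to a fixed point in the rejected-set size (cap 20 iterations,
  warning on non-convergence).  Under a complete null this makes IATSE
  conservative in the FWER sense, consistent with its FDR target.

Every method returns the same result shape: an omnibus decision, the
rejection subset as closed position intervals in domain units, and (where
defined) an adjusted p-value function or envelope.  The invariant
`rejected ⇔ rejection set nonempty ⇔ min adjusted p ≤ alpha` is enforced
and tested.

## Power, sample size, FWER

`estimate_power` runs R simulation replicates (default 2500), counts
omnibus rejections and attaches an exact Clopper–Pearson interval (the
"binomial CI"; exact intervals are conservative and deterministic, which
matters when the search criterion reads CI endpoints).  `find_sample_size`
scans n = 2, 3, … and returns the smallest n whose CI contains the target
power (default 0.80).  Two boundary rules are deliberate choices:

- if the CI jumps past the target (lower bound above 0.80 before any CI
  contains it), that overshooting n is returned with an `overshoot` flag;
- if nothing qualifies by the cap (default 60), the result is censored and
  serialised as ">cap".

An optional bisection accelerator finds the same n as the linear scan
whenever estimated power is monotone in n; candidate estimates are seeded
per (n, replicate), so shared candidates are identical between strategies.
`estimate_fwer` reruns the machinery with both groups drawn around `mu1`.

Reproducibility: each replicate derives its data and permutation streams
from `SeedSequence(root_seed, spawn_key=(n, replicate))`, making results
independent of execution order and byte-stable for a fixed study
configuration.

## Numerical choices

- Kernel truncation at ±4 sigma (mass loss < 1e-4), renormalised before the
  variance-restoration factor is computed.
- Exceedance comparisons against the observed statistic use a relative
  tolerance of 1e-9 so that permutations equal to the observed labelling in
  exact arithmetic (the identity assignment in exhaustive mode) count as
  ties regardless of floating-point evaluation order.
- Zero pooled variance at any grid point raises an error rather than being
  regularised — in this simulation setting it signals an upstream bug.
- Interval/subset statistics use plain sums of F over grid points
  (equivalent to Riemann integration on the uniform grid up to a constant
  that cancels in permutation comparisons).
- The CSV dialect is comma-separated UTF-8 with a header; floats are
  written at shortest round-trip precision and read back with round-trip
  parsing, so write–read is the identity.

## Study sizes used by the shipped checks

The automated checks scale the Monte-Carlo budgets to desk size as their
own design choice: null calibration uses 1000–2500 replicates with 1000
permutations; the sample-size trend studies use 500 replicates, 500
permutations, a cap of 40 and the bisection accelerator.  Full-size studies
(2500 replicates, 1000 permutations, cap 60, linear scan) are the library
defaults.

## Known limitations

- Balanced designs only; unbalanced groups, paired designs and more than
  two groups are out of scope.
- Omnibus power only; centre/region-of-interest power is not computed.
- Stationary Gaussian noise only; no FPCA-based pilot-data simulation.
- The IATSE iteration details follow the published two-stage adaptive FDR
  envelope construction in structure; its exact tuning constants are not
  printed in the primary sources, so the analytic-exit-probability variant
  implemented here is a documented design choice.
- The exact boundary handling and variance restoration of the smoothing
  step are conventions of the SPM power literature; published figures may
  be sensitive to that choice.
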