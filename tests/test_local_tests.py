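"""Unit and oracle tests for the six local inferential methods.

The small-sample permutation oracles enumerate all 70 assignments of 8
curves to two groups of 4 by brute force, independently of the package's
vectorised permutation engine.
"""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from fdapower import (
    DegenerateDataError,
    DomainGrid,
    FunctionalSample,
    NoiseSpec,
    ParameterError,
    TestConfig,
    erl_test,
    estimate_fwhm,
    fmax_test,
    generate_noise,
    iatse_test,
    iwt_test,
    make_fixture_pair,
    permutation_null,
    pointwise_stat,
    run_test,
    simulate_two_sample,
    spm_test,
    twt_test,
)
from fdapower.local_tests import METHODS, _perm_pvalue, mask_to_intervals

from conftest import make_sample


def scalar_pooled_t(x1, x2):
    """Textbook pooled two-sample t for scalars, via plain Python."""
    n1, n2 = len(x1), len(x2)
    m1, m2 = sum(x1) / n1, sum(x2) / n2
    ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
    sp = math.sqrt(ss / (n1 + n2 - 2))
    return (m1 - m2) / (sp * math.sqrt(1 / n1 + 1 / n2))


def brute_force_scalar_perm_p(x1, x2):
    """Exact permutation p-value of F = t^2 over all C(8,4) assignments."""
    pool = list(x1) + list(x2)
    f_obs = scalar_pooled_t(x1, x2) ** 2
    count = total = 0
    for idx in combinations(range(len(pool)), len(x1)):
        a = [pool[i] for i in idx]
        b = [pool[i] for i in range(len(pool)) if i not in idx]
        total += 1
        if scalar_pooled_t(a, b) ** 2 >= f_obs - 1e-12:
            count += 1
    return count / total


class TestPointwiseStat:
    def test_identical_groups_give_zero(self, grid101):
        vals = np.random.default_rng(0).normal(size=(4, 101))
        g = make_sample(grid101, vals)
        assert np.allclose(pointwise_stat(g, g, "t").values, 0.0)
        assert np.allclose(pointwise_stat(g, g, "F").values, 0.0)

    def test_label_swap_antisymmetry(self, grid101):
        rng = np.random.default_rng(1)
        g1 = make_sample(grid101, rng.normal(size=(5, 101)))
        g2 = make_sample(grid101, rng.normal(size=(7, 101)))
        t12 = pointwise_stat(g1, g2, "t").values
        t21 = pointwise_stat(g2, g1, "t").values
        assert np.allclose(t12, -t21)
        assert np.allclose(
            pointwise_stat(g1, g2, "F").values, pointwise_stat(g2, g1, "F").values
        )

    def test_f_is_t_squared(self, grid101):
        rng = np.random.default_rng(2)
        g1 = make_sample(grid101, rng.normal(size=(6, 101)))
        g2 = make_sample(grid101, 0.3 + rng.normal(size=(6, 101)))
        t = pointwise_stat(g1, g2, "t").values
        assert np.allclose(pointwise_stat(g1, g2, "F").values, t**2)

    def test_matches_scalar_oracle(self, tiny_point_samples):
        g1, g2 = tiny_point_samples
        t = pointwise_stat(g1, g2, "t").values[0]
        assert t == pytest.approx(
            scalar_pooled_t([1.1, 0.9, 1.0, 1.2], [0.1, -0.1, 0.2, -0.2])
        )
        # cross-check against an independent implementation
        ref = stats.ttest_ind(g1.values[:, 0], g2.values[:, 0], equal_var=True)
        assert t == pytest.approx(ref.statistic)

    def test_matches_ttest_ind_along_grid(self, grid101):
        rng = np.random.default_rng(3)
        g1 = make_sample(grid101, rng.normal(size=(8, 101)))
        g2 = make_sample(grid101, rng.normal(size=(5, 101)))
        t = pointwise_stat(g1, g2, "t").values
        ref = stats.ttest_ind(g1.values, g2.values, axis=0, equal_var=True).statistic
        assert np.allclose(t, ref)

    def test_zero_pooled_variance_is_degenerate(self, point_grid):
        g1 = make_sample(point_grid, [[1.0], [1.0]])
        g2 = make_sample(point_grid, [[0.0], [0.0]])
        with pytest.raises(DegenerateDataError):
            pointwise_stat(g1, g2)


class TestPermutationEngine:
    def test_exhaustive_mode_enumerates_all_assignments(self, tiny_point_samples):
        g1, g2 = tiny_point_samples
        null = permutation_null(g1, g2, "F", B=100, seed=0)
        assert null.exhaustive and null.n_perm == 70

    def test_same_seed_reproduces(self, grid101):
        rng = np.random.default_rng(4)
        g1 = make_sample(grid101, rng.normal(size=(10, 101)))
        g2 = make_sample(grid101, rng.normal(size=(10, 101)))
        a = permutation_null(g1, g2, "F", B=50, seed=7)
        b = permutation_null(g1, g2, "F", B=50, seed=7)
        assert np.array_equal(a.stats, b.stats)

    def test_observed_max_rank_uniform_under_null(self, grid101):
        """Under exchangeability the observed maximum's rank among the
        permuted maxima is uniform; check the rejection rate it implies."""
        rejections = 0
        n_mc = 400
        for i in range(n_mc):
            noise = generate_noise(8, grid101, NoiseSpec(1.0, 20.0), seed=1000 + i)
            g1 = make_sample(grid101, noise.values[:4])
            g2 = make_sample(grid101, noise.values[4:])
            null = permutation_null(g1, g2, "F", B=99, seed=i)
            m_obs = pointwise_stat(g1, g2, "F").values.max()
            p = _perm_pvalue((null.stats.max(axis=1) >= m_obs).sum(), null)
            rejections += p <= 0.2
        se = math.sqrt(0.2 * 0.8 / n_mc)
        assert abs(rejections / n_mc - 0.2) < 3 * se


class TestExhaustiveOracles:
    """On a single-point domain the permutation methods must reproduce the
    brute-force enumeration over all 70 label assignments exactly."""

    x1 = [1.1, 0.9, 1.0, 1.2]
    x2 = [0.4, -0.1, 0.8, -0.2]

    @pytest.fixture
    def samples(self, point_grid):
        g1 = make_sample(point_grid, [[v] for v in self.x1])
        g2 = make_sample(point_grid, [[v] for v in self.x2])
        return g1, g2

    @pytest.mark.parametrize("test_fn", [fmax_test, iwt_test, twt_test])
    def test_p_equals_brute_force(self, samples, test_fn):
        g1, g2 = samples
        expected = brute_force_scalar_perm_p(self.x1, self.x2)
        result = test_fn(g1, g2, TestConfig(n_perm=100, seed=0))
        assert result.pvalue == pytest.approx(expected, abs=1e-12)

    def test_identical_sets_give_p_one(self, point_grid):
        g = make_sample(point_grid, [[v] for v in self.x1])
        result = fmax_test(g, g, TestConfig(n_perm=100, seed=0))
        assert result.pvalue == 1.0 and not result.rejected


class TestSpm:
    def test_single_point_reduces_to_t_test(self, tiny_point_samples):
        g1, g2 = tiny_point_samples
        result = spm_test(g1, g2)
        ref = stats.ttest_ind(g1.values[:, 0], g2.values[:, 0], equal_var=True)
        assert result.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_overwhelming_effect_rejected_in_pulse_region(self, grid101):
        pair = make_fixture_pair("localized", grid101, amplitude=50.0)
        g1, g2 = simulate_two_sample(pair, NoiseSpec(0.5, 20.0), 10, seed=1)
        result = spm_test(g1, g2)
        assert result.rejected
        assert any(lo <= 75.0 <= hi for lo, hi in result.rejection_set)

    def test_constant_residuals_degenerate(self, grid101):
        g1 = make_sample(grid101, np.tile([1.0, 2.0], (101, 1)).T)
        with pytest.raises(DegenerateDataError):
            spm_test(g1, g1)


class TestEstimateFwhm:
    def test_recovers_nominal_smoothness(self, grid101):
        sample = generate_noise(3000, grid101, NoiseSpec(1.0, 30.0), seed=11)
        assert estimate_fwhm(sample) == pytest.approx(30.0, rel=0.1)

    def test_scale_invariant(self, grid101):
        sample = generate_noise(50, grid101, NoiseSpec(1.0, 20.0), seed=12)
        a = estimate_fwhm(sample.values, grid101)
        b = estimate_fwhm(17.3 * sample.values, grid101)
        assert a == pytest.approx(b, rel=1e-12)

    def test_iid_noise_rougher_than_smoothed(self, grid101):
        iid = generate_noise(2000, grid101, NoiseSpec(1.0, 0.0), seed=13)
        smooth = generate_noise(2000, grid101, NoiseSpec(1.0, 10.0), seed=14)
        assert estimate_fwhm(iid) < estimate_fwhm(smooth)


class TestAdjustedPvalueDominance:
    """Max-aggregated adjusted p-value functions dominate the unadjusted
    pointwise permutation p-values everywhere."""

    @pytest.fixture
    def samples(self, grid101):
        pair = make_fixture_pair("localized", grid101, amplitude=0.7)
        return simulate_two_sample(pair, NoiseSpec(0.5, 20.0), 8, seed=21)

    @pytest.fixture
    def unadjusted(self, samples):
        g1, g2 = samples
        null = permutation_null(g1, g2, "F", B=200, seed=5)
        f_obs = pointwise_stat(g1, g2, "F").values
        return _perm_pvalue((null.stats >= f_obs).sum(axis=0), null)

    @pytest.mark.parametrize("test_fn", [fmax_test, iwt_test, twt_test])
    def test_adjusted_dominates_pointwise(self, samples, unadjusted, test_fn):
        g1, g2 = samples
        result = test_fn(g1, g2, TestConfig(n_perm=200, seed=5))
        assert np.all(result.pvalue_function.values >= unadjusted - 1e-12)


class TestEnvelopes:
    def test_erl_identical_sets_not_rejected(self, grid101):
        vals = np.random.default_rng(30).normal(size=(4, 101))
        g = make_sample(grid101, vals)
        result = erl_test(g, g, TestConfig(n_perm=100, seed=0))
        assert not result.rejected and result.rejection_set == ()

    def test_erl_overwhelming_effect_exits_envelope(self, grid101):
        pair = make_fixture_pair("localized", grid101, amplitude=50.0)
        g1, g2 = simulate_two_sample(pair, NoiseSpec(0.5, 20.0), 10, seed=31)
        result = erl_test(g1, g2, TestConfig(n_perm=200, seed=1))
        assert result.rejected
        assert any(lo <= 75.0 <= hi for lo, hi in result.rejection_set)

    def test_iatse_identical_sets_not_rejected(self, grid101):
        vals = np.random.default_rng(32).normal(size=(4, 101))
        g = make_sample(grid101, vals)
        result = iatse_test(g, g, TestConfig(n_perm=100, seed=0))
        assert not result.rejected

    def test_iatse_overwhelming_widespread_covers_half_maximum_region(self, grid101):
        pair = make_fixture_pair("widespread", grid101, amplitude=80.0)
        g1, g2 = simulate_two_sample(pair, NoiseSpec(1.0, 20.0), 10, seed=33)
        result = iatse_test(g1, g2, TestConfig(n_perm=500, seed=2))
        diff = np.abs(pair.difference.values)
        region = grid101.points[diff > diff.max() / 2]
        rejected_pts = {
            t for t in region for lo, hi in result.rejection_set if lo <= t <= hi
        }
        assert result.rejected
        assert len(rejected_pts) == len(region)


class TestInterfaceLaw:
    """Every method: rejected iff the rejection set is nonempty, and where a
    p-value function exists the rejection set is exactly its alpha level set."""

    @pytest.mark.parametrize("method", sorted(METHODS))
    @pytest.mark.parametrize("seed", [0, 1])
    def test_interface_consistency(self, grid101, method, seed):
        pair = make_fixture_pair("localized", grid101, amplitude=0.9)
        g1, g2 = simulate_two_sample(pair, NoiseSpec(0.5, 30.0), 8, seed=40 + seed)
        cfg = TestConfig(n_perm=200, seed=seed)
        result = run_test(method, g1, g2, cfg)
        assert result.rejected == (len(result.rejection_set) > 0)
        if result.pvalue_function is not None:
            p = result.pvalue_function.values
            assert np.all((p >= 0) & (p <= 1))
            mask = p <= cfg.alpha
            assert mask_to_intervals(grid101, mask) == result.rejection_set
            assert result.rejected == (p.min() <= cfg.alpha)

    def test_within_group_reordering_invariant_in_exhaustive_mode(self, grid101):
        rng = np.random.default_rng(50)
        v1, v2 = rng.normal(size=(4, 101)), rng.normal(size=(4, 101))
        cfg = TestConfig(n_perm=100, seed=3)  # C(8,4)=70 -> exhaustive
        for method in sorted(METHODS):
            r_base = run_test(method, make_sample(grid101, v1), make_sample(grid101, v2), cfg)
            r_perm = run_test(
                method,
                make_sample(grid101, v1[[2, 0, 3, 1]]),
                make_sample(grid101, v2[[1, 3, 0, 2]]),
                cfg,
            )
            assert r_base.rejected == r_perm.rejected
            assert r_base.rejection_set == r_perm.rejection_set
            if r_base.pvalue is not None:
                assert r_base.pvalue == pytest.approx(r_perm.pvalue, abs=1e-12)

    def test_unknown_method_rejected(self, grid101):
        vals = np.random.default_rng(0).normal(size=(3, 101))
        g = make_sample(grid101, vals)
        with pytest.raises(ParameterError):
            run_test("anova", g, g)
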