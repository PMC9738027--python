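"""Core NHPP model: basis, intensity evaluation, likelihood, simulation."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad, simpson

from nhppclust.nhpp import (
    GenomicRegion,
    IntensityFunction,
    SamplePath,
    basis_eval,
    constant_intensity,
    cumulative,
    intensity_at,
    joint_log_likelihood,
    log_likelihood,
    simulate_nhpp,
)
from nhppclust.scenarios import scenario_intensities


def s1_cluster1_rate(t):
    # printed Scenario 1 cluster-1 intensity, used as an independent oracle
    return 3.0 * np.cos(2.0 * np.pi * t / 10.0) + 3.0


class TestBasis:
    def test_cosine_dc_term(self, region):
        assert basis_eval("cosine_dct", 0, 3.7, region) == pytest.approx(1 / np.sqrt(10))

    def test_cosine_first_mode_at_origin(self, region):
        assert basis_eval("cosine_dct", 1, 0.0, region) == pytest.approx(np.sqrt(0.2))

    @pytest.mark.parametrize("i,j", [(1, 2), (0, 3), (2, 4), (2, 2), (0, 0)])
    def test_cosine_orthonormality_by_quadrature(self, region, i, j):
        # composite-Simpson oracle for the L2 inner product on [0, 10]
        t = np.linspace(region.lo, region.hi, 4001)
        prod = basis_eval("cosine_dct", i, t, region) * basis_eval("cosine_dct", j, t, region)
        inner = simpson(prod, x=t)
        assert inner == pytest.approx(1.0 if i == j else 0.0, abs=1e-8)

    def test_unknown_basis_kind_rejected(self, region):
        with pytest.raises(ValueError, match="basis_kind"):
            basis_eval("wavelet", 0, 1.0, region)

    def test_bspline_partition_of_unity(self, region):
        t = np.linspace(0, 10, 57)
        lam = IntensityFunction(np.ones(17), "bspline", region)
        assert np.allclose(lam.raw(t), 1.0)


class TestIntensity:
    def test_constant_basis(self, region):
        lam = constant_intensity(3.0, region)
        assert intensity_at(lam, 0.0) == 3.0
        assert intensity_at(lam, 9.99) == 3.0

    def test_negative_expansion_clamped_to_floor(self, region):
        lam = IntensityFunction(np.array([-np.sqrt(10)]), "cosine_dct", region)
        assert lam.raw(5.0) == pytest.approx(-1.0)
        assert intensity_at(lam, 5.0) == pytest.approx(1e-8)

    def test_scenario1_cluster1_at_zero(self, region):
        lam = scenario_intensities("S1")[0]
        assert intensity_at(lam, 0.0) == pytest.approx(6.0)

    def test_outside_region_rejected(self, region):
        with pytest.raises(ValueError, match="outside"):
            intensity_at(constant_intensity(1.0, region), 10.5)


class TestCumulative:
    def test_constant_rate(self, region):
        assert cumulative(constant_intensity(2.0, region), 0, 10) == pytest.approx(20.0)

    def test_empty_interval(self, region):
        assert cumulative(constant_intensity(2.0, region), 5.0, 5.0) == 0.0

    def test_scenario1_cluster1_total(self):
        # quadrature oracle on the printed formula: the cosine integrates to
        # zero over its full periods, leaving the constant term
        oracle, _ = quad(s1_cluster1_rate, 0, 10)
        lam = scenario_intensities("S1")[0]
        assert oracle == pytest.approx(30.0, abs=1e-9)
        assert cumulative(lam, 0, 10) == pytest.approx(oracle, abs=1e-6)

    def test_reversed_limits_rejected(self, region):
        with pytest.raises(ValueError, match="a <= b"):
            cumulative(constant_intensity(1.0, region), 7.0, 3.0)

    @pytest.mark.parametrize("b", [2.5, 5.0, 8.1])
    def test_additive_over_subintervals(self, b):
        lam = scenario_intensities("S1")[1]
        total = cumulative(lam, 0.0, 10.0)
        split = cumulative(lam, 0.0, b) + cumulative(lam, b, 10.0)
        assert split == pytest.approx(total, abs=1e-9)


class TestLogLikelihood:
    def test_empty_path_is_minus_integral(self, region, unit_rate):
        assert log_likelihood(SamplePath([]), unit_rate) == pytest.approx(-10.0)

    def test_homogeneous_closed_form(self, region):
        lam = constant_intensity(2.0, region)
        value = log_likelihood(SamplePath([1.0, 4.0, 9.0]), lam)
        assert value == pytest.approx(-20.0 + 3 * np.log(2.0))

    def test_scenario1_cluster1_sites(self):
        lam = scenario_intensities("S1")[0]
        sites = np.array([1.0, 2.0, 3.0])
        oracle = -quad(s1_cluster1_rate, 0, 10)[0] + np.log(s1_cluster1_rate(sites)).sum()
        assert log_likelihood(SamplePath(sites), lam) == pytest.approx(oracle, abs=1e-6)

    def test_site_outside_region_rejected(self, region, unit_rate):
        with pytest.raises(ValueError, match="outside"):
            log_likelihood(SamplePath([11.0]), unit_rate)

    def test_joint_reduces_to_single(self, region):
        lam = constant_intensity(2.0, region)
        p = SamplePath([2.0, 3.0])
        assert joint_log_likelihood([p], lam) == log_likelihood(p, lam)

    def test_joint_additivity(self, region):
        lam = constant_intensity(2.0, region)
        p = SamplePath([2.0, 3.0])
        assert joint_log_likelihood([p, p], lam) == pytest.approx(2 * log_likelihood(p, lam))

    def test_joint_counts_integral_once_per_path(self, region, unit_rate):
        paths = [SamplePath([1.0, 2.0]), SamplePath([]), SamplePath([5.0])]
        # log(1) = 0, so only the three -10 integral terms remain
        assert joint_log_likelihood(paths, unit_rate) == pytest.approx(-30.0)

    def test_empty_path_list(self, region, unit_rate):
        assert joint_log_likelihood([], unit_rate) == 0.0

    def test_constant_mle_maximizes_homogeneous_likelihood(self, region):
        # closed form n/|D| beats a numeric scan over constant rates
        path = SamplePath(np.linspace(0.4, 9.6, 23))
        mle = path.n / region.length
        best = log_likelihood(path, constant_intensity(mle, region))
        for rate in np.linspace(0.5, 5.0, 40):
            assert log_likelihood(path, constant_intensity(rate, region)) <= best + 1e-12


class TestSimulator:
    def test_zero_rate_gives_empty_path(self, region):
        lam = IntensityFunction(np.array([0.0]), "constant", region)
        path = simulate_nhpp(lam, region, rng=1)
        assert path.n == 0

    def test_reproducible_given_seed(self, region):
        lam = scenario_intensities("S1")[0]
        a = simulate_nhpp(lam, region, rng=42)
        b = simulate_nhpp(lam, region, rng=42)
        np.testing.assert_array_equal(a.sites, b.sites)

    def test_homogeneous_mean_count(self, region):
        lam = constant_intensity(3.0, region)
        rng = np.random.default_rng(7)
        counts = [simulate_nhpp(lam, region, rng).n for _ in range(2000)]
        se = np.sqrt(30.0 / 2000)
        assert abs(np.mean(counts) - 30.0) < 3 * se

    def test_counts_poisson_distributed(self):
        # chi-square goodness of fit of Scenario 1 cluster-1 counts against
        # Poisson(30); the mean comes from the quadrature oracle above
        lam = scenario_intensities("S1")[0]
        rng = np.random.default_rng(11)
        counts = np.array([simulate_nhpp(lam, rng=rng).n for _ in range(2000)])
        edges = np.concatenate([[-0.5], np.arange(20, 41) + 0.5, [np.inf]])
        observed, _ = np.histogram(counts, bins=edges)
        cdf = stats.poisson(30.0).cdf
        expected = 2000 * np.diff(cdf(edges))
        keep = expected > 5
        chi2 = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
        p = stats.chi2(keep.sum() - 1).sf(chi2)
        assert p > 0.01

    def test_superposition(self, region):
        # merged draws from lambda_a and lambda_b are distributed like draws
        # from lambda_a + lambda_b (two-sample KS on counts)
        lam_a = constant_intensity(2.0, region)
        lam_b = scenario_intensities("S1")[0]
        sum_coefs = lam_b.coefficients.copy()
        sum_coefs[0] += 2.0 * np.sqrt(10.0)  # add the constant rate in DCT terms
        lam_sum = IntensityFunction(sum_coefs, "cosine_dct", region)
        rng = np.random.default_rng(5)
        merged = np.array(
            [
                simulate_nhpp(lam_a, region, rng).n + simulate_nhpp(lam_b, region, rng).n
                for _ in range(1200)
            ]
        )
        direct = np.array([simulate_nhpp(lam_sum, region, rng).n for _ in range(1200)])
        assert stats.ks_2samp(merged, direct).pvalue > 0.001

    def test_independent_increments(self, region):
        lam = scenario_intensities("S1")[0]
        rng = np.random.default_rng(3)
        reps = 1500
        left, right = [], []
        for _ in range(reps):
            s = simulate_nhpp(lam, region, rng).sites
            left.append(np.sum(s <= 5.0))
            right.append(np.sum(s > 5.0))
        r = np.corrcoef(left, right)[0, 1]
        assert abs(r) < 3 / np.sqrt(reps)
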