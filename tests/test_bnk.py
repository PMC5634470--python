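"""Kernel density null, level-set CDF, HDR p-values and bandwidth selection."""

import numpy as np
import pytest

from bnkqtl.bnk import (
    build_null_kernel,
    fit_null_kernel,
    kernel_cdf,
    normal_reference_bandwidth,
    select_bandwidth,
    simulate_null_pairs,
)

from conftest import FAST_EM


@pytest.fixture(scope="module")
def kernel(bivariate_cloud):
    h = normal_reference_bandwidth(bivariate_cloud)
    return fit_null_kernel(bivariate_cloud, h)


class TestKernelDensity:
    def test_total_mass_near_one(self, kernel):
        assert kernel.total_mass == pytest.approx(1.0, abs=0.01)

    def test_density_higher_at_cluster_than_empty_corner(self, kernel):
        center = kernel.pairs.mean(axis=0)
        corner = np.array([kernel.grid_x[0], kernel.grid_y[0]])
        assert kernel.density_at([center])[0] > 10 * kernel.density_at([corner])[0]

    def test_density_zero_outside_grid(self, kernel):
        far = np.array([[kernel.grid_x[-1] + 10.0, kernel.grid_y[-1] + 10.0]])
        assert kernel.density_at(far)[0] == 0.0

    def test_degenerate_pairs_rejected(self):
        pairs = np.column_stack([np.zeros(200), np.arange(200.0)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_null_kernel(pairs, [1.0, 1.0])

    def test_grid_refinement_stability(self, bivariate_cloud, rng):
        """Halving the cell size moves any p-value by less than 0.005."""
        h = normal_reference_bandwidth(bivariate_cloud)
        coarse = fit_null_kernel(bivariate_cloud, h, grid_size=256)
        fine = fit_null_kernel(bivariate_cloud, h, grid_size=512)
        probe = bivariate_cloud[rng.choice(len(bivariate_cloud), 50, replace=False)]
        assert np.abs(coarse.pvalue(probe) - fine.pvalue(probe)).max() < 0.005


class TestLevelSetCDF:
    def test_boundary_levels(self, kernel):
        assert kernel_cdf(kernel, 0.0) == pytest.approx(kernel.total_mass)
        assert kernel_cdf(kernel, kernel.density.max() * 1.01) == 0.0

    def test_monotone_nonincreasing_in_level(self, kernel):
        levels = np.linspace(0.0, kernel.density.max(), 50)
        vals = kernel.cdf(levels)
        assert (np.diff(vals) <= 1e-12).all()

    def test_against_monte_carlo_integration_oracle(self, kernel, rng):
        """F-hat(c) must match the null mass of {f-hat >= c} estimated by
        sampling from the kernel mixture itself."""
        k = kernel.k
        draws = 20000
        idx = rng.integers(0, k, size=draws)
        samples = kernel.pairs[idx] + rng.normal(0.0, 1.0, (draws, 2)) * kernel.bandwidth
        dens = kernel.density_at(samples)
        for c in np.quantile(kernel.density_at(kernel.pairs), [0.1, 0.5, 0.9]):
            mc = np.mean(dens >= c)
            assert kernel.cdf(float(c)) == pytest.approx(mc, abs=0.01)


class TestPValues:
    def test_mode_is_least_extreme(self, kernel):
        i, j = np.unravel_index(np.argmax(kernel.density), kernel.density.shape)
        mode = np.array([kernel.grid_x[i], kernel.grid_y[j]])
        assert kernel.pvalue(mode) > 0.95

    def test_far_point_gets_zero(self, kernel):
        assert kernel.pvalue(np.array([1e3, 1e3])) == 0.0

    def test_monotone_in_density_level(self, kernel, rng):
        pts = kernel.pairs[rng.choice(kernel.k, 100, replace=False)]
        dens = kernel.density_at(pts)
        pv = kernel.pvalue(pts)
        order = np.argsort(dens)
        assert (np.diff(pv[order]) >= -1e-12).all()

    def test_exchangeability_of_pairs(self, bivariate_cloud, rng):
        h = normal_reference_bandwidth(bivariate_cloud)
        k1 = fit_null_kernel(bivariate_cloud, h)
        k2 = fit_null_kernel(bivariate_cloud[rng.permutation(len(bivariate_cloud))], h)
        probe = bivariate_cloud[:20]
        assert np.allclose(k1.pvalue(probe), k2.pvalue(probe), atol=1e-10)

    def test_fresh_null_draws_approximately_uniform(self, rng):
        """Calibration: over fresh draws from the true null, about 5% should
        fall below 0.05 (between 1% and 8%)."""
        cov = np.array([[1.0, 0.5], [0.5, 2.0]])
        cloud = rng.multivariate_normal([0, 0], cov, size=1000)
        kern = build_null_kernel(cloud, alpha=0.05)
        fresh = rng.multivariate_normal([0, 0], cov, size=1000)
        frac = np.mean(kern.pvalue(fresh) < 0.05)
        assert 0.01 <= frac <= 0.08


class TestBandwidthSelection:
    def test_selected_bandwidth_controls_size(self, bivariate_cloud):
        h = select_bandwidth(bivariate_cloud, alpha=0.05)
        kern = fit_null_kernel(bivariate_cloud, h)
        size = np.mean(kern.pvalue(bivariate_cloud) < 0.05)
        assert size <= 0.05

    def test_undersmoothing_inflates_size(self, bivariate_cloud):
        """A tiny bandwidth makes every point its own mode, pushing the
        in-sample size above alpha, so such candidates must be rejected."""
        base = normal_reference_bandwidth(bivariate_cloud)
        tiny = fit_null_kernel(bivariate_cloud, 0.02 * base)
        size_tiny = np.mean(tiny.pvalue(bivariate_cloud) < 0.05)
        assert size_tiny > 0.05
        chosen = select_bandwidth(bivariate_cloud, alpha=0.05,
                                  multipliers=(0.02, 0.5, 1.0, 2.0))
        assert not np.allclose(chosen, 0.02 * base)

    def test_size_nonincreasing_under_oversmoothing(self, bivariate_cloud):
        """From the reference bandwidth upward, widening the kernel merges
        density contours and can only make the test more conservative."""
        base = normal_reference_bandwidth(bivariate_cloud)
        sizes = []
        for m in (1.0, 2.0, 4.0):
            kern = fit_null_kernel(bivariate_cloud, m * base)
            sizes.append(np.mean(kern.pvalue(bivariate_cloud) < 0.05))
        assert (np.diff(sizes) <= 0.005).all()

    def test_alpha_domain(self, bivariate_cloud):
        with pytest.raises(ValueError):
            select_bandwidth(bivariate_cloud, alpha=0.7)


class TestSimulateNullPairs:
    def test_determinism_and_nonnegativity(self):
        kw = dict(n=60, p=0.5, mu=0.0, sigma=1.0, k=100, seed=99,
                  config=FAST_EM)
        with pytest.warns(UserWarning, match="low"):
            a = simulate_null_pairs(**kw)
        with pytest.warns(UserWarning, match="low"):
            b = simulate_null_pairs(**kw)
        assert np.array_equal(a, b)
        assert (a >= 0).all()

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate_null_pairs(n=60, p=0.5, mu=0.0, sigma=1.0, k=50)


def test_kernel_roundtrip_serialization(kernel):
    from bnkqtl.bnk import NullKernel

    clone = NullKernel.from_dict(kernel.to_dict())
    probe = kernel.pairs[:10]
    assert np.allclose(clone.pvalue(probe), kernel.pvalue(probe), atol=1e-12)
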