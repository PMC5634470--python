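"""Data generators: null pairs, linked-QTL draws, F2 crosses, Hotelling."""

import numpy as np
import pytest
from scipy.stats import kstest

from bnkqtl.ld_model import marginal_qtl_probs
from bnkqtl.simulate import (
    F2SimConfig,
    HotellingConfig,
    LinkedQTLConfig,
    haldane_r,
    hotelling_t2,
    simulate_bivariate_normal_pairs,
    simulate_f2_cross,
    simulate_linked_qtl_dataset,
    simulate_null_dataset,
)


class TestNullDataset:
    def test_moments_and_independence(self):
        Y, M = simulate_null_dataset(20000, 0.3, 10.0, 2.0, seed=1)
        assert Y.mean() == pytest.approx(10.0, abs=0.05)
        assert Y.std() == pytest.approx(2.0, abs=0.05)
        assert M.mean() / 2 == pytest.approx(0.3, abs=0.01)
        assert abs(np.corrcoef(Y, M)[0, 1]) < 0.02

    def test_seed_reproducibility(self):
        a = simulate_null_dataset(50, 0.5, 0.0, 1.0, seed=9)
        b = simulate_null_dataset(50, 0.5, 0.0, 1.0, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestLinkedQTLDataset:
    def test_marker_qtl_genotype_covariance_matches_2D(self):
        # under random union of gametes cov(M, G) = 2D
        cfg = LinkedQTLConfig(n=60000, p=0.5, q=0.7, D=0.08, seed=2)
        _, M, G = simulate_linked_qtl_dataset(cfg)
        assert np.cov(M, G)[0, 1] == pytest.approx(2 * 0.08, abs=0.01)

    def test_qtl_marginal_follows_hwe(self):
        cfg = LinkedQTLConfig(n=60000, p=0.5, q=0.7, D=0.08, seed=3)
        _, _, G = simulate_linked_qtl_dataset(cfg)
        freqs = np.bincount(G, minlength=3) / G.size
        assert freqs == pytest.approx(marginal_qtl_probs(0.7), abs=0.01)

    def test_boundary_coupling(self):
        cfg = LinkedQTLConfig(n=2000, p=0.5, q=0.5, D=0.25,
                              mu1=0, mu2=0, mu3=0, seed=4)
        _, M, G = simulate_linked_qtl_dataset(cfg)
        assert np.array_equal(M, G)

    def test_equal_means_collapse_to_single_normal(self):
        cfg = LinkedQTLConfig(n=30000, p=0.5, q=0.7, D=0.08,
                              mu1=3.0, mu2=3.0, mu3=3.0, sigma=1.0, seed=5)
        Y, _, _ = simulate_linked_qtl_dataset(cfg)
        assert kstest((Y - 3.0), "norm").pvalue > 0.01

    def test_infeasible_D_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            LinkedQTLConfig(p=0.5, q=0.7, D=0.3)


class TestHaldane:
    def test_closed_form_values(self):
        assert haldane_r(0.0) == 0.0
        assert haldane_r(100.0) == pytest.approx((1 - np.exp(-2)) / 2)
        assert haldane_r(1e6) == pytest.approx(0.5)

    def test_monotone_and_bounded(self):
        d = np.linspace(0, 300, 50)
        r = haldane_r(d)
        assert (np.diff(r) > 0).all() and (r < 0.5).all()

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_r(-1.0)


class TestF2Cross:
    @pytest.fixture(scope="class")
    def cross(self):
        cfg = F2SimConfig(n=4000, chrom_lengths=(100.0,), marker_counts=(11,),
                          qtl=(), sigma=1.0, seed=6)
        return simulate_f2_cross(cfg)

    def test_segregation_one_two_one(self, cross):
        M, _, _, _ = cross
        freqs = np.bincount(M[:, 0], minlength=3) / M.shape[0]
        assert freqs == pytest.approx([0.25, 0.5, 0.25], abs=0.02)

    def test_adjacent_marker_recombination_matches_haldane(self, cross):
        M, _, mmap, _ = cross
        d = mmap["pos"].iloc[1] - mmap["pos"].iloc[0]
        # genotype correlation between adjacent markers in an F2 is (1-2r)
        expected = 1.0 - 2.0 * haldane_r(d)
        got = np.corrcoef(M[:, 0], M[:, 1])[0, 1]
        assert got == pytest.approx(expected, abs=0.03)

    def test_ld_decays_with_map_distance(self, cross):
        M, _, _, _ = cross
        corr0 = [abs(np.corrcoef(M[:, 0], M[:, j])[0, 1]) for j in (1, 3, 6, 10)]
        assert (np.diff(corr0) < 0.02).all()

    def test_qtl_effects_enter_phenotype(self):
        cfg = F2SimConfig(n=3000, seed=7)
        M, Y, mmap, G = simulate_f2_cross(cfg)
        # phenotype variance = a1^2/2 + a2^2/2 (QTL on separate chromosomes)
        # + residual 1
        expected_var = 0.75**2 / 2 + 1.0**2 / 2 + 1.0
        assert Y.var() == pytest.approx(expected_var, rel=0.1)
        assert mmap.shape[0] == M.shape[1] == 120
        assert G.shape == (3000, 2)

    def test_marker_nearest_qtl_most_correlated(self):
        cfg = F2SimConfig(n=2000, seed=8)
        M, Y, mmap, G = simulate_f2_cross(cfg)
        corr = np.array([abs(np.corrcoef(Y, M[:, j])[0, 1])
                         for j in range(M.shape[1])])
        best = mmap.iloc[int(np.argmax(corr))]
        # strongest QTL sits at chr2 61.6 cM
        assert best["chrom"] == 2
        assert abs(best["pos"] - 61.6) < 15

    def test_qtl_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            F2SimConfig(qtl=((1, 150.0, 1.0),))


class TestHotelling:
    def test_zero_statistic_at_hypothesized_mean(self, rng):
        X = rng.normal(size=(30, 2))
        X = X - X.mean(axis=0)  # exact sample mean (0, 0)
        t2, p, _ = hotelling_t2(X, (0.0, 0.0))
        assert t2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(25, 2))
        mu0 = np.array([0.3, -0.2])
        A = np.array([[2.0, 0.7], [-0.3, 1.5]])
        b = np.array([1.0, -4.0])
        t2a, _, _ = hotelling_t2(X, mu0)
        t2b, _, _ = hotelling_t2(X @ A.T + b, A @ mu0 + b)
        assert t2b == pytest.approx(t2a, rel=1e-9)

    def test_null_pvalues_uniform(self):
        r = np.random.default_rng(11)
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        pvals = [hotelling_t2(r.multivariate_normal([0, 0], cov, 20),
                              (0.0, 0.0))[1] for _ in range(1000)]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_marginal_statistic_conventions(self, rng):
        X = rng.normal(size=(20, 2))
        _, _, (t_var, u_var) = hotelling_t2(X, (0, 0), marginal="variance")
        _, _, (t_sd, u_sd) = hotelling_t2(X, (0, 0), marginal="sd")
        S = np.cov(X, rowvar=False)
        assert t_var * S[0, 0] == pytest.approx(t_sd * np.sqrt(S[0, 0]))

    def test_null_pair_generator_shape_and_determinism(self):
        cfg = HotellingConfig(n=20)
        a = simulate_bivariate_normal_pairs(cfg, 120, seed=3)
        b = simulate_bivariate_normal_pairs(cfg, 120, seed=3)
        assert a.shape == (120, 2)
        assert np.array_equal(a, b)
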