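"""Data generators and replication studies.

Four dataset classes are generated here:

* null marker-phenotype pairs (phenotype and HWE marker independent);
* linked-QTL data: a hidden QTL genotype drawn conditionally on the
  observed marker through (p, q, D), then a phenotype from the mixture;
* F2 intercross genomes: two independent gametes per chromosome, each a
  Markov chain along the ordered loci with Haldane crossover probabilities,
  with additive QTL acting on the phenotype;
* bivariate-normal samples with a Hotelling T-squared comparator for the
  general (non-genetic) two-test setting.

``run_simulation_study`` orchestrates the replication loops for the three
study designs plus the null-distribution study of T_L and T_D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist

from .bnk import build_null_kernel, simulate_null_pairs
from .estimation import EMConfig
from .ld_model import conditional_qtl_prob_matrix, feasible_D_range
from .scan import scan_genome
from .statistics import bivariate_statistic

__all__ = [
    "LinkedQTLConfig",
    "F2SimConfig",
    "HotellingConfig",
    "simulate_null_dataset",
    "simulate_linked_qtl_dataset",
    "haldane_r",
    "simulate_f2_cross",
    "hotelling_t2",
    "simulate_bivariate_normal_pairs",
    "run_simulation_study",
]


@dataclass(frozen=True)
class LinkedQTLConfig:
    """Linked-QTL generator settings (marker p, QTL q, LD D, genotype means)."""

    n: int = 500
    p: float = 0.5
    q: float = 0.7
    D: float = 0.08
    mu1: float = 9.5
    mu2: float = 10.0
    mu3: float = 10.5
    sigma: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = feasible_D_range(self.p, self.q)
        if not lo - 1e-12 <= self.D <= hi + 1e-12:
            raise ValueError(f"D={self.D} infeasible for (p={self.p}, q={self.q}): "
                             f"range [{lo}, {hi}]")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class F2SimConfig:
    """F2 intercross design: chromosome lengths/marker counts and QTL list.

    Defaults reproduce the interval-mapping design used in the second
    replication study: four 100-cM chromosomes with 50/10/50/10 equally
    spaced markers, additive QTL at chr1 44.4 cM (effect 0.75) and chr2
    61.6 cM (effect 1.0), residual sigma 1, n = 100.
    """

    n: int = 100
    chrom_lengths: tuple = (100.0, 100.0, 100.0, 100.0)
    marker_counts: tuple = (50, 10, 50, 10)
    qtl: tuple = ((1, 44.4, 0.75), (2, 61.6, 1.0))  # (chrom, pos cM, effect)
    sigma: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) != len(self.marker_counts):
            raise ValueError("chrom_lengths and marker_counts must align")
        for c, pos, _ in self.qtl:
            if not 1 <= c <= len(self.chrom_lengths):
                raise ValueError(f"QTL chromosome {c} out of range")
            if not 0.0 <= pos <= self.chrom_lengths[c - 1]:
                raise ValueError(f"QTL position {pos} outside chromosome {c} "
                                 f"(length {self.chrom_lengths[c - 1]} cM)")


@dataclass(frozen=True)
class HotellingConfig:
    """Bivariate-normal mean test setting."""

    n: int = 20
    mean: tuple = (0.0, 0.0)
    cov: tuple = ((1.0, 0.3), (0.3, 1.0))
    mu0: tuple = (0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.cov, dtype=float)
        if not np.allclose(S, S.T) or np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("covariance must be symmetric positive definite")


def simulate_null_dataset(n: int, p: float, mu: float, sigma: float,
                          seed: int | None = None):
    """Independent phenotype Y ~ Normal(mu, sigma^2) and HWE marker at p."""
    rng = np.random.default_rng(seed)
    Y = rng.normal(mu, sigma, size=n)
    M = rng.binomial(2, p, size=n)
    return Y, M


def simulate_linked_qtl_dataset(cfg: LinkedQTLConfig):
    """Marker, hidden QTL genotype and mixture phenotype under (p, q, D).

    Returns (Y, M, G) with G the hidden QTL genotype (0/1/2 copies of A),
    exposed so oracle checks can see the latent truth.
    """
    rng = np.random.default_rng(cfg.seed)
    M = rng.binomial(2, cfg.p, size=cfg.n)
    W = conditional_qtl_prob_matrix(cfg.p, cfg.q, cfg.D)
    # vectorized categorical draw: inverse-CDF per individual
    cum = np.cumsum(W[M], axis=1)
    u = rng.random(cfg.n)
    G = (u[:, None] > cum).sum(axis=1)
    means = np.array([cfg.mu1, cfg.mu2, cfg.mu3])
    Y = rng.normal(means[G], cfg.sigma)
    return Y, M, G


def haldane_r(d) -> float | np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def simulate_f2_cross(cfg: F2SimConfig):
    """F2 intercross genomes with hidden QTL columns.

    Each individual inherits two independent gametes per chromosome; a
    gamete's allele sequence along the ordered loci is a Markov chain whose
    switch probability between adjacent loci is the Haldane recombination
    fraction of their cM separation (no interference).  The phenotype is the
    sum of additive QTL contributions a * (g - 1) plus Normal(0, sigma^2)
    noise.

    Returns ``(M, Y, marker_map, G)``: marker genotype matrix (n x P),
    phenotype, a frame with (marker, chrom, pos), and the hidden QTL
    genotype matrix (n x n_qtl).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    marker_cols, map_rows = [], []
    qtl_genos = {}
    for c, (length, n_mark) in enumerate(zip(cfg.chrom_lengths, cfg.marker_counts),
                                         start=1):
        marker_pos = np.linspace(0.0, length, n_mark)
        qtl_here = [(pos, idx) for idx, (qc, pos, _) in enumerate(cfg.qtl) if qc == c]
        loci = np.concatenate([marker_pos, [pos for pos, _ in qtl_here]])
        order = np.argsort(loci, kind="stable")
        loci_sorted = loci[order]
        is_qtl = np.concatenate([np.zeros(n_mark, bool),
                                 np.ones(len(qtl_here), bool)])[order]
        qtl_idx_sorted = np.concatenate([np.full(n_mark, -1),
                                         [idx for _, idx in qtl_here]])[order]

        r = haldane_r(np.diff(loci_sorted))
        geno = np.zeros((n, loci_sorted.size), dtype=int)
        for _gamete in range(2):
            alleles = np.empty((n, loci_sorted.size), dtype=int)
            alleles[:, 0] = rng.random(n) < 0.5
            switch = rng.random((n, loci_sorted.size - 1)) < r[None, :]
            alleles[:, 1:] = switch
            # cumulative XOR along loci turns switch indicators into alleles
            alleles = np.cumsum(alleles, axis=1) % 2
            geno += alleles
        for j in range(loci_sorted.size):
            if is_qtl[j]:
                qtl_genos[int(qtl_idx_sorted[j])] = geno[:, j]
            else:
                marker_cols.append(geno[:, j])
                map_rows.append((c, float(loci_sorted[j])))

    M = np.column_stack(marker_cols)
    marker_map = pd.DataFrame(map_rows, columns=["chrom", "pos"])
    marker_map.insert(0, "marker", [
        f"c{ch}m{i + 1}" for i, ch in zip(marker_map.groupby("chrom").cumcount(),
                                          marker_map["chrom"])
    ])
    G = np.column_stack([qtl_genos[i] for i in range(len(cfg.qtl))]) \
        if cfg.qtl else np.empty((n, 0), dtype=int)
    effects = np.array([a for _, _, a in cfg.qtl])
    Y = (G - 1) @ effects + rng.normal(0.0, cfg.sigma, size=n)
    return M, Y, marker_map, G


def hotelling_t2(X, mu0, marginal: str = "sd"):
    """Hotelling's T-squared test of a bivariate mean vector.

    T^2 = n (Xbar - mu0)' S^{-1} (Xbar - mu0) with S the sample covariance;
    the p-value uses the scaled-F null 2(n-1)/(n-2) * F(2, n-2).  Also
    returns the marginal statistics (T, U): by default the proper t
    forms sqrt(n)(Xbar_j - mu0_j) / sd_j; ``marginal="variance"`` divides by
    the diagonal (variance) entries of S instead.
    """
    X = np.asarray(X, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    n, d = X.shape
    if d != 2 or n < 3:
        raise ValueError("X must be an (n, 2) sample with n >= 3")
    xbar = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    if abs(np.linalg.det(S)) < 1e-14:
        raise np.linalg.LinAlgError("singular sample covariance")
    diff = xbar - mu0
    t2 = float(n * diff @ np.linalg.solve(S, diff))
    pval = float(f_dist.sf(t2 * (n - 2) / (2.0 * (n - 1)), 2, n - 2))
    denom = np.diag(S) if marginal == "variance" else np.sqrt(np.diag(S))
    T, U = np.sqrt(n) * diff / denom
    return t2, pval, (float(T), float(U))


def simulate_bivariate_normal_pairs(cfg: HotellingConfig, k: int,
                                    seed: int | None = None,
                                    marginal: str = "sd") -> np.ndarray:
    """k null (T, U) marginal-statistic pairs for the bivariate-mean test.

    Samples of size n are drawn from Normal(mu0, cov) — the null of the mean
    test — and the marginal statistics computed; these pairs feed the
    general BNK in place of (T_L, T_D).
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(cfg.mu0, dtype=float)
    cov = np.asarray(cfg.cov, dtype=float)
    pairs = np.empty((k, 2))
    for i in range(k):
        X = rng.multivariate_normal(mean, cov, size=cfg.n)
        _, _, (T, U) = hotelling_t2(X, cfg.mu0, marginal=marginal)
        pairs[i] = (T, U)
    return pairs


# ---------------------------------------------------------------------------
# replication studies
# ---------------------------------------------------------------------------


def _study_null_distribution(reps: int, n: int, seed, em_config, p: float = 0.5):
    """Null sampling distribution of (T_L, T_D): summaries vs chi-square refs."""
    pairs = simulate_null_pairs(n, p, 0.0, 1.0, reps, seed=seed, config=em_config)
    t_l, t_d = pairs[:, 0], pairs[:, 1]
    crit5 = float(chi2(5).ppf(0.95))
    crit1 = float(chi2(1).ppf(0.95))
    return {
        "n": n,
        "reps": reps,
        "T_L": {
            "mean": float(t_l.mean()),
            "variance": float(t_l.var(ddof=1)),
            "q95": float(np.quantile(t_l, 0.95)),
            "frac_above_chi2_5_crit": float(np.mean(t_l > crit5)),
        },
        "T_D": {
            "mean": float(t_d.mean()),
            "variance": float(t_d.var(ddof=1)),
            "q95": float(np.quantile(t_d, 0.95)),
            "frac_above_chi2_1_crit": float(np.mean(t_d > crit1)),
        },
        "pairs": pairs,
    }


def _study_1(reps: int, seed, em_config, sample_sizes=(100, 300, 500),
             k: int = 1000, alpha: float = 0.05, mu: float = 10.0,
             sigma: float = 1.0, p: float = 0.5, q: float = 0.7,
             D: float = 0.08, effect: float = 0.5, power: bool = True):
    """Type-I error rate (and optionally power) of single-marker BNK.

    The null kernel for each sample size is built once from k null pairs at
    the design's true moments; T_L is invariant to affine rescaling of Y and
    the marker frequency is the design value, so the shared kernel matches
    the per-replicate null to Monte-Carlo accuracy.  Power replicates use a
    linked QTL at (p, q, D) with additive genotype means
    (mu - effect, mu, mu + effect).
    """
    root = np.random.SeedSequence(seed)
    out = {}
    for n, ss in zip(sample_sizes, root.spawn(len(sample_sizes))):
        s_kernel, s_null, s_power = ss.spawn(3)
        kern_seed = int(s_kernel.generate_state(1)[0] % (2**31 - 1))
        pairs = simulate_null_pairs(n, p, mu, sigma, k, seed=kern_seed,
                                    config=em_config)
        kern = build_null_kernel(pairs, alpha=alpha, seed=kern_seed)

        def rate(data_seed_seq, linked: bool) -> float:
            seeds = data_seed_seq.generate_state(2 * reps) % (2**31 - 1)
            rejected = 0
            for i in range(reps):
                if linked:
                    cfg = LinkedQTLConfig(n=n, p=p, q=q, D=D,
                                          mu1=mu - effect, mu2=mu,
                                          mu3=mu + effect, sigma=sigma,
                                          seed=int(seeds[2 * i]))
                    Y, M, _ = simulate_linked_qtl_dataset(cfg)
                else:
                    Y, M = simulate_null_dataset(n, p, mu, sigma,
                                                 seed=int(seeds[2 * i]))
                if len(np.unique(M)) == 1:
                    continue
                stat = bivariate_statistic(Y, M, config=em_config,
                                           seed=int(seeds[2 * i + 1]))
                if kern.pvalue(stat) < alpha:
                    rejected += 1
            return rejected / reps

        entry = {"type_i_error": rate(s_null, linked=False)}
        if power:
            entry["power"] = rate(s_power, linked=True)
        out[n] = entry
    return {"alpha": alpha, "reps": reps, "by_n": out}


def _study_2(seed, em_config, k: int = 1000, alpha: float = 0.05,
             cfg: F2SimConfig | None = None):
    """F2 interval-mapping genome scan; returns the scan result and truth."""
    root = np.random.SeedSequence(seed)
    s_data, s_scan = root.spawn(2)
    sim_cfg = cfg or F2SimConfig(seed=int(s_data.generate_state(1)[0] % (2**31 - 1)))
    M, Y, marker_map, G = simulate_f2_cross(sim_cfg)
    result = scan_genome(Y, M, marker_ids=list(marker_map["marker"]),
                         marker_map=marker_map, alpha=alpha, k=k,
                         seed=int(s_scan.generate_state(1)[0] % (2**31 - 1)),
                         config=em_config)
    return {"scan": result, "config": sim_cfg, "qtl_genotypes": G}


def _study_3(reps: int, seed, k: int = 1000, alpha: float = 0.05,
             n: int = 20, null_means: bool = False):
    """BNK vs Hotelling on bivariate-normal mean tests.

    One null kernel of k (T, U) pairs is shared by all replications (the
    null distribution of the marginal statistics does not depend on the
    simulated alternative).  Power replications draw the true mean
    components Unif(0, 1); null replications use mean zero.
    """
    root = np.random.SeedSequence(seed)
    s_kernel, s_reps = root.spawn(2)
    base = HotellingConfig(n=n)
    kern_seed = int(s_kernel.generate_state(1)[0] % (2**31 - 1))
    pairs = simulate_bivariate_normal_pairs(base, k, seed=kern_seed)
    kern = build_null_kernel(pairs, alpha=alpha, seed=kern_seed)

    rng = np.random.default_rng(s_reps.generate_state(1)[0] % (2**31 - 1))
    cov = np.asarray(base.cov)
    records = []
    for _ in range(reps):
        mean = np.zeros(2) if null_means else rng.uniform(0.0, 1.0, size=2)
        X = rng.multivariate_normal(mean, cov, size=n)
        t2, p_hot, (T, U) = hotelling_t2(X, base.mu0)
        p_bnk = float(kern.pvalue(np.array([T, U])))
        records.append((p_bnk, p_hot))
    rec = np.array(records)
    sig_bnk, sig_hot = rec[:, 0] < alpha, rec[:, 1] < alpha
    quad = {
        "I_both_significant": int(np.sum(sig_bnk & sig_hot)),
        "II_bnk_only": int(np.sum(sig_bnk & ~sig_hot)),
        "III_neither": int(np.sum(~sig_bnk & ~sig_hot)),
        "IV_hotelling_only": int(np.sum(~sig_bnk & sig_hot)),
    }
    return {
        "reps": reps,
        "alpha": alpha,
        "quadrants": quad,
        "agreement": quad["I_both_significant"] + quad["III_neither"],
        "bnk_rejection_rate": float(np.mean(sig_bnk)),
        "hotelling_rejection_rate": float(np.mean(sig_hot)),
        "pvalues": rec,
        "kernel": kern,
    }


def run_simulation_study(study, reps: int | None = None, seed: int | None = None,
                         em_config: EMConfig | None = None, **overrides):
    """Run one of the replication studies.

    ``study`` is 1, 2, 3 or ``"null_distribution"``.  Default replication
    counts: 1000 for the null-distribution study, 100 for studies 1 and 3
    (study 2 is a single genome scan).  Keyword overrides are forwarded to
    the study runner (e.g. ``k=500``, ``sample_sizes=(100,)``).
    """
    if study == "null_distribution":
        reps = 1000 if reps is None else reps
        n = overrides.pop("n", 500)
        return _study_null_distribution(reps, n, seed, em_config, **overrides)
    if study == 1:
        reps = 100 if reps is None else reps
        return _study_1(reps, seed, em_config, **overrides)
    if study == 2:
        return _study_2(seed, em_config, **overrides)
    if study == 3:
        reps = 100 if reps is None else reps
        return _study_3(reps, seed, **overrides)
    raise ValueError(f"unknown study {study!r}; expected 1, 2, 3 or "
                     "'null_distribution'")
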