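"""Likelihood structure of the LD-based single-marker QTL model.

A bi-allelic marker (alleles M/m, frequency ``p`` of M) is linked to a
hidden bi-allelic QTL (alleles A/a, frequency ``q`` of A) through the
linkage-disequilibrium parameter ``D``.  Marker and QTL jointly define four
gametic haplotypes MA, Ma, mA, ma with frequencies

    p11 = p*q + D        p10 = p*(1-q) - D
    p01 = (1-p)*q - D    p00 = (1-p)*(1-q) + D

Three nested models describe the phenotype Y:

* linked QTL   — 3-component normal mixture whose weights are the
  probabilities of the QTL genotype conditional on each individual's
  observed marker genotype (functions of p, q, D);
* unlinked QTL — the same mixture with marginal Hardy-Weinberg weights
  (1-q)^2, 2q(1-q), q^2 (D = 0 collapses the conditional weights to these);
* no QTL       — a single normal.

All functions here are pure; estimation lives in :mod:`bnkqtl.estimation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "HaplotypeModel",
    "MixtureParams",
    "NullParams",
    "haplotype_frequencies",
    "feasible_D_range",
    "conditional_qtl_probs",
    "conditional_qtl_prob_matrix",
    "marginal_qtl_probs",
    "marker_genotype_probs",
    "loglik_full",
    "loglik_unlinked",
    "loglik_null",
]

_EPS = 1e-12


def feasible_D_range(p: float, q: float) -> tuple[float, float]:
    """Closed interval of D values keeping all four haplotype frequencies in [0,1].

    Non-negativity of (p11, p10, p01, p00) gives
    ``max(-pq, -(1-p)(1-q)) <= D <= min(p(1-q), (1-p)q)``.
    For ``p`` or ``q`` in {0, 1} the marker or QTL is monomorphic and the
    interval degenerates to [0, 0] (a warning is emitted).
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError(f"allele frequencies must lie in [0,1], got p={p}, q={q}")
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        warnings.warn(
            "monomorphic locus (p or q in {0,1}): feasible D range is degenerate [0,0]",
            stacklevel=2,
        )
        return (0.0, 0.0)
    lo = max(-p * q, -(1.0 - p) * (1.0 - q))
    hi = min(p * (1.0 - q), (1.0 - p) * q)
    return (lo, hi)


def haplotype_frequencies(p: float, q: float, D: float) -> tuple[float, float, float, float]:
    """Frequencies (p11, p10, p01, p00) of haplotypes (MA, Ma, mA, ma).

    Raises ``ValueError`` naming the violated bound when ``D`` lies outside
    the feasible range for (p, q).
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ValueError(f"allele frequencies must lie in [0,1], got p={p}, q={q}")
    p11 = p * q + D
    p10 = p * (1.0 - q) - D
    p01 = (1.0 - p) * q - D
    p00 = (1.0 - p) * (1.0 - q) + D
    for name, val in (("p11", p11), ("p10", p10), ("p01", p01), ("p00", p00)):
        if val < -_EPS or val > 1.0 + _EPS:
            raise ValueError(
                f"infeasible D={D} for (p={p}, q={q}): haplotype frequency "
                f"{name}={val} outside [0,1]"
            )
    clip = lambda x: min(1.0, max(0.0, x))
    return (clip(p11), clip(p10), clip(p01), clip(p00))


@dataclass(frozen=True)
class HaplotypeModel:
    """Marker-QTL haplotype system parameterized by (p, q, D)."""

    p: float
    q: float
    D: float

    def __post_init__(self) -> None:
        haplotype_frequencies(self.p, self.q, self.D)  # validates feasibility

    @property
    def frequencies(self) -> tuple[float, float, float, float]:
        """(p11, p10, p01, p00) for haplotypes (MA, Ma, mA, ma)."""
        return haplotype_frequencies(self.p, self.q, self.D)

    @property
    def r_squared(self) -> float:
        """Squared haplotype correlation D^2 / (p(1-p)q(1-q))."""
        p, q = self.p, self.q
        denom = p * (1.0 - p) * q * (1.0 - q)
        if denom == 0.0:
            raise ZeroDivisionError("r^2 undefined for a monomorphic locus")
        return self.D**2 / denom


@dataclass(frozen=True)
class MixtureParams:
    """Phenotype means for QTL genotypes (aa, Aa, AA) and common sigma."""

    mu1: float
    mu2: float
    mu3: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.mu1, self.mu2, self.mu3]).all():
            raise ValueError("genotype means must be finite")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.mu3])


@dataclass(frozen=True)
class NullParams:
    """Single-normal phenotype model (no QTL)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def marker_genotype_probs(p: float) -> np.ndarray:
    """HWE marker genotype probabilities ((1-p)^2, 2p(1-p), p^2) for mm, Mm, MM."""
    return np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p**2])


def marginal_qtl_probs(q: float) -> np.ndarray:
    """Marginal HWE QTL genotype probabilities ((1-q)^2, 2q(1-q), q^2) for (aa, Aa, AA)."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0,1], got {q}")
    return np.array([(1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2])


def conditional_qtl_prob_matrix(p: float, q: float, D: float) -> np.ndarray:
    """3x3 matrix W with W[m, g] = P(QTL genotype g | marker genotype m).

    Rows index the count of marker allele M (0, 1, 2), columns the count of
    QTL allele A.  Built by random union of gametes: an M-bearing gamete
    carries A with probability p11/p, an m-bearing gamete with probability
    p01/(1-p); the two gametes of an individual are independent, and a
    heterozygote carries one gamete of each kind.

    Rows whose marker genotype has zero population probability are filled
    with NaN; conditioning on them is rejected by
    :func:`conditional_qtl_probs`.
    """
    p11, p10, p01, p00 = haplotype_frequencies(p, q, D)
    W = np.full((3, 3), np.nan)
    a = p11 / p if p > 0 else np.nan  # P(A | gamete carries M)
    b = p01 / (1.0 - p) if p < 1 else np.nan  # P(A | gamete carries m)
    if p < 1:  # genotype mm possible
        W[0] = [(1 - b) ** 2, 2 * b * (1 - b), b**2]
    if 0 < p < 1:  # genotype Mm possible
        W[1] = [(1 - a) * (1 - b), a * (1 - b) + (1 - a) * b, a * b]
    if p > 0:  # genotype MM possible
        W[2] = [(1 - a) ** 2, 2 * a * (1 - a), a**2]
    return W


def conditional_qtl_probs(
    marker_genotype: int, p: float, q: float, D: float
) -> tuple[float, float, float]:
    """P(QTL genotype = aa, Aa, AA | marker genotype), the mixture weights.

    ``marker_genotype`` counts copies of allele M (0, 1 or 2).  Raises if the
    conditioning marker genotype has zero probability under HWE at ``p``.
    """
    if marker_genotype not in (0, 1, 2):
        raise ValueError(f"marker genotype must be 0, 1 or 2, got {marker_genotype}")
    geno_prob = marker_genotype_probs(p)[marker_genotype]
    if geno_prob == 0.0:
        raise ValueError(
            f"cannot condition on marker genotype {marker_genotype}: it has "
            f"probability 0 when p={p}"
        )
    row = conditional_qtl_prob_matrix(p, q, D)[marker_genotype]
    return (float(row[0]), float(row[1]), float(row[2]))


def _mixture_loglik(Y: np.ndarray, weights: np.ndarray, mix: MixtureParams) -> float:
    """Sum of log of the 3-component normal mixture; weights is (n, 3)."""
    Y = np.asarray(Y, dtype=float)
    dens = norm.pdf(Y[:, None], loc=mix.means[None, :], scale=mix.sigma)
    mixture = (weights * dens).sum(axis=1)
    if np.any(mixture <= 0.0):
        return -np.inf
    return float(np.log(mixture).sum())


def loglik_full(Y, M, hap: HaplotypeModel, mix: MixtureParams) -> float:
    """Log-likelihood of the linked-QTL model (subject-specific mixture weights)."""
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(M)
    if Y.shape != M.shape or Y.ndim != 1 or Y.size < 1:
        raise ValueError("Y and M must be 1-D arrays of equal positive length")
    W = conditional_qtl_prob_matrix(hap.p, hap.q, hap.D)
    weights = W[M.astype(int)]
    if np.any(np.isnan(weights)):
        bad = int(M[np.isnan(weights).any(axis=1)][0])
        raise ValueError(
            f"observed marker genotype {bad} has probability 0 under p={hap.p}"
        )
    return _mixture_loglik(Y, weights, mix)


def loglik_unlinked(Y, q: float, mix: MixtureParams) -> float:
    """Log-likelihood of the unlinked-QTL model (marginal HWE weights)."""
    Y = np.asarray(Y, dtype=float)
    weights = np.broadcast_to(marginal_qtl_probs(q), (Y.size, 3))
    return _mixture_loglik(Y, weights, mix)


def loglik_null(Y, mu: float, sigma: float) -> float:
    """Log-likelihood of the single-normal no-QTL model."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    Y = np.asarray(Y, dtype=float)
    return float(norm.logpdf(Y, loc=mu, scale=sigma).sum())
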