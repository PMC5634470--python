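"""The bivariate per-marker statistic (T_L, T_D).

T_L is the likelihood-ratio statistic for QTL existence: the linked-QTL
mixture against the single-normal no-QTL model.  The conventional
2*(loglik_full - loglik_null) form is the default (the statistic is compared
against a chi-square(5) reference, whose scale matches 2 log Lambda); the
literal log-ratio is available via ``convention="lnL"``.

T_D measures marker-QTL linkage strength:

    T_D = n * D_hat^2 / (p_hat (1-p_hat) q_hat (1-q_hat)) = n * r^2,

with r the marker-QTL haplotype correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .estimation import EMConfig, FullModelFit, fit_full_em, fit_null

__all__ = [
    "BivariateStatistic",
    "compute_TL",
    "compute_TD",
    "bivariate_statistic",
    "chi2_reference_summary",
]


@dataclass(frozen=True)
class BivariateStatistic:
    """The (T_L, T_D) pair for one marker, with the sample size used."""

    T_L: float
    T_D: float
    n: int


def compute_TL(loglik_full: float, loglik_null: float, convention: str = "2lnL") -> float:
    """Likelihood-ratio statistic for QTL existence.

    A log-likelihood difference below -1e-6 signals broken optimizer nesting
    (the null is a submodel of the full fit) and raises.
    """
    diff = loglik_full - loglik_null
    if diff < -1e-6:
        raise ValueError(
            f"full-model log-likelihood {loglik_full} below null {loglik_null}: "
            "the optimizer violated model nesting"
        )
    diff = max(diff, 0.0)
    if convention == "2lnL":
        return 2.0 * diff
    if convention == "lnL":
        return diff
    raise ValueError(f"unknown T_L convention {convention!r}")


def compute_TD(n: int, p_hat: float, q_hat: float, D_hat: float) -> float:
    """Linkage-strength statistic n * D^2 / (p(1-p)q(1-q)) = n * r^2."""
    if n < 1:
        raise ValueError("n must be at least 1")
    denom = p_hat * (1.0 - p_hat) * q_hat * (1.0 - q_hat)
    if denom == 0.0:
        raise ZeroDivisionError(
            f"T_D undefined: p_hat={p_hat} or q_hat={q_hat} on the boundary"
        )
    return n * D_hat**2 / denom


def bivariate_statistic(
    Y,
    M,
    config: EMConfig | None = None,
    seed: int | None = None,
    convention: str = "2lnL",
    return_fit: bool = False,
) -> BivariateStatistic | tuple[BivariateStatistic, FullModelFit]:
    """Fit the null and linked-QTL models and form (T_L, T_D) for one marker.

    Raises :class:`~bnkqtl.estimation.MonomorphicMarkerError` for a marker
    with a single genotype; callers running genome scans catch it and record
    a status instead of aborting.
    """
    null = fit_null(Y)
    full = fit_full_em(Y, M, config=config, seed=seed)
    t_l = compute_TL(full.loglik, null.loglik, convention=convention)
    t_d = compute_TD(len(Y), full.p_hat, full.q_hat, full.D_hat)
    stat = BivariateStatistic(T_L=t_l, T_D=t_d, n=len(Y))
    if return_fit:
        return stat, full
    return stat


def chi2_reference_summary(df: int = 5) -> dict[str, float]:
    """Mean, variance and 95th quantile of the chi-square reference.

    For df=5 these are 5, 10 and ~11.07 — the reference against which the
    empirical null of T_L is traditionally (and inaccurately) compared.
    """
    dist = chi2(df)
    return {
        "mean": float(dist.mean()),
        "variance": float(dist.var()),
        "q95": float(dist.ppf(0.95)),
    }
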