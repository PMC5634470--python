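"""Maximum-likelihood fits of the three nested phenotype models per marker.

The no-QTL model has closed-form normal MLEs.  The linked-QTL mixture is fit
by a generalized EM with the marker allele frequency ``p`` profiled out (its
MLE under HWE is the allele-count estimate and does not involve the
phenotype model), so the search runs over (q, D, mu1, mu2, mu3, sigma):

* E-step: posterior probability of each QTL genotype per individual from the
  current conditional weights and normal densities;
* M-step: posterior-weighted closed forms for the three means and the common
  sigma; (q, D) updated by maximizing the expected complete-data
  log-likelihood — which depends on the data only through a 3x3 table of
  posterior counts by marker genotype — over a refined (q, D) grid projected
  into the feasible D region.  Any ascent step is accepted (generalized EM),
  so the observed-data log-likelihood is non-decreasing over iterations.

The likelihood is multimodal under weak identifiability, so the fit is the
best of several restarts; a null-collapsed start (all means equal, D = 0)
guarantees the returned optimum nests the no-QTL fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .ld_model import conditional_qtl_prob_matrix, feasible_D_range

__all__ = [
    "EMConfig",
    "FullModelFit",
    "NullModelFit",
    "UnlinkedModelFit",
    "MonomorphicMarkerError",
    "estimate_marker_allele_freq",
    "fit_null",
    "fit_full_em",
    "fit_unlinked_em",
]

_LOG_2PI = np.log(2.0 * np.pi)
_Q_BOUNDS = (1e-6, 1.0 - 1e-6)


class MonomorphicMarkerError(ValueError):
    """The marker has a single observed genotype; D (and T_D) are undefined."""


@dataclass(frozen=True)
class EMConfig:
    """Settings for the generalized EM.

    Parameters
    ----------
    n_restarts
        Number of starting points (a null-collapsed start is always
        included, guaranteeing nesting over the no-QTL fit).
    tol
        Convergence threshold on the change in observed-data log-likelihood.
    max_iter
        Iteration cap per restart; non-convergence returns the best iterate
        with ``converged=False``.
    grid_points, refine_levels
        Resolution of the (q, D) M-step: a ``grid_points`` x ``grid_points``
        grid over (q, D-fraction), refined ``refine_levels`` times around the
        incumbent by shrinking the window 4x per level.
    polish
        Run a box-constrained quasi-Newton pass on the observed-data
        log-likelihood from each surviving restart's solution.
    sigma_floor_frac
        Lower bound on sigma as a fraction of sd(Y), guarding underflow.
    stage1_iters, n_keep
        The restarts are first explored cheaply for ``stage1_iters`` EM
        sweeps each; the ``n_keep`` best are run to full convergence.  The
        likelihood surface is multimodal (boundary-q components capturing
        tail observations, sign-flipped D modes), so breadth of starts
        matters more than depth on most of them.
    """

    n_restarts: int = 12
    tol: float = 1e-8
    max_iter: int = 500
    grid_points: int = 15
    refine_levels: int = 3
    polish: bool = True
    sigma_floor_frac: float = 1e-6
    stage1_iters: int = 40
    n_keep: int = 4


@dataclass(frozen=True)
class NullModelFit:
    mu_hat: float
    sigma_hat: float
    loglik: float


@dataclass(frozen=True)
class FullModelFit:
    p_hat: float
    q_hat: float
    D_hat: float
    mu1_hat: float
    mu2_hat: float
    mu3_hat: float
    sigma_hat: float
    loglik: float
    n_iter: int
    converged: bool
    n_restarts: int


@dataclass(frozen=True)
class UnlinkedModelFit:
    q_hat: float
    mu1_hat: float
    mu2_hat: float
    mu3_hat: float
    sigma_hat: float
    loglik: float
    n_iter: int
    converged: bool
    n_restarts: int


def estimate_marker_allele_freq(M) -> float:
    """Allele-count estimate of the marker allele frequency, (sum M) / (2n)."""
    M = np.asarray(M)
    if M.size == 0:
        raise ValueError("cannot estimate an allele frequency from no genotypes")
    if not np.isin(M, (0, 1, 2)).all():
        raise ValueError("genotypes must be coded 0/1/2 (count of allele M)")
    return float(M.sum()) / (2.0 * M.size)


def fit_null(Y) -> NullModelFit:
    """Closed-form normal MLE (mean, divide-by-n standard deviation)."""
    Y = np.asarray(Y, dtype=float)
    if Y.size < 2:
        raise ValueError("need at least two observations")
    mu = float(Y.mean())
    sigma = float(Y.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("phenotype is constant: null-model sigma would be 0")
    n = Y.size
    loglik = -0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma) + 1.0)
    return NullModelFit(mu_hat=mu, sigma_hat=sigma, loglik=float(loglik))


# ---------------------------------------------------------------------------
# internals shared by the two mixture fits
# ---------------------------------------------------------------------------


def _normal_pdf(Y: np.ndarray, means: np.ndarray, sigma: float) -> np.ndarray:
    """(n, 3) matrix of normal densities, avoiding scipy call overhead."""
    z = (Y[:, None] - means[None, :]) / sigma
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sigma)


def _weights_for_qd(p: float, q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Conditional weight tensor W[k, m, g] for candidate vectors (q_k, t_k).

    ``t`` in [0, 1] parameterizes D linearly over its feasible range at
    (p, q_k), so every candidate is automatically feasible.
    """
    q = np.asarray(q, dtype=float)
    t = np.asarray(t, dtype=float)
    lo = np.maximum(-p * q, -(1.0 - p) * (1.0 - q))
    hi = np.minimum(p * (1.0 - q), (1.0 - p) * q)
    D = lo + t * (hi - lo)
    a = (p * q + D) / p  # P(A | M gamete)
    b = ((1.0 - p) * q - D) / (1.0 - p)  # P(A | m gamete)
    a = np.clip(a, 0.0, 1.0)
    b = np.clip(b, 0.0, 1.0)
    W = np.empty((q.size, 3, 3))
    W[:, 0, 0] = (1 - b) ** 2
    W[:, 0, 1] = 2 * b * (1 - b)
    W[:, 0, 2] = b**2
    W[:, 1, 0] = (1 - a) * (1 - b)
    W[:, 1, 1] = a * (1 - b) + (1 - a) * b
    W[:, 1, 2] = a * b
    W[:, 2, 0] = (1 - a) ** 2
    W[:, 2, 1] = 2 * a * (1 - a)
    W[:, 2, 2] = a**2
    return W


def _qd_from_t(p: float, q: float, t: float) -> float:
    lo, hi = feasible_D_range(p, q)
    return lo + t * (hi - lo)


def _update_qd(p: float, N: np.ndarray, q0: float, t0: float,
               grid_points: int, levels: int,
               half_width: float = 0.5) -> tuple[float, float]:
    """Maximize sum_{m,g} N[m,g] log W[m,g](q, D) by iterated grid refinement.

    N is the 3x3 posterior count table (rows: marker genotype, cols: QTL
    genotype).  The search window is centered on the incumbent with the
    given half-width (0.5 covers the whole parameter square); the incumbent
    is kept unless improved, which preserves the generalized-EM ascent
    property.
    """
    def score(qv: np.ndarray, tv: np.ndarray) -> np.ndarray:
        W = _weights_for_qd(p, qv, tv)
        return np.tensordot(np.log(np.clip(W, 1e-300, None)), N, axes=([1, 2], [0, 1]))

    qu, tu = _unit_grid(grid_points)
    best_q, best_t = q0, t0
    best_val = float(score(np.array([q0]), np.array([t0]))[0])
    q_half = t_half = half_width
    for level in range(levels):
        qq = np.clip(best_q + q_half * qu, _Q_BOUNDS[0], _Q_BOUNDS[1])
        tt = np.clip(best_t + t_half * tu, 0.0, 1.0)
        vals = score(qq, tt)
        k = int(np.argmax(vals))
        if vals[k] > best_val:
            best_val = float(vals[k])
            best_q = float(qq[k])
            best_t = float(tt[k])
        q_half /= 4.0
        t_half /= 4.0
    return best_q, best_t


_UNIT_GRIDS: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _unit_grid(grid_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened unit meshgrid over [-1,1]^2, cached by resolution."""
    if grid_points not in _UNIT_GRIDS:
        u = np.linspace(-1.0, 1.0, grid_points)
        qq, tt = np.meshgrid(u, u, indexing="ij")
        _UNIT_GRIDS[grid_points] = (qq.ravel().copy(), tt.ravel().copy())
    return _UNIT_GRIDS[grid_points]


def _make_starts(Y: np.ndarray, n_restarts: int, rng: np.random.Generator) -> list[dict]:
    """Start list covering the recurring mode families.

    Null-collapsed (guarantees nesting), quantile-spread means crossed with
    D signs, boundary-q starts whose rare component sits in a phenotype
    tail, and random-jitter fill-up.
    """
    ybar, sd = float(Y.mean()), float(Y.std(ddof=0))
    starts = [dict(mu=np.array([ybar, ybar, ybar]), sigma=sd, q=0.5, t=0.5)]
    quant_sets = [np.quantile(Y, [0.10, 0.50, 0.90]), np.quantile(Y, [0.25, 0.50, 0.75])]
    for mu in quant_sets:
        for t in (0.5, 0.9, 0.1):  # D = 0, near-upper, near-lower
            starts.append(dict(mu=mu.copy(), sigma=sd, q=0.5, t=t))
    lo_tail, med, hi_tail = np.quantile(Y, [0.01, 0.50, 0.99])
    starts.append(dict(mu=np.array([lo_tail, med, med]), sigma=sd, q=0.92, t=0.5))
    starts.append(dict(mu=np.array([med, med, hi_tail]), sigma=sd, q=0.08, t=0.5))
    while len(starts) < n_restarts:
        mu = np.sort(np.quantile(Y, rng.uniform(0.02, 0.98, size=3)))
        starts.append(dict(
            mu=mu, sigma=sd * rng.uniform(0.5, 1.2),
            q=float(rng.uniform(0.05, 0.95)), t=float(rng.uniform(0.05, 0.95)),
        ))
    return starts[:max(n_restarts, 1)]


def _em_run(Y: np.ndarray, counts_idx: list[np.ndarray], p: float, start: dict,
            cfg: EMConfig, sigma_floor: float, conditional: bool,
            tol: float, max_iter: int, global_period: int = 25,
            trace: list | None = None):
    """One EM run.  ``conditional=False`` gives the unlinked (marginal-weight) fit.

    The (q, D) sub-step searches the whole parameter square on the first
    sweep and every ``global_period`` sweeps; in between it refines a cheap
    local window around the incumbent.  Returns
    (loglik, params dict, n_iter, converged).
    """
    n = Y.size
    mu = np.asarray(start["mu"], dtype=float).copy()
    sigma = max(float(start["sigma"]), sigma_floor)
    q, t = float(start["q"]), float(start["t"])
    if not conditional:
        t = 0.5  # D identically 0: weights are marginal

    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        W = _weights_for_qd(p, np.array([q]), np.array([t]))[0]  # (3, 3)
        dens = _normal_pdf(Y, mu, sigma)
        # subject-specific weights via the marker genotype lookup
        R = np.empty((n, 3))
        for m, idx in enumerate(counts_idx):
            if idx.size:
                R[idx] = W[m] * dens[idx]
        mix = R.sum(axis=1)
        mix = np.clip(mix, 1e-300, None)
        ll = float(np.log(mix).sum())
        R /= mix[:, None]
        if trace is not None:
            trace.append(ll)

        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

        # M-step: means and common sigma (closed form)
        col = R.sum(axis=0)
        nonzero = col > 1e-12
        mu_new = mu.copy()
        mu_new[nonzero] = (R[:, nonzero] * Y[:, None]).sum(axis=0) / col[nonzero]
        resid2 = (Y[:, None] - mu_new[None, :]) ** 2
        sigma = max(float(np.sqrt((R * resid2).sum() / n)), sigma_floor)
        mu = mu_new

        if conditional:
            # posterior counts by marker genotype, then (q, D) grid ascent:
            # a global window on the first sweep, a cheap local window after
            N = np.vstack([R[idx].sum(axis=0) if idx.size else np.zeros(3)
                           for idx in counts_idx])
            if it == 1 or (global_period and it % global_period == 0):
                q, t = _update_qd(p, N, q, t, cfg.grid_points,
                                  cfg.refine_levels, half_width=0.5)
            elif it % 2 == 0:  # weights drift slowly; alternate sweeps suffice
                q, t = _update_qd(p, N, q, t, 7, 2, half_width=0.05)
        else:
            # closed-form HWE M-step: q = (N_Aa + 2 N_AA) / 2n
            colsum = R.sum(axis=0)
            q = float(np.clip((colsum[1] + 2.0 * colsum[2]) / (2.0 * n),
                              _Q_BOUNDS[0], _Q_BOUNDS[1]))

    params = dict(mu=mu, sigma=sigma, q=q, t=t)
    return ll, params, it, converged


def _observed_loglik(theta: np.ndarray, Y: np.ndarray, counts_idx: list[np.ndarray],
                     p: float, sigma_floor: float) -> float:
    mu = theta[:3]
    sigma = max(theta[3], sigma_floor)
    q = float(np.clip(theta[4], *_Q_BOUNDS))
    t = float(np.clip(theta[5], 0.0, 1.0))
    W = _weights_for_qd(p, np.array([q]), np.array([t]))[0]
    dens = _normal_pdf(Y, mu, sigma)
    ll = 0.0
    for m, idx in enumerate(counts_idx):
        if idx.size:
            ll += float(np.log(np.clip(dens[idx] @ W[m], 1e-300, None)).sum())
    return ll


def fit_full_em(Y, M, config: EMConfig | None = None, seed: int | None = None) -> FullModelFit:
    """Fit the linked-QTL mixture by restarted generalized EM.

    ``p`` is fixed at the allele-count estimate; (q, D, mu1..3, sigma) are
    estimated.  Raises :class:`MonomorphicMarkerError` when the marker shows
    a single genotype (T_D is undefined there).
    """
    cfg = config or EMConfig()
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(M, dtype=int)
    if Y.shape != M.shape or Y.ndim != 1:
        raise ValueError("Y and M must be 1-D arrays of equal length")
    if Y.size < 10:
        raise ValueError("need at least 10 observations for a mixture fit")
    p = estimate_marker_allele_freq(M)
    if p in (0.0, 1.0) or len(np.unique(M)) == 1:
        raise MonomorphicMarkerError(
            f"marker is monomorphic (p_hat={p}); D and T_D are undefined"
        )
    rng = np.random.default_rng(seed)
    counts_idx = [np.flatnonzero(M == m) for m in (0, 1, 2)]
    sigma_floor = cfg.sigma_floor_frac * float(Y.std(ddof=0))

    starts = _make_starts(Y, cfg.n_restarts, rng)
    total_iter = 0

    # stage 1: cheap exploration of every start
    explored = []
    for start in starts:
        ll, params, it, _ = _em_run(Y, counts_idx, p, start, cfg, sigma_floor,
                                    True, tol=1e-5, max_iter=cfg.stage1_iters)
        total_iter += it
        explored.append((ll, params))
    explored.sort(key=lambda e: e[0], reverse=True)

    # stage 2: run the best few to convergence, then polish each
    best = None
    for ll0, params0 in explored[: max(cfg.n_keep, 1)]:
        ll, params, it, conv = _em_run(Y, counts_idx, p, params0, cfg,
                                       sigma_floor, True, tol=cfg.tol,
                                       max_iter=cfg.max_iter)
        total_iter += it
        if cfg.polish:
            theta0 = np.array([*params["mu"], params["sigma"], params["q"],
                               params["t"]])
            res = minimize(
                lambda th: -_observed_loglik(th, Y, counts_idx, p, sigma_floor),
                theta0, method="L-BFGS-B",
                bounds=[(None, None)] * 3 + [(sigma_floor, None), _Q_BOUNDS,
                                             (0.0, 1.0)],
            )
            if -res.fun > ll:
                ll = float(-res.fun)
                params = dict(mu=res.x[:3],
                              sigma=float(max(res.x[3], sigma_floor)),
                              q=float(np.clip(res.x[4], *_Q_BOUNDS)),
                              t=float(np.clip(res.x[5], 0.0, 1.0)))
        if best is None or ll > best[0]:
            best = (ll, params, conv)
    ll, params, conv = best

    D = _qd_from_t(p, params["q"], params["t"])
    return FullModelFit(
        p_hat=p, q_hat=params["q"], D_hat=D,
        mu1_hat=float(params["mu"][0]), mu2_hat=float(params["mu"][1]),
        mu3_hat=float(params["mu"][2]), sigma_hat=params["sigma"],
        loglik=ll, n_iter=total_iter, converged=conv, n_restarts=len(starts),
    )


def fit_unlinked_em(Y, config: EMConfig | None = None, seed: int | None = None) -> UnlinkedModelFit:
    """Fit the unlinked 3-component mixture with HWE weights ((1-q)^2, 2q(1-q), q^2)."""
    cfg = config or EMConfig()
    Y = np.asarray(Y, dtype=float)
    if Y.size < 10:
        raise ValueError("need at least 10 observations for a mixture fit")
    rng = np.random.default_rng(seed)
    # marginal weights == conditional weights at D=0, any p; reuse the machinery
    # with all individuals sharing one marker class
    counts_idx = [np.arange(Y.size), np.array([], dtype=int), np.array([], dtype=int)]
    sigma_floor = cfg.sigma_floor_frac * float(Y.std(ddof=0))

    best = None
    total_iter = 0
    starts = _make_starts(Y, cfg.n_restarts, rng)
    for start in starts:
        ll, params, it, conv = _em_run(Y, counts_idx, 0.5, start, cfg,
                                       sigma_floor, False, tol=cfg.tol,
                                       max_iter=cfg.max_iter)
        total_iter += it
        if best is None or ll > best[0]:
            best = (ll, params, conv)
    ll, params, conv = best
    return UnlinkedModelFit(
        q_hat=params["q"],
        mu1_hat=float(params["mu"][0]), mu2_hat=float(params["mu"][1]),
        mu3_hat=float(params["mu"][2]), sigma_hat=params["sigma"],
        loglik=ll, n_iter=total_iter, converged=conv, n_restarts=len(starts),
    )
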