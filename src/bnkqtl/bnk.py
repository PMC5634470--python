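"""The bivariate null kernel (BNK) test for one marker.

The joint null distribution of the statistic pair (T_L, T_D) is unknown and
poorly approximated by chi-square marginals, so it is estimated directly:

1. simulate ``k`` null datasets (phenotype and marker independent) and
   compute the statistic pair for each;
2. fit a 2-D Gaussian product-kernel density f-hat to the k pairs, with
   axis-wise bandwidths (T_L and T_D live on very different scales);
3. choose the bandwidth so the size of the test is maximal while staying at
   or below the significance level alpha;
4. tabulate the level-set CDF F-hat(c) = integral of f-hat over
   {f-hat >= c};
5. the joint p-value of an observed pair (t*, u*) is
   1 - F-hat(f-hat(t*, u*)) — the estimated null mass of the
   highest-density region through the observed point, so points at the mode
   get p near 1 and points far outside the null cloud get p near 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimation import EMConfig, MonomorphicMarkerError
from .statistics import BivariateStatistic, bivariate_statistic

__all__ = [
    "NullKernel",
    "simulate_null_pairs",
    "fit_null_kernel",
    "select_bandwidth",
    "build_null_kernel",
    "kernel_cdf",
    "bnk_pvalue",
    "normal_reference_bandwidth",
]

DEFAULT_MULTIPLIERS = (0.5, 0.75, 1.0, 1.5, 2.0, 3.0)


@dataclass
class NullKernel:
    """Fitted 2-D kernel estimate of the joint null of a statistic pair.

    Stores the simulated null pairs, the product-Gaussian bandwidth per
    axis, the density on a regular grid (padded 3 bandwidths beyond the
    pairs), and the level-set CDF table used for highest-density-region
    p-values.
    """

    pairs: np.ndarray  # (k, 2)
    bandwidth: np.ndarray  # (2,)
    grid_x: np.ndarray  # (gx,)
    grid_y: np.ndarray  # (gy,)
    density: np.ndarray  # (gx, gy)
    alpha: float | None = None
    seed: int | None = None
    # level-set CDF table: densities ascending + null mass of {f >= level}
    _levels: np.ndarray = field(default=None, repr=False)
    _mass_ge: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float)
        self.bandwidth = np.asarray(self.bandwidth, dtype=float)
        if self._levels is None:
            area = self.cell_area
            flat = np.sort(self.density.ravel())  # ascending
            # mass of cells with density >= each level (inclusive ties)
            mass_from_top = np.cumsum(flat[::-1]) * area
            self._levels = flat
            self._mass_ge = mass_from_top[::-1]

    @property
    def k(self) -> int:
        return self.pairs.shape[0]

    @property
    def cell_area(self) -> float:
        dx = float(self.grid_x[1] - self.grid_x[0])
        dy = float(self.grid_y[1] - self.grid_y[0])
        return dx * dy

    @property
    def total_mass(self) -> float:
        """Riemann-sum mass of the density grid (near 1 by construction)."""
        return float(self.density.sum() * self.cell_area)

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the grid density; 0 outside the grid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = pts[:, 0], pts[:, 1]
        gx, gy = self.grid_x, self.grid_y
        inside = (x >= gx[0]) & (x <= gx[-1]) & (y >= gy[0]) & (y <= gy[-1])
        out = np.zeros(pts.shape[0])
        if inside.any():
            xi = np.clip(np.searchsorted(gx, x[inside]) - 1, 0, gx.size - 2)
            yi = np.clip(np.searchsorted(gy, y[inside]) - 1, 0, gy.size - 2)
            fx = (x[inside] - gx[xi]) / (gx[xi + 1] - gx[xi])
            fy = (y[inside] - gy[yi]) / (gy[yi + 1] - gy[yi])
            d = self.density
            out[inside] = (
                d[xi, yi] * (1 - fx) * (1 - fy)
                + d[xi + 1, yi] * fx * (1 - fy)
                + d[xi, yi + 1] * (1 - fx) * fy
                + d[xi + 1, yi + 1] * fx * fy
            )
        return out

    def cdf(self, c) -> np.ndarray | float:
        """F-hat(c): grid mass of the region {f-hat >= c} (inclusive)."""
        c_arr = np.atleast_1d(np.asarray(c, dtype=float))
        if (c_arr < 0).any():
            raise ValueError("density level must be non-negative")
        idx = np.searchsorted(self._levels, c_arr, side="left")
        out = np.where(idx < self._levels.size, self._mass_ge[np.minimum(idx, self._levels.size - 1)], 0.0)
        return out if np.ndim(c) else float(out[0])

    def pvalue(self, observed) -> np.ndarray | float:
        """Joint HDR p-value 1 - F-hat(f-hat(t*, u*)) for observed pair(s)."""
        if isinstance(observed, BivariateStatistic):
            pts = np.array([[observed.T_L, observed.T_D]])
            scalar = True
        else:
            pts = np.atleast_2d(np.asarray(observed, dtype=float))
            scalar = pts.shape[0] == 1 and np.asarray(observed).ndim == 1
        levels = self.density_at(pts)
        p = np.clip(1.0 - self.cdf(levels), 0.0, 1.0)
        # outside the padded grid the estimated density is 0: maximally
        # extreme, p exactly 0 (the grid's ~1% mass deficit must not leak in)
        p = np.where(levels == 0.0, 0.0, p)
        return float(p[0]) if scalar else p

    def to_dict(self) -> dict:
        """Portable container (JSON-serializable) for reuse across markers."""
        return {
            "pairs": self.pairs.tolist(),
            "bandwidth": self.bandwidth.tolist(),
            "grid_x": self.grid_x.tolist(),
            "grid_y": self.grid_y.tolist(),
            "density": self.density.tolist(),
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NullKernel":
        return cls(
            pairs=np.array(d["pairs"]),
            bandwidth=np.array(d["bandwidth"]),
            grid_x=np.array(d["grid_x"]),
            grid_y=np.array(d["grid_y"]),
            density=np.array(d["density"]),
            alpha=d.get("alpha"),
            seed=d.get("seed"),
        )


def normal_reference_bandwidth(pairs: np.ndarray) -> np.ndarray:
    """Scott's rule per axis for a 2-D sample: sigma_j * k^(-1/6)."""
    pairs = np.asarray(pairs, dtype=float)
    k = pairs.shape[0]
    sd = pairs.std(axis=0, ddof=1)
    return sd * k ** (-1.0 / 6.0)


def simulate_null_pairs(
    n: int,
    p: float,
    mu: float,
    sigma: float,
    k: int,
    seed: int | None = None,
    config: EMConfig | None = None,
    convention: str = "2lnL",
) -> np.ndarray:
    """Simulate k null datasets and return their (T_L, T_D) pairs, shape (k, 2).

    Each dataset draws Y* ~ Normal(mu, sigma^2) of length n and an
    independent HWE marker at allele frequency p (per-individual genotype =
    Binomial(2, p)).  Monomorphic marker draws are redrawn, since T_D is
    undefined for them.
    """
    if k < 100:
        raise ValueError("need at least 100 null replicates for a stable kernel")
    if k < 500:
        warnings.warn(f"k={k} null replicates is low; 500+ recommended", stacklevel=2)
    if not (sigma > 0 and 0 < p < 1 and n >= 10):
        raise ValueError("require sigma > 0, p in (0,1) and n >= 10")
    rng = np.random.default_rng(seed)
    pairs = np.empty((k, 2))
    for i in range(k):
        Y = rng.normal(mu, sigma, size=n)
        M = rng.binomial(2, p, size=n)
        while len(np.unique(M)) == 1:  # redraw monomorphic replicates
            M = rng.binomial(2, p, size=n)
        em_seed = int(rng.integers(0, 2**31 - 1))
        stat = bivariate_statistic(Y, M, config=config, seed=em_seed,
                                   convention=convention)
        pairs[i] = (stat.T_L, stat.T_D)
    return pairs


def fit_null_kernel(
    pairs: np.ndarray,
    bandwidth,
    grid_size: int = 256,
    padding: float = 3.0,
    alpha: float | None = None,
    seed: int | None = None,
) -> NullKernel:
    """Gaussian product-kernel density of the null pairs on a regular grid.

    The grid covers the pairs padded by ``padding`` bandwidths per axis, so
    the Riemann-sum mass is near 1.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be a (k, 2) array")
    if pairs.shape[0] < 100:
        raise ValueError("need at least 100 null pairs")
    h = np.broadcast_to(np.asarray(bandwidth, dtype=float).ravel(), (2,)).copy()
    if (h <= 0).any():
        raise ValueError("bandwidths must be positive")
    if (pairs.std(axis=0) == 0).any():
        raise ValueError("degenerate null pairs: zero variance in a coordinate")
    lo = pairs.min(axis=0) - padding * h
    hi = pairs.max(axis=0) + padding * h
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    k = pairs.shape[0]
    # product kernel: density grid = (Ax @ Ay.T) / k with per-axis Gaussians
    ax = _gauss_cols(gx, pairs[:, 0], h[0])  # (grid_size, k)
    ay = _gauss_cols(gy, pairs[:, 1], h[1])
    density = (ax @ ay.T) / k
    return NullKernel(pairs=pairs, bandwidth=h, grid_x=gx, grid_y=gy,
                      density=density, alpha=alpha, seed=seed)


def _gauss_cols(grid: np.ndarray, centers: np.ndarray, h: float) -> np.ndarray:
    z = (grid[:, None] - centers[None, :]) / h
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * h)


def select_bandwidth(
    pairs: np.ndarray,
    alpha: float = 0.05,
    multipliers=DEFAULT_MULTIPLIERS,
    grid_size: int = 256,
) -> np.ndarray:
    """Size-constrained bandwidth selection.

    Candidates are ``multipliers`` times the normal-reference bandwidth per
    axis.  For each candidate the size of the test is estimated on the null
    pairs themselves with a leave-one-out correction: the density level at
    pair i excludes pair i's own kernel spike (a plain in-sample estimate is
    optimistic — every pair inflates its own density — and under-controls
    the realized type I error).  The candidate maximizing the estimated
    size subject to size <= alpha is returned; ties break toward the larger
    (more conservative) bandwidth.  If no candidate satisfies the
    constraint, the largest is returned with a warning.  The procedure is
    deterministic given the pairs.
    """
    if not 0.0 < alpha <= 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5], got {alpha}")
    base = normal_reference_bandwidth(pairs)
    mults = np.sort(np.asarray(multipliers, dtype=float))
    k = pairs.shape[0]
    sizes = np.empty(mults.size)
    for j, m in enumerate(mults):
        h = m * base
        kern = fit_null_kernel(pairs, h, grid_size=grid_size)
        self_dens = 1.0 / (2.0 * np.pi * h[0] * h[1])
        loo_levels = np.maximum(
            (k * kern.density_at(pairs) - self_dens) / (k - 1), 0.0
        )
        pvals = np.clip(1.0 - kern.cdf(loo_levels), 0.0, 1.0)
        sizes[j] = float(np.mean(pvals < alpha))
    ok = sizes <= alpha
    if not ok.any():
        warnings.warn(
            "no candidate bandwidth achieved size <= alpha; returning the "
            "largest candidate (oversmoothing is conservative)",
            stacklevel=2,
        )
        return mults[-1] * base
    best_size = sizes[ok].max()
    # ties toward larger bandwidth: last index attaining the best size
    j = int(np.flatnonzero(ok & (sizes == best_size))[-1])
    return mults[j] * base


def build_null_kernel(
    pairs: np.ndarray,
    alpha: float = 0.05,
    multipliers=DEFAULT_MULTIPLIERS,
    grid_size: int = 256,
    seed: int | None = None,
) -> NullKernel:
    """Select the size-constrained bandwidth and fit the null kernel."""
    h = select_bandwidth(pairs, alpha=alpha, multipliers=multipliers,
                         grid_size=grid_size)
    return fit_null_kernel(pairs, h, grid_size=grid_size, alpha=alpha, seed=seed)


def kernel_cdf(kernel: NullKernel, c: float) -> float:
    """F-hat(c): null mass of the highest-density region {f-hat >= c}."""
    return kernel.cdf(c)


def bnk_pvalue(kernel: NullKernel, observed) -> float:
    """HDR joint p-value of an observed (T_L, T_D) pair under the kernel."""
    return kernel.pvalue(observed)
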