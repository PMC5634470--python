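"""Genome-wide BNK scan: allele-frequency packets, shared kernels, Holm.

Marker allele frequencies across a genome span (0, 1), and the null of
(T_L, T_D) depends on the allele frequency, so markers are grouped into 20
right-closed frequency bins ("packets") of width 0.05.  One null kernel is
simulated per occupied packet — at the packet's mean allele frequency and
the observed phenotype's moments — and every member marker is scored
against it.  The per-marker joint p-values are then Holm-adjusted to control
the family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bnk import NullKernel, build_null_kernel, simulate_null_pairs
from .estimation import EMConfig, MonomorphicMarkerError
from .statistics import bivariate_statistic

__all__ = [
    "PacketAssignment",
    "GenomeScanResult",
    "assign_packets",
    "holm_adjust",
    "scan_genome",
]

N_PACKETS = 20
_BIN_WIDTH = 0.05


@dataclass(frozen=True)
class PacketAssignment:
    """Per-marker packet index (1..20; 0 = unassigned/monomorphic) and
    per-packet mean estimated allele frequency."""

    packet: np.ndarray  # (P,) int
    packet_mean_freq: dict[int, float]


@dataclass
class GenomeScanResult:
    """Scan output: one row per input marker, plus the packet kernels used."""

    table: pd.DataFrame
    kernels: dict[int, NullKernel]
    alpha: float
    seed: int | None


def assign_packets(p_hat) -> PacketAssignment:
    """Bin markers by estimated allele frequency into 20 right-closed bins.

    Bins are (0, 0.05], (0.05, 0.10], ..., (0.95, 1]; a frequency exactly on
    an edge belongs to the lower packet (right-closed).  Monomorphic markers
    (p-hat 0 or 1) are flagged unassigned with packet index 0.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    if ((p_hat < 0) | (p_hat > 1)).any():
        raise ValueError("allele frequencies must lie in [0,1]")
    # round before ceil so that e.g. 0.10/0.05 = 2.0000000000000004 bins as 2
    packet = np.where(
        (p_hat > 0) & (p_hat < 1),
        np.ceil(np.round(p_hat / _BIN_WIDTH, 9)).astype(int),
        0,
    )
    packet = np.where(p_hat == 1.0, 0, packet)
    means = {
        int(b): float(p_hat[packet == b].mean())
        for b in np.unique(packet)
        if b > 0
    }
    return PacketAssignment(packet=packet, packet_mean_freq=means)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sort ascending, multiply the i-th smallest by (m - i + 1), enforce the
    running maximum, cap at 1, and restore the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def scan_genome(
    Y,
    M,
    marker_ids=None,
    marker_map: pd.DataFrame | None = None,
    alpha: float = 0.05,
    k: int = 1000,
    seed: int | None = None,
    config: EMConfig | None = None,
    per_marker: bool = False,
    grid_size: int = 256,
    convention: str = "2lnL",
    kernels: dict[int, NullKernel] | None = None,
    verbose: bool = False,
) -> GenomeScanResult:
    """Genome-wide BNK with packet-shared null kernels and Holm adjustment.

    Parameters
    ----------
    Y
        Phenotype vector, length n.
    M
        Genotype matrix (n x P) coded 0/1/2; NaN marks a missing genotype
        (complete-case per marker).
    marker_map
        Optional frame with columns (marker, chrom, pos) merged into the
        output.
    per_marker
        Build one kernel per marker at its own allele frequency instead of
        per packet (much slower; the packet approximation is the default).
    kernels
        Pre-computed packet kernels keyed by packet index, bypassing
        simulation (used to prove order-invariance and for reuse).

    Per-marker estimation failures are recorded in the ``status`` column
    (ok / monomorphic / non-converged); they never abort the scan.
    Markers that cannot be tested get raw and adjusted p-value 1, and the
    Holm family size m is the number of markers actually tested.
    """
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != Y.size:
        raise ValueError("M must be an (n, P) matrix aligned with Y")
    n, P = M.shape
    if marker_ids is None:
        marker_ids = [f"m{j + 1}" for j in range(P)]

    # per-marker allele frequency on complete cases
    p_hat = np.empty(P)
    for j in range(P):
        col = M[:, j]
        obs = col[~np.isnan(col)]
        p_hat[j] = np.nan if obs.size == 0 else obs.sum() / (2.0 * obs.size)
    assignment = assign_packets(np.nan_to_num(p_hat, nan=0.0))
    packet = assignment.packet

    ybar, ysd = float(Y.mean()), float(Y.std(ddof=0))
    root = np.random.SeedSequence(seed)
    # one child seed stream per packet index: results do not depend on the
    # order in which packets are processed
    packet_seeds = {b: root.spawn(N_PACKETS + 1)[b] for b in range(N_PACKETS + 1)}

    built_kernels: dict[int, NullKernel] = dict(kernels or {})

    def packet_kernel(b: int, freq: float) -> NullKernel:
        if b in built_kernels:
            return built_kernels[b]
        ss = packet_seeds[b]
        kern_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        if verbose:
            print(f"[bnkqtl] packet {b}: simulating {k} null pairs at "
                  f"p={freq:.3f}, n={n}")
        pairs = simulate_null_pairs(n, freq, ybar, ysd, k, seed=kern_seed,
                                    config=config, convention=convention)
        kern = build_null_kernel(pairs, alpha=alpha, grid_size=grid_size,
                                 seed=kern_seed)
        built_kernels[b] = kern
        if verbose:
            print(f"[bnkqtl] packet {b}: bandwidth {kern.bandwidth}")
        return kern

    rows = []
    marker_seed_root = root.spawn(1)[0]
    marker_seeds = marker_seed_root.generate_state(P) % (2**31 - 1)
    for j in range(P):
        rec = dict(marker=marker_ids[j], p_hat=p_hat[j], packet=int(packet[j]),
                   T_L=np.nan, T_D=np.nan, pvalue=1.0, status="ok")
        col = M[:, j]
        mask = ~np.isnan(col)
        if packet[j] == 0:
            rec["status"] = "monomorphic"
            rows.append(rec)
            continue
        try:
            stat, fit = bivariate_statistic(
                Y[mask], col[mask].astype(int), config=config,
                seed=int(marker_seeds[j]), convention=convention,
                return_fit=True,
            )
        except MonomorphicMarkerError:
            rec["status"] = "monomorphic"
            rows.append(rec)
            continue
        if per_marker:
            pairs = simulate_null_pairs(
                int(mask.sum()), float(p_hat[j]), ybar, ysd, k,
                seed=int(marker_seeds[j]), config=config, convention=convention)
            kern = build_null_kernel(pairs, alpha=alpha, grid_size=grid_size)
        else:
            kern = packet_kernel(int(packet[j]),
                                 assignment.packet_mean_freq[int(packet[j])])
        rec["T_L"], rec["T_D"] = stat.T_L, stat.T_D
        rec["pvalue"] = float(kern.pvalue(stat))
        if not fit.converged:
            rec["status"] = "non-converged"
        rows.append(rec)

    table = pd.DataFrame(rows)
    tested = table["status"] != "monomorphic"
    adj = np.ones(P)
    if tested.any():
        adj[tested.to_numpy()] = holm_adjust(table.loc[tested, "pvalue"].to_numpy())
    table["pvalue_holm"] = adj
    if marker_map is not None:
        table = table.merge(marker_map, on="marker", how="left")
        cols = ["marker", "chrom", "pos"] + [c for c in table.columns
                                             if c not in ("marker", "chrom", "pos")]
        table = table[cols]
    return GenomeScanResult(table=table, kernels=built_kernels, alpha=alpha,
                            seed=seed)
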