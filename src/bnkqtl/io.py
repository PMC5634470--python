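"""Tabular input/output for genome scans.

Native dialect is plain CSV/TSV (delimiter inferred from the file
extension): a phenotype file with one numeric column, a genotype file with a
header row of marker IDs and entries in {0, 1, 2, NA}, and an optional map
file with columns (marker, chrom, pos).  Missing genotypes are coded "NA"
and handled complete-case per marker downstream.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_dataset", "write_dataset", "write_results", "write_sidecar"]

_MISSING = "NA"


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_dataset(phenotype_path, genotype_path, map_path=None):
    """Read aligned phenotype/genotype (and optional map) files.

    Returns ``(Y, M, marker_ids, marker_map)`` where M is an (n, P) float
    matrix with NaN for missing genotypes.  Errors cite the offending
    row/column.
    """
    pheno = pd.read_csv(phenotype_path, sep=_sep(phenotype_path))
    if pheno.shape[1] != 1:
        raise ValueError(
            f"{phenotype_path}: expected a single phenotype column, got "
            f"{pheno.shape[1]}"
        )
    col = pheno.columns[0]
    if not np.issubdtype(pheno[col].dtype, np.number):
        bad = pheno.index[pd.to_numeric(pheno[col], errors="coerce").isna()][0]
        raise ValueError(f"{phenotype_path}: non-numeric phenotype at row {bad + 1}")
    Y = pheno[col].to_numpy(dtype=float)

    geno = pd.read_csv(genotype_path, sep=_sep(genotype_path),
                       na_values=[_MISSING], keep_default_na=True)
    marker_ids = list(geno.columns)
    M = geno.to_numpy(dtype=float)
    valid = np.isnan(M) | np.isin(M, (0.0, 1.0, 2.0))
    if not valid.all():
        r, c = np.argwhere(~valid)[0]
        raise ValueError(
            f"{genotype_path}: invalid genotype code {M[r, c]!r} at "
            f"(row {r + 1}, col {marker_ids[c]!r}); expected 0/1/2/NA"
        )
    if M.shape[0] != Y.size:
        raise ValueError(
            f"dimension mismatch: {Y.size} phenotypes vs {M.shape[0]} "
            "genotype rows"
        )

    marker_map = None
    if map_path is not None:
        marker_map = pd.read_csv(map_path, sep=_sep(map_path))
        need = {"marker", "chrom", "pos"}
        if not need.issubset(marker_map.columns):
            raise ValueError(f"{map_path}: map file needs columns {sorted(need)}")
        unknown = set(marker_map["marker"]) - set(marker_ids)
        if unknown:
            import warnings

            warnings.warn(
                f"{map_path}: {len(unknown)} map marker IDs not in the "
                f"genotype file (e.g. {sorted(unknown)[:3]}); their positions "
                "are ignored",
                stacklevel=2,
            )
            marker_map = marker_map[marker_map["marker"].isin(marker_ids)]
    return Y, M, marker_ids, marker_map


def write_dataset(prefix, Y, M, marker_ids=None, marker_map=None,
                  fmt: str = "csv"):
    """Write phenotype/genotype (and optional map) files; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if fmt == "tsv" else ","
    M = np.asarray(M)
    if marker_ids is None:
        marker_ids = [f"m{j + 1}" for j in range(M.shape[1])]
    pheno_path = prefix.with_suffix(f".pheno.{fmt}")
    geno_path = prefix.with_suffix(f".geno.{fmt}")
    pd.DataFrame({"phenotype": Y}).to_csv(pheno_path, sep=sep, index=False)
    geno = pd.DataFrame(M, columns=marker_ids)
    # keep integer rendering for observed genotypes, NA for missing
    geno.to_csv(geno_path, sep=sep, index=False, na_rep=_MISSING,
                float_format="%.0f")
    paths = [pheno_path, geno_path]
    if marker_map is not None:
        map_path = prefix.with_suffix(f".map.{fmt}")
        marker_map.to_csv(map_path, sep=sep, index=False)
        paths.append(map_path)
    return paths


def write_results(path, table: pd.DataFrame) -> None:
    """Write the per-marker scan table as TSV.

    Floats use the shortest round-trippable representation; re-reading with
    ``pd.read_csv(..., float_precision="round_trip")`` reproduces every
    numeric column bit-exactly.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def write_sidecar(path, config: dict, seed, runtime_s: float | None = None) -> None:
    """Reproducibility sidecar: config, seed, versions, runtime."""
    import bnkqtl

    payload = {
        "config": config,
        "seed": seed,
        "runtime_s": runtime_s,
        "versions": {
            "bnkqtl": bnkqtl.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
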