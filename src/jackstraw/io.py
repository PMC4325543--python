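"""Delimited-text readers and writers for matrices and results."""

from __future__ import annotations

import gzip
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import JackstrawResult
from .fdr import FDRResult
from .pca import ExpressionMatrix

__all__ = ["read_matrix", "write_matrix", "write_results", "matrix_to_frame"]

_SEPARATORS = {"tsv": "\t", "csv": ","}


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _SEPARATORS:
            raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
        return fmt
    return "csv" if str(path).endswith(".csv") else "tsv"


def matrix_to_frame(M: ExpressionMatrix) -> pd.DataFrame:
    return pd.DataFrame(M.values, index=list(M.row_ids), columns=list(M.col_ids))


def read_matrix(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a labeled variables-by-observations matrix from TSV/CSV.

    The first column holds row ids and the header row column ids.  Any
    non-numeric or missing cell is reported with its row/column labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = _SEPARATORS[_infer_format(path, fmt)]
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row label {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column label {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    # convert from the raw strings (not pd.to_numeric's parse, which can be
    # a ulp off) so that write -> read round-trips bit-exactly
    return ExpressionMatrix(
        df.astype(float).to_numpy(), tuple(df.index), tuple(df.columns)
    )


def write_matrix(M: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    sep = _SEPARATORS[_infer_format(path, fmt)]
    matrix_to_frame(M).to_csv(path, sep=sep, float_format="%.17g")


def write_results(
    result: JackstrawResult,
    fdr: FDRResult,
    prefix: str | Path,
    row_ids: tuple[str, ...] | None = None,
    write_null_pool: bool = False,
    extra_meta: dict | None = None,
) -> dict[str, Path]:
    """Write the per-variable table, run metadata and optionally the null pool.

    Produces ``<prefix>.stats.tsv`` (row id, observed F, p-value, q-value,
    significance flag), ``<prefix>.meta.json`` (configuration, seed,
    pi0 estimate, versions) and, on request, ``<prefix>.null.tsv.gz``.
    Numbers are serialized at full precision so reruns diff cleanly.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    m = result.m
    if len(fdr.qvalues) != m:
        raise ValueError("result and FDR vectors have different lengths")
    if row_ids is None:
        row_ids = tuple(f"var{i}" for i in range(m))
    stats_path = prefix.parent / (prefix.name + ".stats.tsv")
    pd.DataFrame(
        {
            "row_id": list(row_ids),
            "observed_f": result.observed_f,
            "pvalue": result.pvalues,
            "qvalue": fdr.qvalues,
            "significant": fdr.significant,
        }
    ).to_csv(stats_path, sep="\t", index=False, float_format="%.17g")

    meta_path = prefix.parent / (prefix.name + ".meta.json")
    meta = {
        "m": m,
        "n_null_statistics": int(result.null_f.size),
        "s": result.config.s,
        "B": result.config.B,
        "seed": result.config.seed,
        "pseudo_count": result.config.pseudo_count,
        "r": result.spec.r,
        "subset": list(result.spec.subset),
        "rotation": result.spec.rotation.tolist() if result.spec.rotation is not None else None,
        "pi0_hat": fdr.pi0_hat,
        "fdr_level": fdr.fdr_level,
        "n_significant": int(fdr.significant.sum()),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra_meta:
        meta.update(extra_meta)
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")

    paths = {"stats": stats_path, "meta": meta_path}
    if write_null_pool:
        null_path = prefix.parent / (prefix.name + ".null.tsv.gz")
        with gzip.open(null_path, "wt") as fh:
            fh.write("iteration\tnull_f\n")
            s = result.config.s
            for j, value in enumerate(result.null_f):
                fh.write(f"{j // s}\t{value:.17g}\n")
        paths["null"] = null_path
    return paths
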