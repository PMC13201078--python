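"""Readers and writers for expression, covariate and result tables.

Expression tables are genes x samples, either plain TSV with a header row
of sample ids or GCT 1.2 (version line ``#1.2``, dimension line, ``Name``
and ``Description`` columns). Covariates are samples x covariates TSV.
"""

from __future__ import annotations

import logging
import os
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CovariateTable, ExpressionMatrix, PairedDataset, Stage

__all__ = [
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "align_paired",
]

logger = logging.getLogger("bloodbrain")


def _validate_numeric(df: pd.DataFrame, path: str) -> np.ndarray:
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.flatnonzero(bad.to_numpy())[0]]
                raise ValueError(
                    f"{path}: non-numeric value at gene {row!r}, "
                    f"sample {col!r}") from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing value at gene {df.index[i]!r}, "
                         f"sample {df.columns[j]!r}")
    return values


def _check_duplicates(ids: Iterable[str], what: str, path: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"{path}: duplicate {what} ids: {dups[:10]}")


def read_expression(path: str, format: str | None = None,
                    stage: Stage | str = Stage.RAW_COUNTS) -> ExpressionMatrix:
    """Read a genes x samples expression table from TSV or GCT 1.2.

    ``format`` is inferred from the extension when omitted. The returned
    matrix is tagged ``raw_counts`` unless ``stage`` says otherwise.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "gct" if str(path).lower().endswith(".gct") else "tsv"
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"{path}: expected GCT version line '#1.2', "
                                 f"got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ValueError(f"{path}: malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
        if "Description" not in df.columns:
            raise ValueError(f"{path}: GCT is missing the Description column")
        df = df.drop(columns=["Description"])
        if df.shape != (n_genes, n_samples):
            raise ValueError(
                f"{path}: GCT dimension line declares {n_genes} x {n_samples} "
                f"but the table holds {df.shape[0]} x {df.shape[1]}")
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_duplicates(df.index, "gene", path)
    _check_duplicates(df.columns, "sample", path)
    values = _validate_numeric(df, path)
    return ExpressionMatrix(list(df.index), list(df.columns), values,
                            Stage(stage))


def write_expression(expr: ExpressionMatrix, path: str,
                     format: str | None = None) -> None:
    """Write an expression matrix as TSV or GCT 1.2 (full float precision)."""
    if format is None:
        format = "gct" if str(path).lower().endswith(".gct") else "tsv"
    df = expr.to_frame()
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", expr.gene_ids)
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format="%.17g")
    elif format == "tsv":
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_covariates(path: str) -> CovariateTable:
    """Read a samples x covariates TSV (sample ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    _check_duplicates(df.index, "sample", path)
    return CovariateTable.from_frame(df)


def write_covariates(cov: CovariateTable, path: str) -> None:
    df = cov.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def align_paired(blood: ExpressionMatrix, brain: ExpressionMatrix,
                 cov: CovariateTable, age: np.ndarray | dict | None = None,
                 tissue_label: str = "brain") -> PairedDataset:
    """Restrict blood, brain and covariates to their shared samples.

    Samples are put in a canonical lexicographic order so the result does
    not depend on input ordering. Dropped samples are reported per input
    via warnings.
    """
    sets = {
        "blood": set(blood.sample_ids),
        "brain": set(brain.sample_ids),
        "covariates": set(cov.sample_ids),
    }
    shared = sets["blood"] & sets["brain"] & sets["covariates"]
    if not shared:
        raise ValueError("no samples shared between blood, brain and "
                         "covariate tables")
    order = sorted(shared)
    for name, ids in sets.items():
        dropped = sorted(ids - shared)
        if dropped:
            warnings.warn(f"align_paired: dropped {len(dropped)} sample(s) "
                          f"present only in {name}: {dropped[:5]}...")
    age_vec = None
    if age is not None:
        if isinstance(age, dict):
            age_vec = np.array([float(age[s]) for s in order])
        else:
            lookup = dict(zip(cov.sample_ids, np.asarray(age, dtype=float)))
            age_vec = np.array([lookup[s] for s in order])
    return PairedDataset(
        blood=blood.subset_samples(order),
        brain=brain.subset_samples(order),
        covariates=cov.subset_samples(order),
        age=age_vec,
        tissue_label=tissue_label,
    )
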