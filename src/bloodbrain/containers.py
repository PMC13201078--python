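"""Core data containers: expression matrices, covariates, paired datasets.

The pipeline moves expression data through three stages — raw counts,
library-size-normalized log2 values, and covariate residuals — and every
matrix carries an explicit stage tag so downstream operations can refuse
inputs at the wrong stage.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "ExpressionMatrix",
    "CovariateTable",
    "PairedDataset",
    "RunConfig",
]


class Stage(str, enum.Enum):
    """Processing stage of an expression matrix."""

    RAW_COUNTS = "raw_counts"
    NORMALIZED_LOG2 = "normalized_log2"
    RESIDUALIZED = "residualized"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a processing-stage tag.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers.
    values
        Dense float array of shape ``(len(gene_ids), len(sample_ids))``.
        Counts for stage ``raw_counts``; log2 relative expression otherwise.
    stage
        One of :class:`Stage`.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    stage: Stage = Stage.RAW_COUNTS

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.stage = Stage(self.stage)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values; "
                             "imputation is not supported")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.stage is Stage.RAW_COUNTS and (self.values < 0).any():
            raise ValueError("raw counts must be non-negative")

    # -- convenience ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   stage: Stage = Stage.RAW_COUNTS) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float), stage)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids),
                                self.values[:, cols], self.stage)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids),
                                self.values[rows, :], self.stage)

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class CovariateTable:
    """Per-sample covariates: numeric (RIN, ischemic time, quality rates)
    and categorical (collection site, sex).

    Single-level categorical covariates carry no information and are
    dropped with a warning at construction time.
    """

    sample_ids: list[str]
    numeric: dict[str, np.ndarray] = field(default_factory=dict)
    categorical: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for name, v in list(self.numeric.items()):
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise ValueError(f"numeric covariate {name!r} has length "
                                 f"{v.shape}, expected {n}")
            if not np.isfinite(v).all():
                raise ValueError(f"numeric covariate {name!r} has missing or "
                                 "non-finite values")
            self.numeric[name] = v
        for name, v in list(self.categorical.items()):
            v = np.asarray(v, dtype=object)
            if v.shape != (n,):
                raise ValueError(f"categorical covariate {name!r} has length "
                                 f"{v.shape}, expected {n}")
            if len(set(v.tolist())) < 2:
                warnings.warn(f"categorical covariate {name!r} has a single "
                              "level and was dropped")
                del self.categorical[name]
            else:
                self.categorical[name] = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CovariateTable":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = np.array([idx[s] for s in sample_ids], dtype=int)
        with warnings.catch_warnings():
            # subsetting may collapse a categorical to one level; that
            # warning is raised (again) where the subset is actually used
            warnings.simplefilter("ignore")
            return CovariateTable(
                list(sample_ids),
                {k: v[cols] for k, v in self.numeric.items()},
                {k: v[cols] for k, v in self.categorical.items()},
            )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {}
        data.update(self.numeric)
        data.update(self.categorical)
        return pd.DataFrame(data, index=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CovariateTable":
        numeric: dict[str, np.ndarray] = {}
        categorical: dict[str, np.ndarray] = {}
        for col in df.columns:
            series = df[col]
            if pd.api.types.is_numeric_dtype(series):
                numeric[str(col)] = series.to_numpy(dtype=float)
            else:
                categorical[str(col)] = series.astype(str).to_numpy(dtype=object)
        return cls(list(df.index.astype(str)), numeric, categorical)

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Intercept + numeric columns + treatment contrasts for categoricals.

        Returns the design matrix (samples x columns) and column names.
        Collinear columns are NOT dropped here; see
        :func:`bloodbrain.preprocess.residualize`.
        """
        n = self.n_samples
        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["intercept"]
        for name in sorted(self.numeric):
            cols.append(self.numeric[name])
            names.append(name)
        for name in sorted(self.categorical):
            v = self.categorical[name]
            levels = sorted(set(v.tolist()))
            for lev in levels[1:]:  # first level is the reference
                cols.append((v == lev).astype(float))
                names.append(f"{name}[{lev}]")
        return np.column_stack(cols), names


@dataclass
class PairedDataset:
    """Blood and brain expression aligned on identical subject ordering."""

    blood: ExpressionMatrix
    brain: ExpressionMatrix
    covariates: CovariateTable
    age: Optional[np.ndarray] = None
    tissue_label: str = "brain"

    def __post_init__(self) -> None:
        ids = self.blood.sample_ids
        if self.brain.sample_ids != ids or self.covariates.sample_ids != ids:
            raise ValueError("blood, brain and covariate sample ids must be "
                             "identical and identically ordered; use "
                             "align_paired() first")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if self.age.shape != (len(ids),):
                raise ValueError("age vector length does not match samples")

    @property
    def sample_ids(self) -> list[str]:
        return self.blood.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def check_cv_feasible(self, k: int) -> None:
        if self.n_samples < 2 * k:
            raise ValueError(
                f"{self.n_samples} samples cannot support {k}-fold CV "
                f"(need at least {2 * k})")


@dataclass
class RunConfig:
    """Run-wide configuration knobs with their defaults.

    All randomness in a run flows from ``seed`` through deterministic
    per-stage substreams (see :func:`bloodbrain.utils.substream`).
    """

    k_folds: int = 5
    inner_cv_folds: int = 10
    seed: int = 0
    thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
    n_perm: int = 10
    fdr: float = 0.05
    min_module_size: int = 10
    hub_p: float = 0.05
    hub_n_perm: int = 100
    feature_cap: int = 1000
    config_subset: Optional[list[str]] = None
    min_mean_expression: Optional[float] = None
    model_mode: str = "choose"  # "choose" | "race" | "linear" | "elastic_net"
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("k_folds", "inner_cv_folds", "n_perm",
                     "min_module_size", "hub_n_perm", "feature_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        th = tuple(float(t) for t in self.thresholds)
        if any(not (0 < t < 1) for t in th):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = th
        if self.model_mode not in ("choose", "race", "linear", "elastic_net"):
            raise ValueError(f"unknown model_mode {self.model_mode!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
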