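"""Normalization and covariate adjustment.

Raw counts are scaled by trimmed-mean-of-M-values (TMM) factors to remove
library-size and composition differences, log2 transformed on a
counts-per-million scale, and then each gene is replaced by its residual
from a linear model on technical and biological covariates (collection
site, RIN, ischemic time, exonic/rRNA/intergenic rates, sex). Downstream
analysis operates entirely on those residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CovariateTable, ExpressionMatrix, Stage

__all__ = ["NormalizationFactors", "tmm_factors", "normalize_log2",
           "residualize"]


@dataclass
class NormalizationFactors:
    """TMM scaling factors per sample (geometric mean rescaled to 1)."""

    sample_ids: list[str]
    library_sizes: np.ndarray
    factors: np.ndarray
    reference_sample: str

    def __post_init__(self) -> None:
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError("TMM factors are not rescaled to geometric "
                             f"mean 1 (got {gm})")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float,
              lib_ref: float, trim_m: float, trim_a: float) -> float:
    """Doubly trimmed, inverse-variance-weighted mean of M-values for one
    sample against the reference; returns the factor on the log2 scale."""
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no expressed genes with the "
                         "reference sample")
    p_obs = obs[both] / lib_obs
    p_ref = ref[both] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method approximate variance of M for binomial sampling
    w = ((lib_obs - obs[both]) / (lib_obs * obs[both])
         + (lib_ref - ref[both]) / (lib_ref * ref[both]))
    if np.max(np.abs(m)) < 1e-6:  # identical relative counts
        return 0.0
    n = m.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    # ranks are 1-based averages so ties are trimmed symmetrically
    rank_m = _rankdata(m)
    rank_a = _rankdata(a)
    keep = ((rank_m >= lo_l) & (rank_m <= hi_l)
            & (rank_a >= lo_s) & (rank_a <= hi_s))
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def _rankdata(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def tmm_factors(counts: ExpressionMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> NormalizationFactors:
    """Compute TMM normalization factors from raw counts.

    The reference sample is the one whose upper quartile of nonzero
    relative counts is closest to the mean upper quartile. For every other
    sample, gene-wise log2 ratios (M) and average log2 abundances (A) of
    relative counts are doubly trimmed (``trim_m`` of M, ``trim_a`` of A,
    each side) and combined by an inverse-variance-weighted mean; the
    factor is 2 to that mean. Factors are rescaled to geometric mean 1.
    """
    if counts.stage is not Stage.RAW_COUNTS:
        raise ValueError("tmm_factors requires raw counts")
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.values
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = [counts.sample_ids[j] for j in np.flatnonzero(lib <= 0)]
        raise ValueError(f"samples with zero total count: {bad}")

    uq = np.array([
        np.quantile(x[x[:, j] > 0, j] / lib[j], 0.75)
        if (x[:, j] > 0).any() else 0.0
        for j in range(counts.n_samples)
    ])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref_idx:
            log_factors[j] = 0.0
            continue
        try:
            log_factors[j] = _tmm_pair(x[:, j], x[:, ref_idx], lib[j],
                                       lib[ref_idx], trim_m, trim_a)
        except ValueError as err:
            raise ValueError(
                f"sample {counts.sample_ids[j]!r}: {err}") from None
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(list(counts.sample_ids), lib, factors,
                                counts.sample_ids[ref_idx])


def normalize_log2(counts: ExpressionMatrix, factors: NormalizationFactors,
                   pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2( count / (library_size * factor) * 1e6 + pseudocount ).
    With all-zero counts every value is log2(pseudocount) (0 for the
    default pseudocount of 1).
    """
    if counts.stage is not Stage.RAW_COUNTS:
        raise ValueError("normalize_log2 requires raw counts")
    if counts.sample_ids != factors.sample_ids:
        raise ValueError("factors were computed on different samples")
    if (np.asarray(factors.factors) <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = factors.library_sizes * factors.factors
    values = np.log2(counts.values / eff[None, :] * 1e6 + pseudocount)
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids),
                            values, Stage.NORMALIZED_LOG2)


def _prune_collinear(design: np.ndarray, names: list[str],
                     tol: float = 1e-10) -> tuple[np.ndarray, list[str]]:
    """Drop columns that are linear combinations of earlier ones (QR)."""
    keep: list[int] = []
    basis: np.ndarray | None = None
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) \
                == len(keep) + 1:
            keep.append(j)
    _ = basis
    if len(keep) < design.shape[1]:
        dropped = [names[j] for j in range(design.shape[1]) if j not in keep]
        warnings.warn(f"residualize: dropped collinear design columns "
                      f"{dropped}")
    return design[:, keep], [names[j] for j in keep]


def residualize(expr: ExpressionMatrix, cov: CovariateTable) -> ExpressionMatrix:
    """Replace every gene by its least-squares residual against the
    covariate design (intercept + numeric + categorical contrasts).

    Residuals are orthogonal to every design column and the operation is
    idempotent. Rank-deficient designs lose their dependent columns with
    a warning; designs wider than the sample count are an error.
    """
    if expr.stage is Stage.RAW_COUNTS:
        raise ValueError("residualize expects normalized (or residualized) "
                         "expression, not raw counts")
    if expr.sample_ids != cov.sample_ids:
        raise ValueError("expression and covariates are not aligned")
    design, names = cov.design_matrix()
    n = expr.n_samples
    if design.shape[1] > n:
        raise ValueError(f"design has {design.shape[1]} columns for only "
                         f"{n} samples")
    design, names = _prune_collinear(design, names)
    # residual = y - X (X^+ y); computed via lstsq for numerical stability
    coef, *_ = np.linalg.lstsq(design, expr.values.T, rcond=None)
    residuals = expr.values - (design @ coef).T
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                            residuals, Stage.RESIDUALIZED)
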