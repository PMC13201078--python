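"""Per-gene integration across the feature-selection grid.

No single feature-selection configuration dominates: configurations are
ranked by how many genes they predict above a cutoff (avg CV r > 0.5 by
default), and the integrated predictor takes, for each gene, the
best-performing configuration among either all of them or the top-k of
that ranking. Threshold-count tables summarize how many genes clear each
accuracy level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["MethodRanking", "IPSResult", "rank_methods", "integrate_best",
           "combination_curve", "best_feature_family_shares",
           "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass
class MethodRanking:
    """Configurations ordered by number of genes with avg CV r above the
    ranking cutoff; ties break toward canonical (column) order."""

    config_ids: list[str]
    counts: pd.Series  # per config, indexed like config_ids
    cutoff: float

    def top(self, k: int) -> list[str]:
        return self.config_ids[:k]


@dataclass
class IPSResult:
    """Best configuration and value per gene, with threshold counts."""

    per_gene: pd.DataFrame  # index gene; columns best_config, best_avg_cv_r
    threshold_counts: pd.Series  # index threshold
    considered: str

    @property
    def values(self) -> pd.Series:
        return self.per_gene["best_avg_cv_r"]


def _as_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Accept either a genes x configs matrix or a long table with
    gene/config_id/avg_cv_r columns."""
    if {"gene", "config_id", "avg_cv_r"}.issubset(results.columns):
        wide = results.pivot(index="gene", columns="config_id",
                             values="avg_cv_r")
        order = list(dict.fromkeys(results["config_id"]))
        return wide.reindex(columns=order)
    return results


def rank_methods(results: pd.DataFrame, cutoff: float = 0.5) -> MethodRanking:
    """Order configurations by their count of genes with avg CV r > cutoff.

    The input is a genes x configs matrix of avg CV r (or the long result
    table); column order defines the canonical tie-break.
    """
    mat = _as_matrix(results)
    counts = (mat > cutoff).sum(axis=0)
    order = sorted(range(len(mat.columns)),
                   key=lambda j: (-int(counts.iloc[j]), j))
    ordered = [mat.columns[j] for j in order]
    return MethodRanking(ordered, counts.reindex(ordered), cutoff)


def integrate_best(results: pd.DataFrame,
                   considered: str | Sequence[str] = "all",
                   ranking: Optional[MethodRanking] = None,
                   thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                   ) -> IPSResult:
    """Per-gene best configuration among the considered set.

    ``considered`` is "all", "top_k" (requires ``ranking``; k from
    ``ranking`` top-5 unless written as "top_3" etc.), or an explicit
    list of configuration ids. Per-gene ties resolve toward the config
    ranked higher (or earlier in canonical order when no ranking is
    given).
    """
    mat = _as_matrix(results)
    if isinstance(considered, str):
        if considered == "all":
            cols = list(mat.columns)
            label = "all"
        elif considered.startswith("top"):
            if ranking is None:
                raise ValueError("top-k integration requires a ranking")
            k = int(considered.split("_")[1]) if "_" in considered else 5
            cols = ranking.top(k)
            label = f"top_{k}"
        else:
            raise ValueError(f"unknown considered set {considered!r}")
    else:
        cols = list(considered)
        label = f"explicit({len(cols)})"
    if ranking is not None:
        # priority order = ranking order restricted to the considered set
        cols = [c for c in ranking.config_ids if c in cols]
    sub = mat[cols]
    arr = sub.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        filled = np.where(np.isnan(arr), -np.inf, arr)
    best_j = np.argmax(filled, axis=1)  # first max = highest priority
    best_val = filled[np.arange(len(sub)), best_j]
    best_val = np.where(np.isfinite(best_val), best_val, np.nan)
    per_gene = pd.DataFrame({
        "best_config": [cols[j] for j in best_j],
        "best_avg_cv_r": best_val,
    }, index=sub.index)
    per_gene.loc[np.isnan(best_val), "best_config"] = ""
    counts = pd.Series(
        {t: int(np.nansum(best_val > t)) for t in thresholds},
        name="n_genes")
    counts.index.name = "threshold"
    return IPSResult(per_gene, counts, label)


def combination_curve(results: pd.DataFrame, k_max: int = 5,
                      ranking: Optional[MethodRanking] = None,
                      cutoff: float = 0.5,
                      thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                      ) -> pd.DataFrame:
    """Counts of genes above each threshold when integrating the best of
    the top-k configurations, for k = 1..k_max.

    Counts are non-decreasing in k at every threshold (supersets of
    maxima).
    """
    mat = _as_matrix(results)
    if ranking is None:
        ranking = rank_methods(mat, cutoff)
    rows = []
    for k in range(1, k_max + 1):
        ips = integrate_best(mat, ranking.top(k), ranking=ranking,
                             thresholds=thresholds)
        row = {"k": k, "methods": "|".join(ranking.top(k))}
        for t in thresholds:
            row[f"n_r_gt_{t:g}"] = int(ips.threshold_counts[t])
        rows.append(row)
    return pd.DataFrame(rows)


def best_feature_family_shares(results: pd.DataFrame,
                               families: dict[str, str],
                               ranking: Optional[MethodRanking] = None,
                               ) -> pd.DataFrame:
    """Fraction of genes (with a defined winner) for which each feature
    family provides the best configuration.

    ``families`` maps config id -> family label. Ties resolve toward the
    canonical/ranking order; the number of tied winners is reported.
    """
    mat = _as_matrix(results)
    ips = integrate_best(mat, "all", ranking=ranking)
    defined = ips.per_gene["best_config"] != ""
    winners = ips.per_gene.loc[defined, "best_config"].map(families)
    arr = mat.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        n_tied = np.nansum(
            np.isclose(arr, np.nanmax(arr, axis=1, keepdims=True)), axis=1)
    share = winners.value_counts(normalize=True)
    out = pd.DataFrame({
        "family": share.index,
        "share": share.to_numpy(),
        "n_genes_won": winners.value_counts().reindex(share.index).to_numpy(),
    })
    out.attrs["n_ties"] = int(np.sum(n_tied[defined.to_numpy()] > 1))
    return out
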