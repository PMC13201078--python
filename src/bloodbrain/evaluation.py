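"""Diagnostics and baselines for a completed prediction run.

* a top-40-global-PC linear baseline on the same fold plan (the standard
  blood-to-brain imputation baseline the grid is compared against);
* preservation of age-associated expression in predicted profiles,
  stratified by prediction accuracy;
* independence of prediction accuracy from expression abundance; and
* per-gene extraction of recurrently selected blood predictor genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PairedDataset, RunConfig
from .cv import FoldPlan, GridResult, cross_correlations, pearson_r, run_grid
from .features import FeatureConfig, Family
from .network import ModulePCSpec

__all__ = ["AgePreservationResult", "PredictorSummary", "baseline_top40pc",
           "age_preservation", "abundance_check", "top_predictors",
           "assemble_oof"]

BANDS = (("poor", -np.inf, 0.1), ("moderate", 0.1, 0.5),
         ("good", 0.5, np.inf))


def baseline_top40pc(paired: PairedDataset, genes: list[str],
                     plan: FoldPlan, options: RunConfig | None = None,
                     collect_predictions: bool = False) -> GridResult:
    """Linear model on the top 40 global blood PCs, same fold plan.

    Equivalent to restricting the grid to the gPC(40PC) configuration
    with linear-only modeling; used as the named baseline column in
    comparisons.
    """
    options = options or RunConfig(seed=plan.seed, k_folds=plan.k)
    opts = RunConfig(**{**options.__dict__, "model_mode": "linear"})
    config = FeatureConfig(Family.GPC, gpc_spec=ModulePCSpec("count", 40))
    return run_grid(paired, genes, [config], plan, opts,
                    collect_predictions=collect_predictions)


@dataclass
class AgePreservationResult:
    """Observed (r1) vs predicted (r2) age correlations per gene, with
    band-level agreement statistics."""

    per_gene: pd.DataFrame  # index gene; r1, r2, avg_cv_r, band
    per_band: pd.DataFrame  # index band; n, corr_r1_r2, mean_abs_diff


def assemble_oof(predictions: dict[tuple[str, str], np.ndarray],
                 per_gene_config: pd.Series) -> dict[str, np.ndarray]:
    """Pick each gene's out-of-fold prediction vector for its assigned
    configuration (e.g. the integrated best)."""
    out = {}
    for gene, config_id in per_gene_config.items():
        if (gene, config_id) in predictions:
            out[gene] = predictions[(gene, config_id)]
    return out


def _band_of(r: float) -> str:
    if np.isnan(r):
        return ""
    for name, lo, hi in BANDS:
        if (lo < r < hi) or (name == "moderate" and (r == 0.1 or r == 0.5)):
            return name
    return ""


def age_preservation(paired: PairedDataset, accuracy: pd.Series,
                     oof_predictions: dict[str, np.ndarray],
                     ) -> AgePreservationResult:
    """Does predicted expression retain each gene's age association?

    For every gene with out-of-fold predictions, r1 = corr(observed
    expression, age) and r2 = corr(predicted expression, age). Genes are
    stratified into poor (r < 0.1), moderate (0.1 <= r <= 0.5) and good
    (r > 0.5) prediction bands by ``accuracy`` (avg CV r), and each band
    reports corr(r1, r2) and mean |r1 - r2|.
    """
    if paired.age is None:
        raise ValueError("age_preservation requires per-sample ages")
    age = paired.age
    rows = []
    for gene, pred in oof_predictions.items():
        acc = accuracy.get(gene, np.nan)
        obs = paired.brain.gene_row(gene)
        mask = ~np.isnan(pred)
        if mask.sum() < 3:
            continue
        rows.append({
            "gene": gene,
            "r1": pearson_r(obs[mask], age[mask]),
            "r2": pearson_r(pred[mask], age[mask]),
            "avg_cv_r": acc,
            "band": _band_of(acc),
        })
    per_gene = pd.DataFrame(rows).set_index("gene")
    band_rows = []
    for name, _lo, _hi in BANDS:
        sub = per_gene[per_gene["band"] == name].dropna(subset=["r1", "r2"])
        band_rows.append({
            "band": name,
            "n": len(sub),
            "corr_r1_r2": pearson_r(sub["r1"].to_numpy(),
                                    sub["r2"].to_numpy())
            if len(sub) >= 3 else np.nan,
            "mean_abs_diff": float(np.mean(np.abs(sub["r1"] - sub["r2"])))
            if len(sub) else np.nan,
        })
    per_band = pd.DataFrame(band_rows).set_index("band")
    return AgePreservationResult(per_gene, per_band)


def abundance_check(paired: PairedDataset, accuracy: pd.Series,
                    ) -> pd.DataFrame:
    """Correlation between mean expression (abundance) and prediction
    accuracy, per tissue source. Undefined correlations (constant
    accuracy) are reported as NaN."""
    rows = []
    for tissue, expr in (("brain", paired.brain), ("blood", paired.blood)):
        genes = [g for g in accuracy.index if g in expr.gene_ids]
        acc = accuracy.reindex(genes).to_numpy(dtype=float)
        defined = ~np.isnan(acc)
        if defined.sum() < 3:
            rows.append({"tissue": tissue, "r": np.nan, "n": 0})
            continue
        idx = {g: i for i, g in enumerate(expr.gene_ids)}
        abundance = expr.values[[idx[g] for g in genes]].mean(axis=1)
        rows.append({"tissue": tissue,
                     "r": pearson_r(abundance[defined], acc[defined]),
                     "n": int(defined.sum())})
    return pd.DataFrame(rows)


@dataclass
class PredictorSummary:
    """Blood genes recurrently selected for one target across CV folds."""

    gene: str
    predictors: pd.DataFrame  # index blood gene; n_folds_selected

    def __len__(self) -> int:
        return len(self.predictors)


def top_predictors(paired: PairedDataset, gene: str, plan: FoldPlan,
                   rho_thr: float = 0.2, min_folds: int = 2,
                   ) -> PredictorSummary:
    """Blood genes with training-fold |r| > rho_thr against the target in
    at least ``min_folds`` of the k folds."""
    if gene not in paired.brain.gene_ids:
        raise ValueError(f"gene {gene!r} is not in the brain matrix")
    if min_folds > plan.k:
        warnings.warn(f"min_folds={min_folds} exceeds k={plan.k}; "
                      "no predictor can qualify")
    counts = np.zeros(paired.blood.n_genes, dtype=int)
    for fold in range(plan.k):
        corr = cross_correlations(paired, plan.train_indices(fold), [gene])
        counts += (np.abs(corr[gene]) > rho_thr).astype(int)
    sel = np.flatnonzero(counts >= min_folds)
    df = pd.DataFrame({
        "n_folds_selected": counts[sel],
    }, index=[paired.blood.gene_ids[i] for i in sel])
    df.index.name = "blood_gene"
    return PredictorSummary(gene, df.sort_values("n_folds_selected",
                                                 ascending=False))
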