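"""Model / Results interface over the prediction pipeline.

`BloodBrainImputation` is constructed from a paired dataset (plus the
configuration grid and run options); its :meth:`fit` runs the per-gene,
per-configuration cross-validation and returns an
:class:`ImputationResults` carrying the full result table, integration,
diagnostics and a text summary — the same shape statsmodels gives its
estimators.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .containers import (CovariateTable, ExpressionMatrix, PairedDataset,
                         RunConfig, Stage)
from .cv import FoldPlan, GridResult, make_folds, run_grid
from .features import FeatureConfig, enumerate_configs
from .integrate import (IPSResult, MethodRanking, best_feature_family_shares,
                        combination_curve, integrate_best, rank_methods)
from . import evaluation as _evaluation
from .io import align_paired

__all__ = ["BloodBrainImputation", "ImputationResults"]


class BloodBrainImputation:
    """Per-gene brain-expression prediction from blood, over a grid of
    feature-selection configurations.

    Parameters
    ----------
    paired
        Aligned blood/brain/covariate data (residualized stage expected).
    configs
        Feature-selection grid; defaults to the canonical 70.
    options
        Run options (fold counts, seeds, network parameters, model mode).
    """

    def __init__(self, paired: PairedDataset,
                 configs: Optional[Sequence[FeatureConfig]] = None,
                 options: Optional[RunConfig] = None):
        self.paired = paired
        self.options = options or RunConfig()
        all_configs = list(configs) if configs is not None \
            else enumerate_configs()
        if self.options.config_subset:
            wanted = set(self.options.config_subset)
            unknown = wanted - {c.config_id for c in all_configs}
            if unknown:
                raise ValueError(f"unknown config ids: {sorted(unknown)}")
            all_configs = [c for c in all_configs if c.config_id in wanted]
        self.configs = all_configs
        paired.check_cv_feasible(self.options.k_folds)

    @classmethod
    def from_dataframes(cls, blood: pd.DataFrame, brain: pd.DataFrame,
                        covariates: pd.DataFrame,
                        age: Optional[Sequence[float]] = None,
                        stage: Stage = Stage.RESIDUALIZED,
                        **kwargs) -> "BloodBrainImputation":
        """Build from genes x samples DataFrames and a samples x
        covariates DataFrame; samples are aligned on shared ids."""
        paired = align_paired(ExpressionMatrix.from_frame(blood, stage),
                              ExpressionMatrix.from_frame(brain, stage),
                              CovariateTable.from_frame(covariates),
                              age=age)
        return cls(paired, **kwargs)

    def fit(self, genes: Optional[Sequence[str]] = None,
            plan: Optional[FoldPlan] = None,
            collect_predictions: bool = False,
            whole_data_network: bool = False,
            trace_features: bool = False) -> "ImputationResults":
        """Run the cross-validated grid and return results."""
        genes = list(genes) if genes is not None \
            else list(self.paired.brain.gene_ids)
        if self.options.min_mean_expression is not None:
            means = {g: self.paired.brain.gene_row(g).mean() for g in genes}
            genes = [g for g in genes
                     if means[g] >= self.options.min_mean_expression]
        if plan is None:
            plan = make_folds(self.paired.n_samples, self.options.k_folds,
                              self.options.seed)
        grid = run_grid(self.paired, genes, self.configs, plan, self.options,
                        collect_predictions=collect_predictions,
                        whole_data_network=whole_data_network,
                        trace_features=trace_features)
        return ImputationResults(self, grid)


class ImputationResults:
    """Results of a fitted grid: per-gene/config CV correlations plus
    integration and diagnostics."""

    def __init__(self, model: BloodBrainImputation, grid: GridResult):
        self.model = model
        self.grid = grid
        self._table: Optional[pd.DataFrame] = None

    # -- core tables ----------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        if self._table is None:
            self._table = self.grid.table
        return self._table

    @property
    def matrix(self) -> pd.DataFrame:
        """genes x configs matrix of avg CV r."""
        return self.grid.pivot()

    @property
    def plan(self) -> FoldPlan:
        return self.grid.plan

    # -- integration ----------------------------------------------------
    def rank_methods(self, cutoff: float = 0.5) -> MethodRanking:
        return rank_methods(self.matrix, cutoff)

    def integrate(self, considered: str = "all",
                  ranking: Optional[MethodRanking] = None) -> IPSResult:
        if considered != "all" and ranking is None:
            ranking = self.rank_methods()
        return integrate_best(self.matrix, considered, ranking=ranking,
                              thresholds=self.model.options.thresholds)

    def combination_curve(self, k_max: int = 5) -> pd.DataFrame:
        return combination_curve(self.matrix, k_max,
                                 thresholds=self.model.options.thresholds)

    def family_shares(self) -> pd.DataFrame:
        return best_feature_family_shares(self.matrix, self.grid.families)

    # -- diagnostics ----------------------------------------------------
    def baseline_top40pc(self, collect_predictions: bool = False
                         ) -> GridResult:
        genes = sorted(set(self.table["gene"]))
        return _evaluation.baseline_top40pc(self.model.paired, genes,
                                            self.plan, self.model.options,
                                            collect_predictions)

    def age_preservation(self, considered: str = "all"):
        if not self.grid.predictions:
            raise ValueError("fit with collect_predictions=True to run "
                             "age preservation")
        ips = self.integrate(considered)
        oof = _evaluation.assemble_oof(self.grid.predictions,
                                       ips.per_gene["best_config"])
        return _evaluation.age_preservation(self.model.paired, ips.values,
                                            oof)

    def abundance_check(self, considered: str = "all",
                        expression_source: Optional[PairedDataset] = None,
                        ) -> pd.DataFrame:
        """``expression_source`` should carry pre-residualization
        (normalized) values: residuals are mean-zero by construction, so
        abundance is only meaningful before covariate adjustment."""
        ips = self.integrate(considered)
        paired = expression_source or self.model.paired
        return _evaluation.abundance_check(paired, ips.values)

    def top_predictors(self, gene: str, rho_thr: float = 0.2,
                       min_folds: int = 2):
        return _evaluation.top_predictors(self.model.paired, gene,
                                          self.plan, rho_thr, min_folds)

    # -- presentation ----------------------------------------------------
    def summary(self, top_k: int = 5) -> str:
        """Plain-text summary: run shape, top configurations, and gene
        counts at each accuracy threshold for the single best method vs
        the per-gene integrated predictor."""
        mat = self.matrix
        ranking = self.rank_methods()
        ips_all = self.integrate("all")
        ips_top = self.integrate(f"top_{top_k}", ranking=ranking)
        thresholds = self.model.options.thresholds
        lines = [
            "Blood-to-brain expression imputation",
            "=" * 52,
            f"samples: {self.model.paired.n_samples}   "
            f"genes: {mat.shape[0]}   configs: {mat.shape[1]}   "
            f"folds: {self.plan.k}",
            "",
            f"top {top_k} configurations by genes with avg CV r > "
            f"{ranking.cutoff:g}:",
        ]
        for cid in ranking.top(top_k):
            lines.append(f"  {cid:<28s} {int(ranking.counts[cid]):>6d}")
        lines += ["", "genes above threshold "
                      "(best single method | best of top-"
                      f"{top_k} | best of all):"]
        best_single = (mat[ranking.top(1)[0]]
                       if ranking.config_ids else pd.Series(dtype=float))
        for t in thresholds:
            lines.append(
                f"  r > {t:.1f}: {int((best_single > t).sum()):>6d} | "
                f"{int(ips_top.threshold_counts[t]):>6d} | "
                f"{int(ips_all.threshold_counts[t]):>6d}")
        lines.append("")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        mat = self.matrix
        return (f"<ImputationResults: {mat.shape[0]} genes x "
                f"{mat.shape[1]} configs, k={self.plan.k}>")
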