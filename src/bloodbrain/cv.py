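"""Leakage-safe per-gene, per-configuration cross-validation.

For every brain gene and every feature-selection configuration, a shared
k-fold plan drives outer cross-validation in which *all* feature
statistics — global PCA, per-gene correlations, network modules and their
PCs — are recomputed from the training four-fifths of each fold, and the
held-out fifth is mapped into the feature space through frozen projection
recipes. The per-gene accuracy metric is the average over folds of the
Pearson correlation between predicted and observed held-out expression
(``avg_cv_r``).

Module construction dominates the cost, so networks and the global PCA
are computed once per fold and shared across every gene and
configuration in that fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PairedDataset, RunConfig
from .features import (FeatureConfig, Family, select_features)
from .network import (ModuleSet, PCARecipe, build_pmfg, calibrate_cutoff,
                      fit_pca, multiscale_cluster)
from .regression import (ElasticNetSpec, choose_model, fit_elastic_net,
                         fit_linear, predict)
from .utils import subseed, substream

__all__ = ["FoldPlan", "GeneConfigResult", "FoldContext", "GridResult",
           "make_folds", "run_gene_config", "run_grid", "pearson_r"]

logger = logging.getLogger("bloodbrain")


@dataclass
class FoldPlan:
    """A seed-deterministic balanced partition of samples into k folds."""

    k: int
    labels: np.ndarray  # per-sample fold index in [0, k)
    seed: int

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels != fold)


def make_folds(n_samples: int, k: int = 5, seed: int = 0) -> FoldPlan:
    """Random balanced fold assignment (sizes differ by at most one)."""
    if n_samples < 2 * k:
        raise ValueError(f"{n_samples} samples cannot support {k}-fold CV")
    rng = substream(seed, "folds")
    perm = rng.permutation(n_samples)
    labels = np.empty(n_samples, dtype=int)
    for fold, idx in enumerate(np.array_split(perm, k)):
        labels[idx] = fold
    return FoldPlan(k, labels, seed)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class GeneConfigResult:
    """Per-fold and aggregate accuracy for one (gene, configuration)."""

    gene: str
    config_id: str
    family: str
    fold_r: np.ndarray
    model_kinds: list[str]
    n_features: np.ndarray
    status: str

    @property
    def avg_cv_r(self) -> float:
        defined = self.fold_r[~np.isnan(self.fold_r)]
        return float(defined.mean()) if defined.size else float("nan")


@dataclass
class FoldContext:
    """Training-fold artifacts shared across genes and configurations."""

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_blood: ExpressionMatrix
    test_blood: ExpressionMatrix
    gpca: Optional[PCARecipe] = None
    modules: Optional[ModuleSet] = None
    corr: dict[str, np.ndarray] = field(default_factory=dict)
    # gene-independent feature sets (gPC, mPC) cached per config id as
    # (train FeatureSet, transformed test matrix)
    cache: dict = field(default_factory=dict)

    @classmethod
    def build(cls, paired: PairedDataset, plan: FoldPlan, fold: int,
              configs: Sequence[FeatureConfig], genes: Sequence[str],
              options: RunConfig,
              shared_modules: Optional[ModuleSet] = None) -> "FoldContext":
        train_idx = plan.train_indices(fold)
        test_idx = plan.test_indices(fold)
        ids = paired.sample_ids
        train_blood = paired.blood.subset_samples([ids[i] for i in train_idx])
        test_blood = paired.blood.subset_samples([ids[i] for i in test_idx])
        ctx = cls(fold, train_idx, test_idx, train_blood, test_blood)

        if any(c.family == Family.GPC for c in configs):
            ctx.gpca = fit_pca(train_blood.values,
                               list(train_blood.gene_ids),
                               unit_scale=False, name_prefix="gPC")
        if any(c.uses_modules for c in configs):
            if shared_modules is not None:
                ctx.modules = shared_modules
            else:
                ctx.modules = build_fold_modules(train_blood, options, fold)
        if any(c.supervised for c in configs) and genes:
            ctx.corr = cross_correlations(paired, train_idx, genes)
        return ctx


def build_fold_modules(train_blood: ExpressionMatrix, options: RunConfig,
                       fold: int) -> ModuleSet:
    """Calibrate the cutoff, build the PMFG, and cluster — on one fold's
    training samples only."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calib = calibrate_cutoff(train_blood, n_perm=options.n_perm,
                                 fdr=options.fdr,
                                 seed=subseed(options.seed, "network", fold))
        net = build_pmfg(train_blood, calib.rho_star)
        modules = multiscale_cluster(net, min_size=options.min_module_size)
    logger.info("fold %d: rho*=%.2f, %d edges, %d modules", fold,
                calib.rho_star, len(net.edges), len(modules))
    return modules


def cross_correlations(paired: PairedDataset, train_idx: np.ndarray,
                       genes: Sequence[str]) -> dict[str, np.ndarray]:
    """Training-set Pearson r of every target gene against every blood
    gene, in one matrix product."""
    gene_rows = [paired.brain.gene_ids.index(g) for g in genes]
    yb = paired.brain.values[np.ix_(gene_rows, train_idx)]
    xb = paired.blood.values[:, train_idx]
    yc = yb - yb.mean(axis=1, keepdims=True)
    xc = xb - xb.mean(axis=1, keepdims=True)
    sy = np.sqrt(np.sum(yc ** 2, axis=1))
    sx = np.sqrt(np.sum(xc ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc.T) / np.outer(sy, sx)
    r = np.where(np.isfinite(r), r, 0.0)
    return {g: r[i] for i, g in enumerate(genes)}


def _features_with_test(ctx: FoldContext, config: FeatureConfig, gene: str,
                        y_train: np.ndarray):
    """Feature matrices for one (config, gene) in one fold, reusing the
    fold cache for the gene-independent gPC and mPC parts."""
    from .features import select_combined, select_rg

    def unsupervised(cfg: FeatureConfig):
        key = cfg.config_id
        if key not in ctx.cache:
            fs = select_features(cfg, ctx.train_blood, modules=ctx.modules,
                                 pca=ctx.gpca)
            ctx.cache[key] = (fs, fs.transform(ctx.test_blood))
        return ctx.cache[key]

    if config.family in (Family.GPC, Family.MPC):
        fs, x_test = unsupervised(config)
        return fs, x_test
    if config.family == Family.RG:
        fs = select_rg(ctx.train_blood, y_train, config.rg_spec,
                       corr=ctx.corr.get(gene))
        fs.config_id = config.config_id
        return fs, fs.transform(ctx.test_blood)
    # RG_MPC: supervised part per gene, module part from the cache
    mpc_cfg = FeatureConfig(Family.MPC, mpc_spec=config.mpc_spec)
    mpc_fs, mpc_test = unsupervised(mpc_cfg)
    rg_fs = select_rg(ctx.train_blood, y_train, config.rg_spec,
                      corr=ctx.corr.get(gene))
    fs = select_combined(rg_fs, mpc_fs)
    fs.config_id = config.config_id
    x_test = np.hstack([rg_fs.transform(ctx.test_blood), mpc_test])
    return fs, x_test


def _fit_and_predict(kind: str, X_train: np.ndarray, y_train: np.ndarray,
                     X_test: np.ndarray, names: list[str],
                     options: RunConfig, fold_seed: int,
                     ) -> tuple[Optional[np.ndarray], str]:
    if kind == "linear":
        fit = fit_linear(X_train, y_train, names)
    else:
        spec = ElasticNetSpec(inner_cv_folds=options.inner_cv_folds)
        fit = fit_elastic_net(X_train, y_train, spec, seed=fold_seed,
                              feature_names=names)
        if fit.kind == "unfittable":
            return None, "unfittable"
    return predict(fit, X_test, names), fit.kind


def run_gene_config(paired: PairedDataset, gene: str, config: FeatureConfig,
                    plan: FoldPlan, options: Optional[RunConfig] = None,
                    contexts: Optional[list[FoldContext]] = None,
                    ) -> GeneConfigResult:
    """Outer-CV evaluation of one gene under one configuration."""
    options = options or RunConfig(seed=plan.seed, k_folds=plan.k)
    if contexts is None:
        contexts = [FoldContext.build(paired, plan, f, [config], [gene],
                                      options) for f in range(plan.k)]
    result, _ = _evaluate(paired, gene, config, plan, options, contexts)
    return result


def _evaluate(paired: PairedDataset, gene: str, config: FeatureConfig,
              plan: FoldPlan, options: RunConfig,
              contexts: list[FoldContext],
              trace: Optional[list] = None,
              ) -> tuple[GeneConfigResult, dict[str, np.ndarray]]:
    """Returns the result and out-of-fold predictions per model kind."""
    y_all = paired.brain.gene_row(gene)
    k = plan.k
    race = options.model_mode == "race"
    kinds_per_fold: list[str] = []
    n_features = np.zeros(k)
    fold_r = {m: np.full(k, np.nan) for m in ("primary", "race_alt")}
    oof = {m: np.full(plan.n_samples, np.nan) for m in ("primary",
                                                        "race_alt")}
    any_features = False
    for ctx in contexts:
        y_train = y_all[ctx.train_idx]
        y_test = y_all[ctx.test_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs, X_test = _features_with_test(ctx, config, gene, y_train)
        n_features[ctx.fold] = fs.n_features
        if trace is not None:
            for name in fs.names:
                trace.append({"gene": gene, "config_id": config.config_id,
                              "fold": ctx.fold, "feature": name,
                              "family": config.family})
        if fs.n_features == 0:
            kinds_per_fold.append("unfittable")
            continue
        any_features = True
        X_train = fs.matrix
        fold_seed = subseed(options.seed, "model", gene, config.config_id,
                            ctx.fold)

        if options.model_mode == "linear":
            kinds = ["linear"]
        elif options.model_mode == "elastic_net":
            kinds = ["elastic_net"]
        elif race:
            kinds = (["linear", "elastic_net"]
                     if fs.n_features < options.feature_cap
                     else ["elastic_net"])
        else:  # choose
            kinds = [choose_model(fs.n_features, options.feature_cap)]

        fold_kinds = []
        for slot, kind in zip(("primary", "race_alt"), kinds):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred, used = _fit_and_predict(kind, X_train, y_train, X_test,
                                              fs.names, options, fold_seed)
            if pred is None:
                fold_kinds.append("unfittable")
                continue
            fold_r[slot][ctx.fold] = pearson_r(pred, y_test)
            oof[slot][ctx.test_idx] = pred
            fold_kinds.append(used)
        kinds_per_fold.append("+".join(fold_kinds))

    def _avg(arr: np.ndarray) -> float:
        d = arr[~np.isnan(arr)]
        return float(d.mean()) if d.size else -np.inf

    if race and _avg(fold_r["race_alt"]) > _avg(fold_r["primary"]):
        chosen, chosen_oof = fold_r["race_alt"], oof["race_alt"]
        kinds_per_fold = [k.split("+")[-1] for k in kinds_per_fold]
    else:
        chosen, chosen_oof = fold_r["primary"], oof["primary"]
        if race:
            kinds_per_fold = [k.split("+")[0] for k in kinds_per_fold]

    defined = int(np.sum(~np.isnan(chosen)))
    if not any_features or defined == 0:
        status = "unfittable"
    elif defined < k:
        status = "partial"
    else:
        status = "ok"
    result = GeneConfigResult(gene, config.config_id, config.family,
                              chosen, kinds_per_fold, n_features, status)
    return result, {"oof": chosen_oof}


@dataclass
class GridResult:
    """The complete gene x configuration result table."""

    results: list[GeneConfigResult]
    plan: FoldPlan
    config_ids: list[str]
    predictions: dict[tuple[str, str], np.ndarray] = field(
        default_factory=dict)
    feature_trace: Optional[pd.DataFrame] = None

    @property
    def table(self) -> pd.DataFrame:
        k = self.plan.k
        rows = []
        for r in self.results:
            row = {"gene": r.gene, "config_id": r.config_id,
                   "family": r.family}
            for f in range(k):
                row[f"fold_r_{f + 1}"] = r.fold_r[f]
            row["avg_cv_r"] = r.avg_cv_r
            row["model_kind"] = ";".join(dict.fromkeys(r.model_kinds)) \
                if r.model_kinds else ""
            row["n_features_mean"] = float(r.n_features.mean())
            row["status"] = r.status
            rows.append(row)
        df = pd.DataFrame(rows)
        order = {c: i for i, c in enumerate(self.config_ids)}
        return df.sort_values(
            ["gene", "config_id"],
            key=lambda s: s.map(order) if s.name == "config_id" else s,
        ).reset_index(drop=True)

    def pivot(self, value: str = "avg_cv_r") -> pd.DataFrame:
        """genes x configs matrix of the given value column."""
        df = self.table.pivot(index="gene", columns="config_id", values=value)
        return df.reindex(columns=[c for c in self.config_ids
                                   if c in df.columns])

    @property
    def families(self) -> dict[str, str]:
        return {r.config_id: r.family for r in self.results}


def run_grid(paired: PairedDataset, genes: Sequence[str],
             configs: Sequence[FeatureConfig], plan: FoldPlan,
             options: Optional[RunConfig] = None,
             collect_predictions: bool = False,
             whole_data_network: bool = False,
             trace_features: bool = False) -> GridResult:
    """Evaluate every (gene, configuration) pair under one shared fold plan.

    Per-gene failures are recorded as ``unfittable`` rows rather than
    aborting the grid. Results are independent of gene ordering. With
    ``whole_data_network`` the co-expression modules are built once on all
    samples instead of per training fold (not leakage-safe; off by
    default).
    """
    options = options or RunConfig(seed=plan.seed, k_folds=plan.k)
    paired.check_cv_feasible(plan.k)
    known = [g for g in genes if g in paired.brain.gene_ids]
    unknown = sorted(set(genes) - set(known))
    if unknown:
        warnings.warn(f"{len(unknown)} target gene(s) not in the brain "
                      f"matrix were skipped: {unknown[:5]}...")
    configs = list(configs)

    shared_modules = None
    if whole_data_network and any(c.uses_modules for c in configs):
        shared_modules = build_fold_modules(paired.blood, options, fold=-1)

    results: list[GeneConfigResult] = []
    predictions: dict[tuple[str, str], np.ndarray] = {}
    trace: Optional[list] = [] if trace_features else None
    contexts = []
    for fold in range(plan.k):
        contexts.append(FoldContext.build(paired, plan, fold, configs, known,
                                          options,
                                          shared_modules=shared_modules))
    for gene in sorted(known):
        for config in configs:
            res, extra = _evaluate(paired, gene, config, plan, options,
                                   contexts, trace=trace)
            results.append(res)
            if collect_predictions:
                predictions[(gene, config.config_id)] = extra["oof"]
    trace_df = pd.DataFrame(trace) if trace is not None else None
    return GridResult(results, plan, [c.config_id for c in configs],
                      predictions, feature_trace=trace_df)
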