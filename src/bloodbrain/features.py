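"""The feature-selection grid.

Four families of blood-derived features are used to predict each brain
gene, always computed from the training samples of a fold only:

* ``gPC`` — global principal components of the whole blood transcriptome
  (top 40/80/100/120 PCs, or the PCs explaining 80/85/90/95% variance);
* ``RG`` — "related genes": individual blood genes whose training-set
  Pearson correlation with the target brain gene passes a threshold
  (|r| > 0.2/0.25/0.3 or signed r > 0.2/0.25/0.3);
* ``mPC`` — principal components of each blood co-expression module
  (top 1/2/5/10 PCs, or 70/75/80/85% variance per module);
* ``RG+mPC`` — the union of an RG selection and an mPC selection.

Enumerating every cutoff yields the canonical grid of 70 configurations
(8 gPC + 6 RG + 8 mPC + 48 RG x mPC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import ExpressionMatrix
from .network import (ModulePCSpec, ModuleSet, PCARecipe, fit_pca,
                      module_pcs, n_components_for)

__all__ = [
    "Family",
    "FeatureConfig",
    "FeatureSet",
    "enumerate_configs",
    "select_gpc",
    "select_rg",
    "select_mpc",
    "select_combined",
    "select_features",
]

GPC_COUNTS = (40, 80, 100, 120)
GPC_VARIANCES = (80, 85, 90, 95)
RG_THRESHOLDS = (0.2, 0.25, 0.3)
MPC_COUNTS = (1, 2, 5, 10)
MPC_VARIANCES = (70, 75, 80, 85)


class Family:
    GPC = "GPC"
    RG = "RG"
    MPC = "MPC"
    RG_MPC = "RG_MPC"

    ALL = (GPC, RG, MPC, RG_MPC)


def _fmt_thr(t: float) -> str:
    return f"{t:g}"


@dataclass(frozen=True)
class RGSpec:
    signed: bool  # True: r > thr; False: |r| > thr
    threshold: float

    @property
    def label(self) -> str:
        return (f"r>{_fmt_thr(self.threshold)}" if self.signed
                else f"|r|>{_fmt_thr(self.threshold)}")


@dataclass(frozen=True)
class FeatureConfig:
    """One member of the 70-configuration feature-selection grid."""

    family: str
    gpc_spec: Optional[ModulePCSpec] = None
    rg_spec: Optional[RGSpec] = None
    mpc_spec: Optional[ModulePCSpec] = None

    def __post_init__(self) -> None:
        need = {
            Family.GPC: ("gpc_spec",),
            Family.RG: ("rg_spec",),
            Family.MPC: ("mpc_spec",),
            Family.RG_MPC: ("rg_spec", "mpc_spec"),
        }[self.family]
        for name in ("gpc_spec", "rg_spec", "mpc_spec"):
            have = getattr(self, name) is not None
            if have != (name in need):
                raise ValueError(f"{self.family} config must populate "
                                 f"exactly {need}")

    @property
    def config_id(self) -> str:
        if self.family == Family.GPC:
            return f"gPC({self.gpc_spec.label})"
        if self.family == Family.RG:
            return f"RG({self.rg_spec.label})"
        if self.family == Family.MPC:
            return f"mPC({self.mpc_spec.label})"
        return f"RG({self.rg_spec.label})+mPC({self.mpc_spec.label})"

    @property
    def uses_modules(self) -> bool:
        return self.family in (Family.MPC, Family.RG_MPC)

    @property
    def supervised(self) -> bool:
        return self.family in (Family.RG, Family.RG_MPC)


def enumerate_configs() -> list[FeatureConfig]:
    """The canonical 70-configuration grid, in stable order.

    gPC counts, gPC variances, RG absolute thresholds, RG signed
    thresholds, mPC counts, mPC variances, then every RG x mPC pair in
    that same nested order: 8 + 6 + 8 + 48 = 70.
    """
    gpc = ([ModulePCSpec("count", k) for k in GPC_COUNTS]
           + [ModulePCSpec("variance", v) for v in GPC_VARIANCES])
    rg = ([RGSpec(False, t) for t in RG_THRESHOLDS]
          + [RGSpec(True, t) for t in RG_THRESHOLDS])
    mpc = ([ModulePCSpec("count", k) for k in MPC_COUNTS]
           + [ModulePCSpec("variance", v) for v in MPC_VARIANCES])
    configs = [FeatureConfig(Family.GPC, gpc_spec=s) for s in gpc]
    configs += [FeatureConfig(Family.RG, rg_spec=s) for s in rg]
    configs += [FeatureConfig(Family.MPC, mpc_spec=s) for s in mpc]
    configs += [FeatureConfig(Family.RG_MPC, rg_spec=r, mpc_spec=m)
                for r in rg for m in mpc]
    return configs


# ---------------------------------------------------------------------------
# recipes: frozen maps from held-out expression to the training feature space
# ---------------------------------------------------------------------------

class GeneLookupRecipe:
    """Features are the expression rows of selected genes themselves."""

    def __init__(self, gene_ids: list[str]):
        self.gene_ids = list(gene_ids)

    def transform(self, expr: ExpressionMatrix) -> np.ndarray:
        if not self.gene_ids:
            return np.empty((expr.n_samples, 0))
        return expr.subset_genes(self.gene_ids).values.T


class PCAProjectionRecipe:
    def __init__(self, recipe: PCARecipe):
        self.recipe = recipe

    def transform(self, expr: ExpressionMatrix) -> np.ndarray:
        return self.recipe.transform(expr)


class ModulePCsRecipe:
    def __init__(self, recipes: list[tuple[PCARecipe, int]]):
        self.recipes = recipes

    def transform(self, expr: ExpressionMatrix) -> np.ndarray:
        if not self.recipes:
            return np.empty((expr.n_samples, 0))
        return np.hstack([rec.transform(expr) for rec, _k in self.recipes])


class ConcatRecipe:
    def __init__(self, parts: list):
        self.parts = parts

    def transform(self, expr: ExpressionMatrix) -> np.ndarray:
        if not self.parts:
            return np.empty((expr.n_samples, 0))
        return np.hstack([p.transform(expr) for p in self.parts])


@dataclass
class FeatureSet:
    """A training feature matrix plus the recipe that rebuilds it for new
    samples from training-fold statistics alone."""

    matrix: np.ndarray  # samples x features
    names: list[str]
    recipe: object
    config_id: str = ""
    fold_id: Optional[int] = None
    target_gene: Optional[str] = None
    status: str = "ok"
    extras: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def transform(self, expr: ExpressionMatrix) -> np.ndarray:
        return self.recipe.transform(expr)


# ---------------------------------------------------------------------------
# selection operations (training data only)
# ---------------------------------------------------------------------------

def select_gpc(train_blood: ExpressionMatrix, spec: ModulePCSpec,
               pca: Optional[PCARecipe] = None) -> FeatureSet:
    """Global blood PCs. ``pca`` may carry a precomputed full-rank PCA of
    the same training submatrix (shared across specs within a fold)."""
    if train_blood.n_samples < 2:
        raise ValueError("global PCA needs at least 2 training samples")
    if pca is None:
        pca = fit_pca(train_blood.values, list(train_blood.gene_ids),
                      unit_scale=False, name_prefix="gPC")
    k = n_components_for(pca, spec)
    kept = PCARecipe(pca.gene_ids, pca.center, pca.scale,
                     pca.loadings[:, :k], pca.feature_names[:k],
                     pca.explained_ratio[:k])
    recipe = PCAProjectionRecipe(kept)
    return FeatureSet(recipe.transform(train_blood), list(kept.feature_names),
                      recipe)


def correlation_with_target(train_blood_values: np.ndarray,
                            y: np.ndarray) -> np.ndarray:
    """Pearson r of every blood gene (rows) with the target vector.

    Zero-variance blood genes get r = 0 (never selected); a zero-variance
    target yields all zeros.
    """
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc ** 2))
    xc = train_blood_values - train_blood_values.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.sum(xc ** 2, axis=1))
    if sy == 0:
        return np.zeros(train_blood_values.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    return np.where(sx > 0, r, 0.0)


def select_rg(train_blood: ExpressionMatrix, target: np.ndarray,
              spec: RGSpec, corr: Optional[np.ndarray] = None) -> FeatureSet:
    """Blood genes correlated with the target brain gene in training.

    ``corr`` may carry precomputed per-gene correlations for this target
    on the same training samples.
    """
    target = np.asarray(target, dtype=float)
    if corr is None:
        corr = correlation_with_target(train_blood.values, target)
    if np.std(target) == 0:
        recipe = GeneLookupRecipe([])
        return FeatureSet(np.empty((train_blood.n_samples, 0)), [], recipe,
                          status="constant_target")
    score = corr if spec.signed else np.abs(corr)
    idx = np.flatnonzero(score > spec.threshold)
    genes = [train_blood.gene_ids[i] for i in idx]
    recipe = GeneLookupRecipe(genes)
    return FeatureSet(recipe.transform(train_blood), list(genes), recipe,
                      extras={"correlations": corr[idx]})


def select_mpc(train_blood: ExpressionMatrix, modules: ModuleSet,
               spec: ModulePCSpec) -> FeatureSet:
    """Per-module PCs, concatenated across all modules of the set."""
    if len(modules) == 0:
        recipe = ModulePCsRecipe([])
        return FeatureSet(np.empty((train_blood.n_samples, 0)), [], recipe,
                          status="no_modules")
    matrix, names, recipes = module_pcs(train_blood, modules, spec)
    return FeatureSet(matrix, names, ModulePCsRecipe(recipes))


def select_combined(rg: FeatureSet, mpc: FeatureSet) -> FeatureSet:
    """Column-wise union of RG genes and module PCs (namespaces disjoint)."""
    matrix = np.hstack([rg.matrix, mpc.matrix])
    names = list(rg.names) + list(mpc.names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names when combining RG and mPC")
    status = "ok"
    if rg.status != "ok" and mpc.status != "ok":
        status = "empty"
    elif rg.status == "constant_target":
        status = "constant_target"
    return FeatureSet(matrix, names, ConcatRecipe([rg.recipe, mpc.recipe]),
                      status=status)


def select_features(config: FeatureConfig, train_blood: ExpressionMatrix,
                    target: Optional[np.ndarray] = None,
                    modules: Optional[ModuleSet] = None,
                    pca: Optional[PCARecipe] = None,
                    corr: Optional[np.ndarray] = None) -> FeatureSet:
    """Dispatch a FeatureConfig to its selection routine."""
    if config.family == Family.GPC:
        fs = select_gpc(train_blood, config.gpc_spec, pca=pca)
    elif config.family == Family.RG:
        fs = select_rg(train_blood, target, config.rg_spec, corr=corr)
    elif config.family == Family.MPC:
        fs = select_mpc(train_blood, modules, config.mpc_spec)
    else:
        rg = select_rg(train_blood, target, config.rg_spec, corr=corr)
        mpc = select_mpc(train_blood, modules, config.mpc_spec)
        fs = select_combined(rg, mpc)
    fs.config_id = config.config_id
    return fs
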