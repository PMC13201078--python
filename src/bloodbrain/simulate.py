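"""Synthetic paired blood-brain expression with known ground truth.

The generator emulates the statistical structure the prediction pipeline
assumes in real paired cohorts: blood expression organized into
co-expression modules by latent per-subject factors, brain genes driven
linearly by those factors or by individual blood marker genes with a
planted blood-explained variance fraction q, technical covariates and sex
with planted linear effects in both tissues, and age entering through
designated age-associated modules so that a predictable brain gene can
inherit an age association through blood. An optional negative-binomial
observation layer produces raw counts for end-to-end testing of
normalization.

Everything operates on a latent log2-like Gaussian scale: the pipeline's
statistics (correlations, PCA, linear models) act on residualized
log-scale data, so Gaussian fixtures exercise the math directly while
count mode exercises preprocessing.

Effect sizes are solved analytically so the planted q is exact in
expectation: a brain signal gene is sqrt(q) * (standardized blood signal)
+ sqrt(1-q) * noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (CovariateTable, ExpressionMatrix, PairedDataset,
                         Stage)
from .utils import substream

__all__ = ["SimulationSpec", "SyntheticTruth", "generate", "truth_eval"]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic paired cohort.

    Defaults describe the reference condition used throughout the test
    suite: 200 subjects, 1,000 blood genes in 10 modules of 30 (the rest
    unstructured), 500 brain genes with a 25/25/10/40 percent mix of
    module-driven / marker-driven / covariate-only / null targets, and a
    planted blood-explained variance fraction q = 0.5 for signal genes.
    """

    n_subjects: int = 200
    n_blood_genes: int = 1000
    n_brain_genes: int = 500
    n_modules: int = 10
    module_size: int = 30
    loading_range: tuple[float, float] = (0.6, 0.9)
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "module_driven": 0.25, "marker_driven": 0.25,
        "covariate_only": 0.10, "null": 0.40})
    q: float | tuple[float, float] = 0.5
    covariate_effect_sd: float = 0.3
    covariate_gene_frac: float = 0.2
    age_range: tuple[float, float] = (20.0, 70.0)
    age_module_frac: float = 0.3
    age_effect: float = 0.4
    noise_sd: float = 1.0
    abundance_mean: float = 5.0
    abundance_sd: float = 2.0
    count_mode: bool = False
    mean_library_size: float = 3e7
    # technical overdispersion only: biological variation lives in the
    # latent layer, so the NB layer is close to Poisson
    dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mix proportions sum to {total}, not 1")
        qs = self.q if isinstance(self.q, tuple) else (self.q, self.q)
        if not (0 < qs[0] <= qs[1] < 1):
            raise ValueError("q must lie in (0, 1)")
        if self.n_modules * self.module_size > self.n_blood_genes:
            raise ValueError("module sizes exceed the blood gene count")
        for name in ("n_subjects", "n_blood_genes", "n_brain_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def draw_q(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if isinstance(self.q, tuple):
            return rng.uniform(self.q[0], self.q[1], size=n)
        return np.full(n, float(self.q))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    brain: pd.DataFrame   # index gene: class, generators, q, age_assoc
    blood: pd.DataFrame   # index gene: module, loading, age_assoc
    age_modules: list[str]
    module_genes: dict[str, list[str]]

    def generators_of(self, gene: str) -> list[str]:
        g = self.brain.loc[gene, "generators"]
        return g.split("|") if g else []


def _covariate_table(rng: np.random.Generator, n: int) -> CovariateTable:
    numeric = {
        "SMRIN": rng.normal(7.0, 0.8, n),
        "SMTSISCH": rng.normal(0.0, 1.0, n),
        "SMEXNCRT": rng.normal(0.0, 1.0, n),
        "SMRRNART": rng.normal(0.0, 1.0, n),
        "SMNTERRT": rng.normal(0.0, 1.0, n),
    }
    categorical = {
        "SMCENTER": rng.choice(["B1", "C1", "D1"], size=n),
        "SEX": rng.choice(["1", "2"], size=n),
    }
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return CovariateTable(ids, numeric, categorical)


def _covariate_design(cov: CovariateTable) -> np.ndarray:
    """Standardized numeric + contrast columns, without intercept."""
    design, names = cov.design_matrix()
    x = design[:, 1:]  # drop intercept
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    return x / np.where(sd > 0, sd, 1.0)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def generate(spec: SimulationSpec) -> tuple[PairedDataset, SyntheticTruth]:
    """Generate one paired cohort and its ground truth.

    Same spec (including seed) always yields bitwise-identical output.
    """
    rng = substream(spec.seed, "simulate")
    n = spec.n_subjects
    blood_ids = [f"BL{i + 1:05d}" for i in range(spec.n_blood_genes)]
    brain_ids = [f"BR{i + 1:05d}" for i in range(spec.n_brain_genes)]

    cov = _covariate_table(rng, n)
    age = rng.uniform(*spec.age_range, size=n)
    age_std = _standardize(age)
    xc = _covariate_design(cov)

    # --- blood: module factors and member genes -----------------------
    module_ids = [f"mod{m + 1:02d}" for m in range(spec.n_modules)]
    n_age_mod = int(round(spec.age_module_frac * spec.n_modules))
    age_modules = list(rng.choice(module_ids, size=n_age_mod, replace=False))
    factors = np.zeros((spec.n_modules, n))
    for m, mid in enumerate(module_ids):
        z = rng.standard_normal(n)
        if mid in age_modules and spec.age_effect > 0:
            g = spec.age_effect
            factors[m] = np.sqrt(1 - g ** 2) * z + g * age_std
        else:
            factors[m] = z

    blood = np.empty((spec.n_blood_genes, n))
    blood_module = np.array([""] * spec.n_blood_genes, dtype=object)
    blood_loading = np.zeros(spec.n_blood_genes)
    gi = 0
    for m, mid in enumerate(module_ids):
        for _ in range(spec.module_size):
            lam = rng.uniform(*spec.loading_range)
            blood[gi] = (lam * factors[m]
                         + np.sqrt(1 - lam ** 2) * rng.standard_normal(n))
            blood_module[gi] = mid
            blood_loading[gi] = lam
            gi += 1
    blood[gi:] = rng.standard_normal((spec.n_blood_genes - gi, n))

    # --- brain genes by class -----------------------------------------
    classes = list(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    gene_class = rng.choice(classes, size=spec.n_brain_genes, p=probs)
    qs = spec.draw_q(rng, spec.n_brain_genes)
    brain = np.empty((spec.n_brain_genes, n))
    generators: list[str] = []
    age_assoc = np.zeros(spec.n_brain_genes)

    module_index = {mid: m for m, mid in enumerate(module_ids)}
    module_gene_lists = {
        mid: [blood_ids[i] for i in np.flatnonzero(blood_module == mid)]
        for mid in module_ids}

    for i in range(spec.n_brain_genes):
        cls = gene_class[i]
        noise = spec.noise_sd * rng.standard_normal(n)
        if cls == "module_driven":
            k = int(rng.integers(1, 4))
            mods = list(rng.choice(module_ids, size=k, replace=False))
            w = rng.uniform(0.5, 1.0, size=k)
            signal = w @ factors[[module_index[m] for m in mods]]
            s = _standardize(signal)
            brain[i] = (np.sqrt(qs[i]) * s
                        + np.sqrt(1 - qs[i]) * _standardize(noise))
            generators.append("|".join(mods))
            if any(m in age_modules for m in mods):
                age_assoc[i] = 1.0
        elif cls == "marker_driven":
            k = int(rng.integers(1, 6))
            idx = rng.choice(spec.n_blood_genes, size=k, replace=False)
            w = rng.uniform(0.5, 1.0, size=k)
            signal = w @ blood[idx]
            s = _standardize(signal)
            brain[i] = (np.sqrt(qs[i]) * s
                        + np.sqrt(1 - qs[i]) * _standardize(noise))
            generators.append("|".join(blood_ids[j] for j in idx))
            if any(blood_module[j] in age_modules for j in idx):
                age_assoc[i] = 1.0
        elif cls == "covariate_only":
            beta = rng.normal(0, 1.0, xc.shape[1])
            brain[i] = _standardize(xc @ beta) + 0.5 * noise
            generators.append("")
            qs[i] = np.nan
        else:  # null
            brain[i] = noise
            generators.append("")
            qs[i] = np.nan

    # --- covariate effects planted in both tissues --------------------
    if spec.covariate_effect_sd > 0:
        for mat in (blood, brain):
            n_aff = int(round(spec.covariate_gene_frac * mat.shape[0]))
            rows = rng.choice(mat.shape[0], size=n_aff, replace=False)
            betas = rng.normal(0, spec.covariate_effect_sd,
                               size=(n_aff, xc.shape[1]))
            mat[rows] += betas @ xc.T

    # --- abundance offsets, independent of class and q ----------------
    blood += rng.normal(spec.abundance_mean, spec.abundance_sd,
                        spec.n_blood_genes)[:, None]
    brain += rng.normal(spec.abundance_mean, spec.abundance_sd,
                        spec.n_brain_genes)[:, None]

    sample_ids = cov.sample_ids
    if spec.count_mode:
        blood_expr = _to_counts(blood, blood_ids, sample_ids, spec,
                                substream(spec.seed, "counts", "blood"))
        brain_expr = _to_counts(brain, brain_ids, sample_ids, spec,
                                substream(spec.seed, "counts", "brain"))
    else:
        blood_expr = ExpressionMatrix(blood_ids, sample_ids, blood,
                                      Stage.NORMALIZED_LOG2)
        brain_expr = ExpressionMatrix(brain_ids, sample_ids, brain,
                                      Stage.NORMALIZED_LOG2)

    truth = SyntheticTruth(
        brain=pd.DataFrame({
            "class": gene_class, "generators": generators, "q": qs,
            "age_assoc": age_assoc,
        }, index=brain_ids),
        blood=pd.DataFrame({
            "module": blood_module, "loading": blood_loading,
            "age_assoc": [1.0 if m in age_modules else 0.0
                          for m in blood_module],
        }, index=blood_ids),
        age_modules=age_modules,
        module_genes=module_gene_lists,
    )
    paired = PairedDataset(blood_expr, brain_expr, cov, age=age,
                           tissue_label="synthetic_brain")
    return paired, truth


def _to_counts(latent_log2: np.ndarray, gene_ids: list[str],
               sample_ids: list[str], spec: SimulationSpec,
               rng: np.random.Generator) -> ExpressionMatrix:
    """Negative-binomial observation layer over the latent log2 matrix.

    The latent value is interpreted as log2 counts-per-million; each
    sample gets a log-normal library size around the spec mean.
    """
    cpm = 2.0 ** latent_log2
    lib = rng.lognormal(np.log(spec.mean_library_size), 0.2,
                        size=len(sample_ids))
    mu = cpm / 1e6 * lib[None, :]
    # NB with var = mu + dispersion * mu^2, via gamma-Poisson mixture
    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(float)
    return ExpressionMatrix(gene_ids, sample_ids, counts, Stage.RAW_COUNTS)


def truth_eval(truth: SyntheticTruth,
               module_set=None,
               results: Optional[pd.DataFrame] = None,
               families: Optional[dict[str, str]] = None) -> dict:
    """Recovery metrics against the generator's ground truth.

    * module recovery: adjusted Rand index between planted module labels
      and the detected leaf-module assignment of blood genes that belong
      to a planted module;
    * predictability recovery: per-class mean avg CV r (and planted q);
    * family attribution: fraction of module-driven genes whose best
      configuration is module-based (mPC or RG+mPC) and of marker-driven
      genes whose best is correlation-based (RG or RG+mPC).
    """
    out: dict = {}
    if module_set is not None:
        from sklearn.metrics import adjusted_rand_score

        planted = truth.blood["module"]
        in_module = planted[planted != ""].index
        detected: dict[str, str] = {}
        for module in module_set.leaves:
            for g in module.gene_ids:
                detected[g] = module.module_id
        genes = [g for g in in_module]
        if not genes:
            raise ValueError("truth lists no module genes")
        a = [planted[g] for g in genes]
        b = [detected.get(g, f"unassigned_{g}") for g in genes]
        out["module_ari"] = float(adjusted_rand_score(a, b))

    if results is not None:
        from .integrate import integrate_best

        mat = results.pivot(index="gene", columns="config_id",
                            values="avg_cv_r") \
            if "config_id" in results.columns else results
        common = [g for g in mat.index if g in truth.brain.index]
        if not common:
            raise ValueError("result genes do not match the truth table")
        mat = mat.loc[common]
        per_class = {}
        best = integrate_best(mat, "all")
        for cls in truth.brain["class"].unique():
            genes = [g for g in common
                     if truth.brain.loc[g, "class"] == cls]
            vals = best.values.reindex(genes)
            q_vals = truth.brain.loc[genes, "q"].to_numpy(dtype=float)
            per_class[cls] = {
                "n": len(genes),
                "mean_avg_cv_r": float(np.nanmean(vals)) if genes else np.nan,
                "mean_q": float(np.mean(q_vals[~np.isnan(q_vals)]))
                if np.any(~np.isnan(q_vals)) else np.nan,
            }
        out["per_class"] = per_class

        if families is not None:
            winner_family = best.per_gene["best_config"].map(families)
            for cls, fams in (("module_driven", {"MPC", "RG_MPC"}),
                              ("marker_driven", {"RG", "RG_MPC"})):
                genes = [g for g in common
                         if truth.brain.loc[g, "class"] == cls]
                if genes:
                    won = winner_family.reindex(genes).isin(fams)
                    out[f"{cls}_family_share"] = float(won.mean())
    return out
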