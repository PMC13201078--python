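"""Outer cross-validation: folds, leakage safety, and the result grid."""

import warnings

import numpy as np
import pandas as pd
import pytest

import bloodbrain as bb
from bloodbrain.containers import (CovariateTable, ExpressionMatrix,
                                   PairedDataset, RunConfig)
from bloodbrain.cv import make_folds, pearson_r, run_gene_config, run_grid
from bloodbrain.features import FeatureConfig, Family, RGSpec
from conftest import family_representatives


def _paired(rng, n=40, n_blood=20, brain_rows=None):
    blood = rng.normal(size=(n_blood, n))
    if brain_rows is None:
        brain_rows = rng.normal(size=(2, n))
    ids = [f"s{j}" for j in range(n)]
    return PairedDataset(
        ExpressionMatrix([f"bl{i}" for i in range(n_blood)], ids, blood,
                         bb.Stage.RESIDUALIZED),
        ExpressionMatrix([f"br{i}" for i in range(len(brain_rows))], ids,
                         np.asarray(brain_rows), bb.Stage.RESIDUALIZED),
        CovariateTable(ids, {"SMRIN": rng.normal(size=n)}, {}),
    )


class TestFolds:
    def test_balanced_sizes(self):
        plan = make_folds(10, 5, seed=1)
        sizes = sorted(np.bincount(plan.labels))
        assert sizes == [2, 2, 2, 2, 2]
        plan11 = make_folds(11, 5, seed=1)
        assert sorted(np.bincount(plan11.labels)) == [2, 2, 2, 2, 3]

    def test_deterministic(self):
        np.testing.assert_array_equal(make_folds(23, 5, seed=9).labels,
                                      make_folds(23, 5, seed=9).labels)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_folds(9, 5, seed=0)

    def test_partition_covers_everything(self):
        plan = make_folds(17, 4, seed=3)
        all_idx = np.concatenate([plan.test_indices(f) for f in range(4)])
        assert sorted(all_idx) == list(range(17))


class TestRunGeneConfig:
    def test_perfect_linear_signal_is_recovered(self, rng):
        n = 50
        blood = rng.normal(size=(10, n))
        # coefficients large enough that every generator's marginal
        # correlation clears the 0.2 selection threshold in every fold
        brain = (2 * blood[0] - 1.5 * blood[3] + blood[7])[None, :]
        paired = _paired(rng, n=n, n_blood=10, brain_rows=brain)
        paired.blood.values[:] = blood
        plan = make_folds(n, 5, seed=2)
        config = FeatureConfig(Family.RG, rg_spec=RGSpec(False, 0.2))
        res = run_gene_config(paired, "br0", config, plan,
                              RunConfig(seed=2))
        assert res.avg_cv_r >= 0.999
        assert res.status == "ok"

    def test_fold_r_matches_manual_recomputation(self, rng):
        """Recompute each fold's held-out correlation from scratch with
        an independent lstsq path on a small worked case."""
        n = 15
        paired = _paired(rng, n=n, n_blood=6)
        plan = make_folds(n, 3, seed=5)
        config = FeatureConfig(Family.RG, rg_spec=RGSpec(False, 0.2))
        res = run_gene_config(paired, "br0", config, plan, RunConfig(seed=5))
        y = paired.brain.values[0]
        for fold in range(3):
            tr, te = plan.train_indices(fold), plan.test_indices(fold)
            x = paired.blood.values
            r = np.array([np.corrcoef(x[i, tr], y[tr])[0, 1]
                          for i in range(x.shape[0])])
            sel = np.flatnonzero(np.abs(r) > 0.2)
            if sel.size == 0:
                assert np.isnan(res.fold_r[fold])
                continue
            design = np.column_stack([np.ones(tr.size), x[sel][:, tr].T])
            beta, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
            pred = np.column_stack([np.ones(te.size),
                                    x[sel][:, te].T]) @ beta
            expected = np.corrcoef(pred, y[te])[0, 1]
            assert res.fold_r[fold] == pytest.approx(expected, abs=1e-10)

    def test_constant_prediction_fold_is_undefined(self, rng):
        n = 20
        paired = _paired(rng, n=n)
        # target uncorrelated beyond threshold with every blood gene is
        # possible; force it by thresholding at 0.999
        config = FeatureConfig(Family.RG, rg_spec=RGSpec(False, 0.999))
        plan = make_folds(n, 4, seed=1)
        res = run_gene_config(paired, "br0", config, plan, RunConfig(seed=1))
        assert res.status == "unfittable"
        assert np.isnan(res.avg_cv_r)


class TestRunGrid:
    def test_row_count_and_order_independence(self, small_cohort):
        paired, _ = small_cohort
        plan = make_folds(paired.n_samples, 5, seed=3)
        configs = family_representatives()[:3]
        genes = paired.brain.gene_ids[:2]
        opts = RunConfig(seed=3, min_module_size=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g1 = run_grid(paired, genes, configs, plan, opts)
            g2 = run_grid(paired, genes[::-1], configs, plan, opts)
        assert len(g1.table) == 6
        pd.testing.assert_frame_equal(g1.table, g2.table)

    def test_grid_matches_standalone_gene_config(self, small_cohort):
        """The fold-cached grid path and the uncached single-gene path
        produce identical numbers."""
        paired, _ = small_cohort
        plan = make_folds(paired.n_samples, 5, seed=4)
        config = family_representatives()[3]  # RG+mPC exercises the cache
        gene = paired.brain.gene_ids[0]
        opts = RunConfig(seed=4, min_module_size=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = run_grid(paired, [gene], [config], plan, opts)
            solo = run_gene_config(paired, gene, config, plan, opts)
        np.testing.assert_allclose(grid.results[0].fold_r, solo.fold_r,
                                   equal_nan=True)

    def test_unknown_genes_warn_and_are_skipped(self, rng):
        paired = _paired(rng)
        plan = make_folds(paired.n_samples, 5, seed=0)
        config = family_representatives()[1]
        with pytest.warns(UserWarning, match="not in the brain"):
            grid = run_grid(paired, ["br0", "nope"], [config], plan,
                            RunConfig(seed=0))
        assert sorted(set(grid.table["gene"])) == ["br0"]

    def test_no_leakage_from_heldout_brain_values(self, rng):
        """Perturbing held-out brain values must not change the held-out
        predictions of any fold (they may change the reported r)."""
        n = 30
        paired = _paired(rng, n=n)
        plan = make_folds(n, 5, seed=6)
        config = family_representatives()[1]
        opts = RunConfig(seed=6)
        grid = run_grid(paired, ["br0"], [config], plan, opts,
                        collect_predictions=True)
        fold0_test = plan.test_indices(0)
        tampered = paired.brain.values.copy()
        tampered[0, fold0_test] += 100.0
        paired2 = PairedDataset(
            paired.blood,
            ExpressionMatrix(paired.brain.gene_ids, paired.brain.sample_ids,
                             tampered, bb.Stage.RESIDUALIZED),
            paired.covariates)
        grid2 = run_grid(paired2, ["br0"], [config], plan, opts,
                         collect_predictions=True)
        p1 = grid.predictions[("br0", config.config_id)][fold0_test]
        p2 = grid2.predictions[("br0", config.config_id)][fold0_test]
        np.testing.assert_array_equal(p1, p2)

    def test_race_mode_reports_the_better_model(self, rng):
        n = 40
        blood = rng.normal(size=(8, n))
        brain = (blood[0] + 0.3 * rng.normal(size=n))[None, :]
        paired = _paired(rng, n=n, n_blood=8, brain_rows=brain)
        paired.blood.values[:] = blood
        plan = make_folds(n, 5, seed=7)
        config = FeatureConfig(Family.RG, rg_spec=RGSpec(False, 0.2))
        raced = run_gene_config(paired, "br0", config, plan,
                                RunConfig(seed=7, model_mode="race"))
        linear = run_gene_config(paired, "br0", config, plan,
                                 RunConfig(seed=7, model_mode="linear"))
        enet = run_gene_config(paired, "br0", config, plan,
                               RunConfig(seed=7, model_mode="elastic_net"))
        assert raced.avg_cv_r == pytest.approx(
            max(linear.avg_cv_r, enet.avg_cv_r), abs=1e-12)


def test_feature_trace_records_provenance(rng):
    paired = _paired(rng)
    plan = make_folds(paired.n_samples, 5, seed=8)
    config = family_representatives()[1]
    grid = run_grid(paired, ["br0"], [config], plan, RunConfig(seed=8),
                    trace_features=True)
    trace = grid.feature_trace
    assert set(trace.columns) == {"gene", "config_id", "fold", "feature",
                                  "family"}
    counts = trace.groupby("fold").size().reindex(range(5), fill_value=0)
    np.testing.assert_array_equal(counts.to_numpy(),
                                  grid.results[0].n_features)


def test_pearson_r_degenerate_cases():
    assert np.isnan(pearson_r(np.ones(5), np.arange(5)))
    assert pearson_r(np.arange(5), np.arange(5)) == pytest.approx(1.0)


def test_out_of_fold_assembly_covers_each_sample_once(small_grid):
    pred = next(iter(small_grid.grid.predictions.values()))
    assert np.sum(np.isnan(pred)) == 0
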