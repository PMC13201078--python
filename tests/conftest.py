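import warnings

import numpy as np
import pytest

import bloodbrain as bb
from bloodbrain.containers import RunConfig
from bloodbrain.features import FeatureConfig, Family, RGSpec
from bloodbrain.network import ModulePCSpec
from bloodbrain.preprocess import residualize


def residualized(paired: bb.PairedDataset) -> bb.PairedDataset:
    """Residualize both tissues of a generated cohort against its
    covariates."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        blood = residualize(paired.blood, paired.covariates)
        brain = residualize(paired.brain, paired.covariates)
    return bb.PairedDataset(blood, brain, paired.covariates,
                            age=paired.age, tissue_label=paired.tissue_label)


def family_representatives() -> list[FeatureConfig]:
    """One configuration per feature family (reduced grid for speed)."""
    return [
        FeatureConfig(Family.GPC, gpc_spec=ModulePCSpec("count", 40)),
        FeatureConfig(Family.RG, rg_spec=RGSpec(False, 0.2)),
        FeatureConfig(Family.MPC, mpc_spec=ModulePCSpec("count", 1)),
        FeatureConfig(Family.RG_MPC, rg_spec=RGSpec(False, 0.2),
                      mpc_spec=ModulePCSpec("count", 1)),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-subject cohort with 4 blood modules, residualized."""
    spec = bb.SimulationSpec(n_subjects=80, n_blood_genes=200,
                             n_brain_genes=30, n_modules=4, module_size=20,
                             seed=11)
    paired, truth = bb.generate(spec)
    return residualized(paired), truth


@pytest.fixture(scope="session")
def small_grid(small_cohort):
    """Family-representative grid fitted on the small cohort."""
    paired, truth = small_cohort
    options = RunConfig(seed=7, min_module_size=8)
    model = bb.BloodBrainImputation(paired,
                                    configs=family_representatives(),
                                    options=options)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = model.fit(collect_predictions=True)
    return results


@pytest.fixture
def rng():
    return np.random.default_rng(0)
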