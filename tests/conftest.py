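import numpy as np
import pandas as pd
import pytest

from vttml import CohortSpec, generate_cohort
from vttml.predictor import PipelineConfig

#: data seed of the fixed synthetic stand-in cohort used across tests
TRIAL_DATA_SEED = 314159


def tiny_grid():
    """Two-point grid for fast structural tests."""
    return [
        {"alpha": 1e-3, "penalty": "l2", "learning_rate": "optimal"},
        {"alpha": 1e-1, "penalty": "l2", "learning_rate": "optimal"},
    ]


@pytest.fixture
def tiny_config():
    return PipelineConfig(grid=tiny_grid(), inner_folds=3, seed=0)


@pytest.fixture(scope="session")
def trial_cohort():
    """Synthetic stand-in for the trial dataset at the study conditions:
    20 patients, 7 responders, 62 baseline features, 7 plasma markers."""
    return generate_cohort(CohortSpec(seed=TRIAL_DATA_SEED))


@pytest.fixture(scope="session")
def small_cohort():
    """Fast small cohort for structural/pipeline tests."""
    spec = CohortSpec(n_patients=12, n_responders=4, n_features=14,
                      effect_map={"Ki67 index": -2.0, "CD31/CD34 MVD": 2.0},
                      n_genes=300, n_de_genes=10, missing_rate=0.04,
                      collinear_groups=[], seed=7)
    return generate_cohort(spec)


@pytest.fixture
def toy_table():
    """Complete 6x4 feature table with known structure."""
    from vttml.containers import FeatureTable
    rng = np.random.default_rng(3)
    vals = pd.DataFrame(
        rng.normal(size=(6, 4)),
        index=[f"P{i}" for i in range(6)],
        columns=["a", "b", "c", "d"],
    )
    return FeatureTable(vals)
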