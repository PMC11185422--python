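import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vernier2ifc.data import collapse_to_level_summaries
from vernier2ifc.design import Task
from vernier2ifc.observers import ObserverSpec, simulate_prediction_table
from vernier2ifc.synth import GroundTruth, default_ground_truth, generate_dataset


@pytest.fixture(scope="session")
def small_masked_trials():
    """A compact masked cohort (4 participants, 60 trials/level) for data and
    metric tests; driven by the diagonal marginalizing-confidence observer."""
    truth = default_ground_truth(Task.MASKED, model_id=3, sigma_d=0.2,
                                 n_participants=4, seed=10)
    truth.trials_per_level = [60] * 4
    return generate_dataset(truth, seed=11)


@pytest.fixture(scope="session")
def small_masked_summaries(small_masked_trials):
    return collapse_to_level_summaries(small_masked_trials)


@pytest.fixture(scope="session")
def table_m3():
    """Prediction table of observer 3 over the full strength and noise grids
    at a Monte-Carlo size adequate for fitting tests."""
    return simulate_prediction_table(ObserverSpec(3), n_sim=20_000, seed=42)


@pytest.fixture(scope="session")
def chance_truth():
    """A cohort with zero evidence at every level: all accuracies at chance."""
    n_levels, n_parts = 6, 6
    return GroundTruth(
        task=Task.MASKED,
        observer=ObserverSpec(3),
        c_per_participant=[np.zeros(n_levels)] * n_parts,
        sigma_d_per_participant=[0.0] * n_parts,
        trials_per_level=[120] * n_parts,
    )
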