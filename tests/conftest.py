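import pandas as pd
import pytest

from wmprecision.cohort import GenerativeConfig, simulate_experiment
from wmprecision.precision import compute_errors, estimate_precision, zscore_precisions


@pytest.fixture(scope="session")
def exp2_dataset():
    """Small simulated replication-experiment dataset (auditory WM + perception)."""
    cfg = GenerativeConfig(n_participants=60, seed=11)
    participants, responses, pframe = simulate_experiment(
        cfg, experiment="exp2", trials_per_condition=30
    )
    precision = zscore_precisions(estimate_precision(compute_errors(responses)))
    return {
        "participants": participants,
        "responses": responses,
        "participants_frame": pframe,
        "precision": precision,
    }


@pytest.fixture(scope="session")
def exp1_dataset():
    """Small simulated first-experiment dataset (four WM domains)."""
    cfg = GenerativeConfig(n_participants=50, seed=5)
    participants, responses, pframe = simulate_experiment(
        cfg, experiment="exp1", trials_per_condition=14
    )
    precision = zscore_precisions(estimate_precision(compute_errors(responses)))
    return {
        "participants": participants,
        "responses": responses,
        "participants_frame": pframe,
        "precision": precision,
    }
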