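"""Shared fixtures.

Expensive artefacts (the 140-study reference dataset and its final-model
fit) are session-scoped so every test file reuses one simulation and one
maximum-likelihood fit.
"""

import pytest

from adprog.data import ArmObservation, StudyArm, TrialSet
from adprog.estimation import final_model_spec, fit
from adprog.simulate import default_config, generate_trial_set

#: one fixed seed for the whole suite's reference dataset
SUITE_SEED = 17


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def default_set(default_cfg):
    """Reference study conditions: 140 studies at the generating truth."""
    ts, truth = generate_trial_set(default_cfg)
    return ts, truth


@pytest.fixture(scope="session")
def final_fit(default_set):
    """Final covariate model fitted to the reference dataset."""
    ts, _ = default_set
    fr = fit(ts, final_model_spec(ts), n_restarts=2, seed=SUITE_SEED)
    assert fr.converged
    return fr


@pytest.fixture()
def tiny_set():
    """Hand-built two-study TrialSet for contract tests."""
    arms = [
        StudyArm(
            study_id="A", baseline_adas=24.5, baseline_age=73.5,
            randomized_n=120, publication_year=2012, region="NorthAmerica",
            add_on=False,
            observations=(
                ArmObservation(12.0, 0.4, 100),
                ArmObservation(26.0, 1.1, 95),
                ArmObservation(52.0, 3.0, 90),
            )),
        StudyArm(
            study_id="B", baseline_adas=30.0, baseline_age=68.0,
            randomized_n=60, publication_year=2001, region="EastAsia",
            add_on=False,
            observations=(
                ArmObservation(13.0, 0.2, 55),
                ArmObservation(26.0, 0.9, 50),
            )),
    ]
    return TrialSet(arms=arms)
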