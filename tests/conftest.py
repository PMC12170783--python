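"""Shared fixtures: small synthetic signals and a session-scoped trained model.

The trained brain-age model is expensive (a 200-subject healthy cohort run
through the full feature pipeline), so it is built once per session and
shared by the model-behaviour tests and the end-to-end acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from sleepbai.pipeline import cohort_stage_vectors, subject_bai_table, train_model_on_cohort
from sleepbai.simulate import SimulationConfig, healthy_training_group, simulate_cohort_table

#: desk-scale night length (epochs cover all five stages; see docs/methods.md)
TRAIN_NIGHT_HR = 0.5


@pytest.fixture(scope="session")
def healthy_model_bundle():
    """(features table, model) for a 200-subject brain-healthy cohort."""
    config = SimulationConfig(groups=[healthy_training_group(200)], seed=101)
    cohort = simulate_cohort_table(config)
    features = cohort_stage_vectors(cohort, config, duration_hr=TRAIN_NIGHT_HR)
    model = train_model_on_cohort(features, seed=0)
    return features, model


@pytest.fixture(scope="session")
def heldout_offset0_bai(healthy_model_bundle):
    """Mean BAI table for a held-out offset-0 cohort of 200 subjects."""
    _, model = healthy_model_bundle
    config = SimulationConfig(groups=[healthy_training_group(200)], seed=202)
    cohort = simulate_cohort_table(config)
    features = cohort_stage_vectors(cohort, config, duration_hr=TRAIN_NIGHT_HR)
    return subject_bai_table(features, model)


@pytest.fixture()
def gauss_epochs():
    """Clean Gaussian epochs (E=8, C=2) at 250 Hz, std 20 µV, max < 200 µV."""
    rng = np.random.default_rng(42)
    x = rng.normal(0.0, 20.0, size=(8, 2, 7500))
    return np.clip(x, -180.0, 180.0)


@pytest.fixture()
def wearable_recording():
    """One deterministic 0.25-hr wearable night with its hypnogram."""
    from sleepbai.simulate import subject_night

    config = SimulationConfig(seed=7)
    row = {"subject_id": "fix-1", "age": 40.0, "true_brain_age_offset": 0.0,
           "device": "wearable", "group": "fixture"}
    rec, hyp, _ = subject_night(row, 1, config, duration_hr=0.25)
    return rec, hyp
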