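"""Shared fixtures: synthetic cohorts at several scales.

The full-size cohort (10 subjects, default schedule) drives the
parameter-recovery checks; miniature cohorts with a shortened activity
schedule keep the unit tests fast while exercising identical code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from actipatch import evaluation, preprocessing
from actipatch.cnn_classifier import CnnConfig
from actipatch.synthetic_data import GeneratorConfig, generate_cohort_data

#: Shortened schedule for unit tests (same structure, ~4 min per subject).
TINY_SCHEDULE = (
    ("lying", 40.0),
    ("sitting", 60.0),
    ("standing", 40.0),
    ("walking", 50.0),
    ("jogging", 30.0),
)


def tiny_config(n_subjects: int = 3, seed: int = 0, **overrides) -> GeneratorConfig:
    return GeneratorConfig(
        n_subjects=n_subjects, seed=seed, schedule=TINY_SCHEDULE, **overrides
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three short subjects for fast pipeline tests."""
    return generate_cohort_data(tiny_config(n_subjects=3, seed=0))


@pytest.fixture(scope="session")
def cohort10():
    """The default study-scale cohort: 10 subjects, full schedule, seed 1."""
    return generate_cohort_data(GeneratorConfig(n_subjects=10, seed=1))


@pytest.fixture(scope="session")
def cohort10_subjects(cohort10):
    return {sid: (rec, lab) for sid, (rec, lab, _hr) in cohort10.items()}


@pytest.fixture(scope="session")
def loocv10(cohort10_subjects):
    """Full LOOCV of the CNN on the study-scale cohort (the expensive fixture)."""
    config = CnnConfig(epochs=30, seed=1)
    return evaluation.run_loocv(cohort10_subjects, config)


@pytest.fixture(scope="session")
def cohort6_subjects():
    """Six full-schedule subjects for the direction-check sweeps."""
    data = generate_cohort_data(GeneratorConfig(n_subjects=6, seed=1))
    return {sid: (rec, lab) for sid, (rec, lab, _hr) in data.items()}
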