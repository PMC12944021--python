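"""Shared fixtures.

The desk-scale LOPO run is expensive (eight folds of GRU training), so it is
computed once per session and shared between the pipeline-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from densehar.models import reduced_gru_preset
from densehar.synthetic import desk_profiles, generate_cohort
from densehar.training import TrainingConfig, lopo_cv

DESK_SEED = 11


@pytest.fixture(scope="session")
def desk_cohorts():
    """Desk-scale synthetic cohorts: 8 young + 6 old participants x ~5 min."""
    young_profile, old_profile, models = desk_profiles()
    young = generate_cohort(young_profile, models, seed=DESK_SEED)
    old = generate_cohort(old_profile, models, seed=DESK_SEED + 1)
    return young, old


@pytest.fixture(scope="session")
def desk_tcfg():
    return TrainingConfig(seed=DESK_SEED, max_epochs=10, patience=3, batch_size=32)


@pytest.fixture(scope="session")
def lopo_run(desk_cohorts, desk_tcfg):
    """Full LOPO-CV of the reduced GRU preset on the desk young cohort."""
    young, _ = desk_cohorts
    return lopo_cv(young, reduced_gru_preset(), desk_tcfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three participants x 1 min — structural checks that need real folds."""
    from dataclasses import replace

    young_profile, _, models = desk_profiles()
    profile = replace(young_profile, participant_count=3, duration_mean=1.0,
                      duration_sd=0.05)
    return generate_cohort(profile, models, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
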