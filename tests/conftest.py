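"""Shared fixtures: speckle frames, tracked synthetic cohorts, grids.

The expensive fixtures (full 10-participant cohort with DISC fields) are
session-scoped and computed once; everything is seeded so the suite is
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import discmotion as dm
from discmotion.session import StimulusSchedule, compute_session_fields
from discmotion.synthetic import (
    SyntheticCohortConfig,
    cohort_grid,
    generate_cohort,
    make_speckle,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


COHORT_SEED = 7
MIXED_SEED = 11


@pytest.fixture(scope="session")
def small_grid() -> dm.GridSpec:
    return dm.GridSpec(subset_size=21, step=12, search_radius=5)


@pytest.fixture(scope="session")
def analysis_grid() -> dm.GridSpec:
    """Grid proportioned to the 200-px synthetic cohort frames."""
    return cohort_grid()


@pytest.fixture(scope="session")
def speckle_frame() -> dm.GrayFrame:
    return make_speckle((160, 160), seed=1)


@pytest.fixture(scope="session")
def strong_cohort():
    """Default (strong-effect) 10-participant cohort with DISC fields computed.

    This is the desk-scale stand-in for the study's participant videos: 230
    frames each under the default schedule, mouth-corner vs brow deformation
    ramping 1 to 6 px over each viewing block.
    """
    config = SyntheticCohortConfig(seed=COHORT_SEED)
    cohort = generate_cohort(config)
    grid = cohort_grid(config)
    for syn in cohort:
        compute_session_fields(syn.session, grid, subpixel=True)
    return config, cohort


@pytest.fixture(scope="session")
def strong_sessions(strong_cohort):
    _, cohort = strong_cohort
    return {syn.session.participant_id: syn.session for syn in cohort}


@pytest.fixture(scope="session")
def mixed_cohort():
    """Reduced cohort with two weak-responding participants (shorter schedule,
    smaller frames) for participant-level ordering checks."""
    schedule = StimulusSchedule(
        (
            ("neutral", 4.0),
            ("happy", 24.0),
            ("neutral", 4.0),
            ("sad", 24.0),
            ("neutral", 4.0),
        )
    )
    config = SyntheticCohortConfig(
        n_participants=10,
        frame_shape=(160, 160),
        schedule=schedule,
        n_weak=2,
        seed=MIXED_SEED,
    )
    cohort = generate_cohort(config)
    grid = cohort_grid(config)
    for syn in cohort:
        compute_session_fields(syn.session, grid, subpixel=True)
    return config, cohort


@pytest.fixture(scope="session")
def null_matrix(analysis_grid):
    """Similarity matrix of label-free frames (shared texture + noise only)."""
    from discmotion.similarity import build_matrix

    rng = np.random.default_rng(1234)
    base = make_speckle((200, 200), seed=rng)
    frames = [
        dm.GrayFrame(
            np.clip(base.pixels + rng.normal(0.0, 2.0, base.pixels.shape), 0, 255),
            frame_index=i,
            label="happy" if i < 12 else "sad",
        )
        for i in range(24)
    ]
    return build_matrix(frames, analysis_grid)
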