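"""Shared fixtures: small phantoms and sessions generated at test time."""

import numpy as np
import pytest

from fusbmi import TaskConfig, generate_session, make_phantom

SMALL_GRID = (24, 32)


@pytest.fixture(scope="session")
def phantom():
    """Two-patch phantom on a small grid (fast; same statistical structure)."""
    return make_phantom(seed=11, grid=SMALL_GRID, patch_area_vox=40)


@pytest.fixture(scope="session")
def phantom_null():
    """Same layout with zero response amplitude: pure noise sessions."""
    return make_phantom(seed=11, grid=SMALL_GRID, patch_area_vox=40, amplitude=0.0)


@pytest.fixture(scope="session")
def session_2t(phantom):
    """Sixty-trial two-target session with default noise."""
    return generate_session(phantom, TaskConfig(n_targets=2), n_trials=60, seed=21)


@pytest.fixture(scope="session")
def session_8t(phantom):
    """Sixty-four-trial eight-target session (8 cues per direction)."""
    return generate_session(phantom, TaskConfig(n_targets=8), n_trials=64, seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
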