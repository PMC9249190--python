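"""Shared fixtures: small, fast synthetic studies.

Everything is generated at test time from seeded configurations; reduced
sampling rates / trial counts are used wherever the property under test is
invariant to scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from cortimuscle.preprocess import preprocess_session
from cortimuscle.simulate import SimulationConfig, simulate_session

# fast config: fs 400 Hz keeps all bands below Nyquist (gamma tops at 80 Hz)
FAST = dict(fs=400.0, rest_s=0.5, contraction_s=5.0)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(n_subjects=1, n_trials_per_task=2, seed=7, **FAST)


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    return simulate_session(tiny_config, subject_id=0, task_id=1)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_session):
    # sEMG band capped below the 200 Hz Nyquist of the fast config
    return preprocess_session(tiny_session, emg_band=(5.0, 150.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
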