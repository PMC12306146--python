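"""Shared fixtures.

The expensive fixtures (trained networks) are session-scoped and sized so
the whole suite stays desk-scale; tests that only need structure use tiny
configurations instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from ipdnet import TaskConfig, TrainConfig, train
from ipdnet.seeding import rng_for


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def task_small() -> TaskConfig:
    """A miniature task for structural tests."""
    return TaskConfig(n_psi=10, duration=0.05)


@pytest.fixture(scope="session")
def base_run():
    """A trained base model at reduced scale, shared across analysis tests.

    Same architecture and task as the full protocol (f = 50 Hz, tau = 2 ms,
    N_psi = 100, N_h = 8, N_c = 12) with a shortened optimisation
    (30 epochs x 16,384 samples), which already brings the IPD error under
    10 degrees and produces the characteristic dip-shaped hidden tuning.
    """
    task = TaskConfig()
    cfg = TrainConfig(epochs=30, seed=7)
    return train(task, cfg)


@pytest.fixture(scope="session")
def base_task() -> TaskConfig:
    return TaskConfig()
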