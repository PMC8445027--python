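"""Shared fixtures: episodes are simulated once per session where possible."""

import numpy as np
import pytest

from atgraph.config import WorldConfig
from atgraph.simulator import Episode, PolicySpec, run_episode


def make_episode(positions, haptics=None, dt=0.05, reset_times=(), motors=None):
    """Wrap raw position arrays in an Episode for signal-level tests."""
    positions = np.asarray(positions, dtype=float)
    T = positions.shape[0]
    if positions.ndim == 2:  # (T, 2) single channel -> tile to 7 SIPs
        positions = np.repeat(positions[:, None, :], 7, axis=1)
    cfg = WorldConfig(dt=dt)
    return Episode(
        positions=positions,
        haptics=np.zeros((T, 7)) if haptics is None else np.asarray(haptics, dtype=float),
        motors=np.zeros((T, 6)) if motors is None else np.asarray(motors, dtype=float),
        ball_vx=np.zeros(T),
        contact_flags=np.zeros((T, 2), dtype=bool),
        contact_events=[],
        reset_times=list(reset_times),
        meta={},
        config=cfg,
    )


@pytest.fixture(scope="session")
def world():
    return WorldConfig()


@pytest.fixture(scope="session")
def push_episode():
    """Lower arm pushing a static upper arm's world: the canonical contact trial."""
    return run_episode(PolicySpec("constant_push"), PolicySpec("static"), 300, 1)


@pytest.fixture(scope="session")
def static_episode():
    return run_episode(PolicySpec("static"), PolicySpec("static"), 100, 2)


@pytest.fixture(scope="session")
def babbling_episode():
    """Moderate babbling episode for correlation-structure tests."""
    return run_episode(PolicySpec("babbling"), PolicySpec("babbling"), 4000, 3)
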