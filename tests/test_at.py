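"""Acceleration transfer: filter arithmetic, series, matrix, lag behavior."""

import numpy as np
import pytest

from atgraph.at import at_instant, at_matrix, at_series
from atgraph.signals import derive_dataset
from atgraph.synth import SignalPairSpec, gen_signal_pair

from conftest import make_episode


@pytest.mark.parametrize(
    "ai, aj, version, expected",
    [
        (0.3, 0.3, 4, 0.0),  # same sign: gated
        (0.0, 0.5, 4, 0.0),  # zero source: scaled to nothing
        (-0.2, 0.6, 4, 0.2),  # raw 0.8 -> x1/3 -> clamp at 0.2
        (-0.2, 0.6, 0, 0.8),  # bare subtraction
        (-0.2, 0.6, 1, 0.2),  # clamp only
        (-0.2, 0.6, 2, pytest.approx(0.8 / 3)),  # scale only
        (-0.2, 0.6, 3, 0.8),  # gate passes, no scaling
        (0.6, -0.2, 4, -0.2),  # reversed pair reverses the transfer
    ],
)
def test_instant_worked_examples(ai, aj, version, expected):
    assert at_instant(ai, aj, version) == pytest.approx(expected)


def test_instant_validation():
    with pytest.raises(ValueError, match="version"):
        at_instant(0.1, 0.2, version=7)
    with pytest.raises(ValueError, match="epsilon"):
        at_instant(0.1, 0.2, epsilon=0.0)
    with pytest.raises(ValueError, match="finite"):
        at_instant(np.nan, 0.2)


def test_filter_invariants_on_random_pairs():
    rng = np.random.default_rng(0)
    ai = rng.uniform(-1, 1, 100_000)
    aj = rng.uniform(-1, 1, 100_000)
    v4 = at_instant(ai, aj, 4)
    assert np.all(np.abs(v4) <= np.minimum(np.abs(ai), np.abs(aj)) + 1e-15)
    same_sign = ai * aj >= 0
    assert np.all(at_instant(ai, aj, 3)[same_sign] == 0.0)
    assert np.all(at_instant(np.zeros_like(aj), aj, 2) == 0.0)
    assert np.all(at_instant(ai, np.zeros_like(ai), 2) == 0.0)
    v0 = at_instant(ai, aj, 0)
    assert np.array_equal(v0, -at_instant(aj, ai, 0))


def test_vectorized_matches_scalar_loop():
    rng = np.random.default_rng(1)
    ai = rng.normal(size=300)
    aj = rng.normal(size=300)
    for version in range(5):
        vec = at_instant(ai, aj, version)
        loop = np.array([at_instant(a, b, version) for a, b in zip(ai, aj)])
        assert np.allclose(vec, loop, atol=1e-12)


def test_series_identical_signals_transfer_nothing():
    rng = np.random.default_rng(2)
    a = rng.normal(size=200)
    assert at_series(a, a, 4).cumulative == 0.0


def test_series_v0_antisymmetry_and_length_check():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=(2, 150))
    assert at_series(a, b, 0).cumulative == pytest.approx(-at_series(b, a, 0).cumulative)
    with pytest.raises(ValueError, match="length"):
        at_series(a, b[:-1])


def test_opposite_sign_bumps_transfer_from_decelerating_to_accelerating():
    """A pulse lost by x and gained by y reads as a positive x -> y transfer
    concentrated where the two pulses overlap."""
    x, y = gen_signal_pair(SignalPairSpec(family=1, noise_sd=0.0))
    fwd = at_series(x, y, 4)
    assert fwd.cumulative > 1.0
    assert at_series(y, x, 4).cumulative < 0.0
    peak = int(np.argmax(fwd.per_step))
    assert abs(peak - 50) <= 3  # bump center


def test_transfer_fades_with_lag():
    cums = []
    for lag in (0, 2, 4, 8, 16, 32):
        x, y = gen_signal_pair(SignalPairSpec(family=2, lag=lag, noise_sd=0.0))
        cums.append(at_series(x, y, 4).cumulative)
    assert all(a >= b - 1e-12 for a, b in zip(cums, cums[1:]))
    assert cums[0] > cums[-1]


def test_at_matrix_zero_dataset_and_diagonal():
    eps = [make_episode(np.zeros((50, 7, 2)))]
    ds = derive_dataset(eps)
    m = at_matrix(ds)
    assert np.all(m.values == 0.0)
    assert m.labels == [f"a{i}" for i in range(7)]
    with pytest.raises(ValueError, match="non-empty"):
        at_matrix([])


def test_at_matrix_rectified_entries_dominate_signed():
    rng = np.random.default_rng(4)
    eps = [make_episode(np.cumsum(rng.normal(size=(80, 7, 2)), axis=0))]
    ds = derive_dataset(eps)
    signed = at_matrix(ds).values
    rect = at_matrix(ds, rectify=True).values
    off = ~np.eye(7, dtype=bool)
    assert np.all(rect[off] >= signed[off] - 1e-12)
    assert np.all(rect[off] >= 0.0)
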