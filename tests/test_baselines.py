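"""GC and TE baselines against constructed processes and brute-force oracles."""

import itertools

import numpy as np
import pytest

from atgraph.baselines import (
    check_stationarity,
    gc_matrix,
    granger_test,
    te_matrix,
    transfer_entropy,
)
from atgraph.signals import derive_dataset

from conftest import make_episode


def test_granger_detects_constructed_causal_link():
    rng = np.random.default_rng(0)
    x = rng.normal(size=500)
    y = np.empty(500)
    y[0] = 0.0
    y[1:] = 0.9 * x[:-1] + rng.normal(0, 0.1, 499)
    assert granger_test(x, y, lag=2).p_value < 0.05
    # and no back-channel
    assert granger_test(y, x, lag=2).p_value > 0.001


def test_granger_size_under_independence():
    hits = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 500))
        if granger_test(x, y, lag=5).p_value > 0.05:
            hits += 1
    assert hits >= 34  # ~95% expected under the null


def test_granger_matches_nested_lstsq_oracle():
    """F statistic equals a hand-built nested least-squares comparison."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=20)
    y = np.empty(20)
    y[0] = rng.normal()
    for t in range(1, 20):
        y[t] = 0.5 * y[t - 1] + 0.4 * x[t - 1] + 0.1 * rng.normal()
    lag = 2
    n = len(y) - lag

    def design(series):
        return np.column_stack([series[lag - k - 1 : lag - k - 1 + n] for k in range(lag)])

    target = y[lag:]
    xr = np.column_stack([np.ones(n), design(y)])
    xf = np.column_stack([np.ones(n), design(y), design(x)])
    rss_r = np.sum((target - xr @ np.linalg.lstsq(xr, target, rcond=None)[0]) ** 2)
    rss_f = np.sum((target - xf @ np.linalg.lstsq(xf, target, rcond=None)[0]) ** 2)
    f_oracle = ((rss_r - rss_f) / lag) / (rss_f / (n - xf.shape[1]))
    res = granger_test(x, y, lag=lag)
    assert res.f_stat == pytest.approx(f_oracle, abs=1e-8)


def test_granger_input_validation():
    with pytest.raises(ValueError, match="constant"):
        granger_test(np.ones(100), np.random.default_rng(0).normal(size=100))
    with pytest.raises(ValueError, match="equal-length"):
        granger_test(np.zeros(10), np.zeros(11))
    with pytest.raises(ValueError, match="too short"):
        granger_test(np.arange(8.0), np.arange(8.0) ** 2, lag=3)


def test_te_binary_copy_approaches_one_bit():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 10_000).astype(float)
    y = np.roll(x, 1)
    y[0] = 0.0
    assert transfer_entropy(x, y, bins=8, history=1).te_bits == pytest.approx(1.0, abs=0.05)


def test_te_independent_series_near_zero():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=(2, 10_000))
    assert transfer_entropy(x, y, bins=8, history=1).te_bits < 0.02


def test_te_matches_exhaustive_histogram_oracle():
    """12-step binary toy sequence vs. a dict-counted plug-in computation."""
    x = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 1, 0, 0], dtype=float)
    y = np.array([1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 1], dtype=float)

    triples = list(zip(y[1:], y[:-1], x[:-1]))

    def entropy(groups):
        counts = {}
        for g in groups:
            counts[g] = counts.get(g, 0) + 1
        total = sum(counts.values())
        plug_in = -sum(c / total * np.log2(c / total) for c in counts.values())
        return plug_in + (len(counts) - 1) / (2 * total * np.log(2))

    oracle = (
        entropy([(a, b) for a, b, _ in triples])
        - entropy([b for _, b, _ in triples])
        - entropy(triples)
        + entropy([(b, c) for _, b, c in triples])
    )
    res = transfer_entropy(x, y, bins=2, history=1)
    assert res.te_bits == pytest.approx(oracle, abs=1e-12)


def test_te_degenerate_series_warns_and_returns_zero():
    with pytest.warns(UserWarning, match="degenerate"):
        res = transfer_entropy(np.ones(50), np.arange(50.0))
    assert res.te_bits == 0.0
    with pytest.raises(ValueError, match="history"):
        transfer_entropy(np.arange(10.0), np.arange(10.0), history=0)


def test_stationarity_check():
    rng = np.random.default_rng(3)
    assert check_stationarity(rng.normal(size=500))["stationary"]
    walks = sum(
        not check_stationarity(np.cumsum(np.random.default_rng(s).normal(size=500)))["stationary"]
        for s in range(10)
    )
    assert walks >= 8
    with pytest.raises(ValueError, match="constant"):
        check_stationarity(np.ones(100))


def test_simulator_signals_are_stationary(babbling_episode):
    from atgraph.signals import derive_signals

    sig = derive_signals(babbling_episode)
    ch = sig.accel_channels()
    for i in (0, 3, 6):
        assert check_stationarity(ch[:2000, i])["stationary"]


def test_measure_matrices_shapes_and_asymmetry():
    rng = np.random.default_rng(4)
    eps = [make_episode(np.cumsum(rng.normal(size=(120, 7, 2)), axis=0)) for _ in range(2)]
    ds = derive_dataset(eps)
    gc = gc_matrix(ds, lag=2)
    te = te_matrix(ds, bins=4)
    assert gc["values"].shape == (7, 7) and te["values"].shape == (7, 7)
    assert np.all((gc["values"] >= 0) & (gc["values"] <= 1))
    assert np.all(np.diag(gc["values"]) == 0) and np.all(np.diag(te["values"]) == 0)
    # never symmetrized
    assert not np.allclose(te["values"], te["values"].T)
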