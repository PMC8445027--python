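"""Granger-causality and transfer-entropy baselines, plus a stationarity check.

Granger causality: x Granger-causes y when x's past adds explanatory power
to y beyond y's own past.  Tested by comparing nested autoregressions
(restricted: y on its own `lag` lags; full: plus x's lags) with an F-test on
the added coefficients.

Transfer entropy: the reduction in uncertainty of y's next value given x's
past beyond y's own past, in bits.  Estimated with the plug-in (histogram)
estimator over an equal-width discretization with a Miller-Madow bias
correction, so independent series score near zero (and may dip slightly
below it).

The stationarity check is the augmented Dickey-Fuller unit-root test,
delegated to statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tsa.stattools import adfuller

from .signals import DerivedSignals


@dataclass
class GCResult:
    p_value: float
    f_stat: float
    lag: int
    direction: tuple


@dataclass
class TEResult:
    te_bits: float
    bins: int
    history: int
    direction: tuple | None = None


def _lag_design(x: np.ndarray, lag: int) -> np.ndarray:
    """Columns x_{t-1} .. x_{t-lag} aligned with targets x_{lag:}."""
    n = len(x) - lag
    return np.column_stack([x[lag - k - 1 : lag - k - 1 + n] for k in range(lag)])


def granger_test(x: np.ndarray, y: np.ndarray, lag: int = 5) -> GCResult:
    """Test whether x Granger-causes y via nested autoregressions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n = len(y) - lag
    if n < 2 * lag + 2:
        raise ValueError("series too short for the requested lag")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant series: singular design")

    target = y[lag:]
    y_lags = _lag_design(y, lag)
    x_lags = _lag_design(x, lag)
    restricted = sm.OLS(target, sm.add_constant(y_lags)).fit()
    full = sm.OLS(target, sm.add_constant(np.column_stack([y_lags, x_lags]))).fit()
    f_stat, p_value, _ = full.compare_f_test(restricted)
    return GCResult(p_value=float(p_value), f_stat=float(f_stat), lag=lag, direction=("x", "y"))


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros(len(x), dtype=np.int64)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, bins - 1)


def _entropy_from_codes(codes: np.ndarray, bias_correction: bool) -> float:
    """Plug-in entropy in bits, optionally Miller-Madow corrected.

    The correction adds (K - 1) / (2 N ln 2) bits (K = occupied cells); in
    the TE combination the four terms cancel the finite-sample bias that
    would otherwise make independent series score ~df/(2 N ln 2) bits.
    """
    _, counts = np.unique(codes, return_counts=True)
    n = counts.sum()
    p = counts / n
    h = float(-(p * np.log2(p)).sum())
    if bias_correction:
        h += (len(counts) - 1) / (2.0 * n * math.log(2.0))
    return h


def transfer_entropy(
    x: np.ndarray,
    y: np.ndarray,
    bins: int = 8,
    history: int = 1,
    bias_correction: bool = True,
) -> TEResult:
    """Histogram transfer entropy x -> y in bits.

    TE = H(y_t | y_past) - H(y_t | y_past, x_past) with `history` past steps
    of each series, each discretized into `bins` equal-width bins.  With the
    default Miller-Madow correction, independent series score ~0 (possibly
    slightly negative); `bias_correction=False` gives the raw plug-in value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if history < 1:
        raise ValueError("history must be >= 1")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("degenerate (constant) series: transfer entropy is 0", stacklevel=2)
        return TEResult(te_bits=0.0, bins=bins, history=history)

    xc = _discretize(x, bins)
    yc = _discretize(y, bins)
    k = history
    n = len(y) - k
    y_t = yc[k:]
    # encode past windows as single integers (base `bins`)
    y_past = np.zeros(n, dtype=np.int64)
    x_past = np.zeros(n, dtype=np.int64)
    for i in range(k):
        y_past = y_past * bins + yc[k - 1 - i : k - 1 - i + n]
        x_past = x_past * bins + xc[k - 1 - i : k - 1 - i + n]

    b = np.int64(bins**k)
    jo_ypast = y_past
    jo_y_ypast = y_t * (b) + y_past  # y_t in [0, bins)
    jo_ypast_xpast = y_past * b + x_past
    jo_all = (y_t * b + y_past) * b + x_past
    te = (
        _entropy_from_codes(jo_y_ypast, bias_correction)
        - _entropy_from_codes(jo_ypast, bias_correction)
        - _entropy_from_codes(jo_all, bias_correction)
        + _entropy_from_codes(jo_ypast_xpast, bias_correction)
    )
    return TEResult(te_bits=float(te), bins=bins, history=history)


def check_stationarity(x: np.ndarray, alpha: float = 0.05) -> dict:
    """Augmented Dickey-Fuller unit-root test; stationary iff p < alpha."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("constant series")
    stat, p_value, *_ = adfuller(x)
    return {"stationary": bool(p_value < alpha), "statistic": float(stat), "p_value": float(p_value)}


# ---------------------------------------------------------------------------
# dataset-level matrices
# ---------------------------------------------------------------------------


def gc_matrix(
    dataset: list[DerivedSignals],
    lag: int = 5,
    component: str = "dspeed",
    alpha: float = 0.05,
) -> dict:
    """7x7 matrix: fraction of episodes where i Granger-causes j at p < alpha.

    Episodes where the test is undefined (constant channel) count as not
    passed.  The matrix is asymmetric and is never symmetrized.
    """
    n = 7
    passed = np.zeros((n, n))
    for sig in dataset:
        chans = sig.accel_channels(component)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                try:
                    res = granger_test(chans[:, i], chans[:, j], lag)
                    if res.p_value < alpha:
                        passed[i, j] += 1.0
                except ValueError:
                    pass
    values = passed / len(dataset)
    comp = component if component in ("x", "y") else ""
    return {"labels": [f"a{i}{comp}" for i in range(n)], "values": values, "measure": "gc"}


def te_matrix(
    dataset: list[DerivedSignals],
    bins: int = 8,
    history: int = 1,
    component: str = "dspeed",
) -> dict:
    """7x7 matrix of mean transfer entropy (bits) i -> j across episodes."""
    n = 7
    acc = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sig in dataset:
            chans = sig.accel_channels(component)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    acc[i, j] += transfer_entropy(chans[:, i], chans[:, j], bins, history).te_bits
    values = acc / len(dataset)
    comp = component if component in ("x", "y") else ""
    return {"labels": [f"a{i}{comp}" for i in range(n)], "values": values, "measure": "te"}
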