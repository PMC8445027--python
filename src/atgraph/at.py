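"""The acceleration-transfer (AT) measure.

AT estimates the instantaneous transfer of acceleration from one feature
point to another: if one point loses acceleration while another gains it at
the same instant, the difference is read as a transfer (acceleration being a
proxy for force through F = m*a).  The raw per-step value is the bare
subtraction T(a_i, a_j) = a_j - a_i (positive = transfer i -> j), refined by
three successive filters:

* version 1 clamps |T| to min(|a_i|, |a_j|): a transfer cannot exceed the
  smaller of the two signals;
* version 2 scales T by min{1, |a_i|/|a_j|}, nulling transfers whenever the
  source signal is (close to) zero; the factor is defined as 0 when a_j = 0;
* version 3 gates T to zero unless the signals have opposite signs, enforced
  by |a_i| + |a_j| >= |a_i + a_j| + epsilon (default epsilon = 0.01) — only
  moments where one signal loses what the other gains count as an exchange.

Version 4 (the measure proper) composes all three: gate (v3), then scale
(v2), then clamp (v1).  The cumulative AT over a series is the sum of
per-step values; summed over episode datasets it fills the pairwise AT
matrix whose thresholded directed graph exposes passive entities as sinks.

Version 0 is antisymmetric by construction; the filtered versions are not
(and the code never assumes they are).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import DerivedSignals

DEFAULT_EPSILON = 0.01


@dataclass
class ATResult:
    per_step: np.ndarray
    cumulative: float
    version: int
    epsilon: float


@dataclass
class ATMatrix:
    labels: list
    values: np.ndarray  # (7, 7), entry (i, j) = cumulative AT i -> j
    version: int
    epsilon: float
    component: str


def at_instant(ai, aj, version: int = 4, epsilon: float = DEFAULT_EPSILON):
    """Instantaneous AT between two acceleration samples (vectorized).

    Accepts scalars or equal-shaped arrays; returns the same shape.
    Positive values denote transfer i -> j.
    """
    if version not in (0, 1, 2, 3, 4):
        raise ValueError("version must be in 0..4")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    ai = np.asarray(ai, dtype=float)
    aj = np.asarray(aj, dtype=float)
    if not (np.all(np.isfinite(ai)) and np.all(np.isfinite(aj))):
        raise ValueError("non-finite acceleration input")
    raw = aj - ai
    if version == 0:
        return raw if raw.ndim else float(raw)

    abs_i = np.abs(ai)
    abs_j = np.abs(aj)
    t = raw
    if version in (3, 4):
        gate = (abs_i + abs_j) >= (np.abs(ai + aj) + epsilon)
        t = np.where(gate, t, 0.0)
    if version in (2, 4):
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(abs_j > 0.0, np.minimum(1.0, abs_i / np.where(abs_j > 0, abs_j, 1.0)), 0.0)
        t = t * factor
    if version in (1, 4):
        bound = np.minimum(abs_i, abs_j)
        t = np.clip(t, -bound, bound)
    return t if t.ndim else float(t)


def at_series(a_i: np.ndarray, a_j: np.ndarray, version: int = 4, epsilon: float = DEFAULT_EPSILON) -> ATResult:
    """Per-step AT values and their cumulative sum for two aligned series."""
    a_i = np.asarray(a_i, dtype=float)
    a_j = np.asarray(a_j, dtype=float)
    if a_i.shape != a_j.shape:
        raise ValueError("length mismatch")
    per_step = at_instant(a_i, a_j, version, epsilon)
    return ATResult(
        per_step=per_step,
        cumulative=float(per_step.sum()),
        version=version,
        epsilon=epsilon,
    )


def at_matrix(
    dataset: list[DerivedSignals],
    component: str = "dspeed",
    version: int = 4,
    epsilon: float = DEFAULT_EPSILON,
    rectify: bool = False,
) -> ATMatrix:
    """Pairwise AT matrix over the 7 SIP acceleration channels.

    Entry (i, j) sums the cumulative AT from channel i to channel j over all
    episodes of the dataset (signed by default; `rectify=True` sums only the
    positive per-step parts).  The diagonal is exactly zero.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    n = 7
    values = np.zeros((n, n))
    for sig in dataset:
        chans = sig.accel_channels(component)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                per = at_instant(chans[:, i], chans[:, j], version, epsilon)
                if rectify:
                    per = np.maximum(per, 0.0)
                values[i, j] += float(per.sum())
    np.fill_diagonal(values, 0.0)
    comp = component if component in ("x", "y") else ""
    labels = [f"a{i}{comp}" for i in range(n)]
    return ATMatrix(labels=labels, values=values, version=version, epsilon=epsilon, component=component)
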