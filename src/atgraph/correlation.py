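"""Pearson-correlation analysis of SIP velocities and motor commands.

Under the Gestalt principle of common fate ("what moves together clusters
together"), the velocity correlation structure of the tracked feature points
separates the two arms (self vs. other) and exposes the proximo-distal
organization of each kinematic chain; motor-to-velocity correlations mark
the channels an agent controls.  Correlation is undefined whenever one
variance is zero (e.g. an untouched, static ball) — such entries carry an
explicit NaN sentinel and a `defined=False` flag, never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import ContactMask, DerivedSignals
from .simulator import Episode, MOTOR_NAMES

#: sentinel for undefined correlations (zero variance)
UNDEFINED = float("nan")

_VAR_TOL = 1e-24


@dataclass
class CorrelationMatrix:
    labels_rows: list
    labels_cols: list
    rho: np.ndarray
    defined: np.ndarray  # bool, False where a variance was 0
    n_samples: int
    condition: str | None = None

    @property
    def labels(self) -> list:
        return self.labels_cols


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's rho; NaN sentinel when either variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx < _VAR_TOL or vy < _VAR_TOL:
        return UNDEFINED
    return float((xc @ yc) / np.sqrt(vx * vy))


def _cross_matrix(rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nr, nc = rows.shape[1], cols.shape[1]
    rho = np.empty((nr, nc))
    defined = np.ones((nr, nc), dtype=bool)
    for i in range(nr):
        for j in range(nc):
            r = pearson(rows[:, i], cols[:, j])
            rho[i, j] = r
            defined[i, j] = not np.isnan(r)
    return rho, defined


def velocity_correlation_matrix(
    signals: DerivedSignals,
    component: str = "x",
    mask: ContactMask | None = None,
) -> CorrelationMatrix:
    """7x7 correlation matrix of SIP velocities restricted to a step mask."""
    chans = signals.vel_channels(component)
    if mask is not None:
        chans = chans[mask.mask]
    if chans.shape[0] < 3:
        raise ValueError("insufficient conditioned samples")
    labels = [f"v{i}{component if component != 'mag' else ''}" for i in range(7)]
    rho, defined = _cross_matrix(chans, chans)
    return CorrelationMatrix(
        labels_rows=labels,
        labels_cols=labels,
        rho=rho,
        defined=defined,
        n_samples=chans.shape[0],
        condition=mask.condition if mask is not None else None,
    )


def motor_sensory_matrix(
    episode: Episode,
    signals: DerivedSignals,
    component: str = "x",
    mask: ContactMask | None = None,
) -> CorrelationMatrix:
    """6 motors x 7 SIP velocity channels correlation matrix.

    Rows are the applied joint angle changes per step, columns the SIP
    velocity component, both restricted to the mask when given.
    """
    motors = episode.motors
    chans = signals.vel_channels(component)
    if mask is not None:
        motors = motors[mask.mask]
        chans = chans[mask.mask]
    if chans.shape[0] < 3:
        raise ValueError("insufficient conditioned samples")
    rho, defined = _cross_matrix(motors, chans)
    return CorrelationMatrix(
        labels_rows=list(MOTOR_NAMES),
        labels_cols=[f"v{i}{component if component != 'mag' else ''}" for i in range(7)],
        rho=rho,
        defined=defined,
        n_samples=chans.shape[0],
        condition=mask.condition if mask is not None else None,
    )
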