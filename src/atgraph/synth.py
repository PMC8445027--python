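"""Synthetic signal pairs for validating the dependency measures.

Six families of acceleration-like test signals, each with a small Gaussian
observation noise:

1. two Gaussian bumps of opposite signs (a crude contact: one entity loses
   acceleration, the other gains it),
2. the same with a lag on the receiving signal (compliance / delay),
3. two Gaussian bumps of the same sign (two entities hit by a third — no
   exchange between them),
4. same sign with a lag,
5. random smoothed signals (shared smoothed base, same sign),
6. random smoothed signals of opposite signs (the documented false-positive
   mode of the AT measure).

A well-behaved directional measure should fire on families 1, 2 and 6 only,
with the family-2 effect fading as the lag grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SignalPairSpec:
    family: int
    length: int = 100
    amplitude: float = 1.0
    center: float = 50.0
    width: float = 5.0
    lag: int = 0
    noise_sd: float = 0.02
    smooth_window: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in range(1, 7):
            raise ValueError("family must be in 1..6")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.lag >= self.length:
            raise ValueError("lag must be smaller than length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _bump(t: np.ndarray, c: float, w: float) -> np.ndarray:
    return np.exp(-((t - c) ** 2) / (2.0 * w**2))


def _smoothed_noise(rng: np.random.Generator, n: int, window: int) -> np.ndarray:
    base = rng.normal(0.0, 1.0, n + window)
    kernel = np.ones(window) / window
    return np.convolve(base, kernel, mode="valid")[:n]


def gen_signal_pair(spec: SignalPairSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (x, y) pair; deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.length, dtype=float)
    A, c, w = spec.amplitude, spec.center, spec.width
    if spec.family in (1, 2):
        lag = spec.lag if spec.family == 2 else 0
        x = -A * _bump(t, c, w)
        y = A * _bump(t, c + lag, w)
    elif spec.family in (3, 4):
        lag = spec.lag if spec.family == 4 else 0
        x = A * _bump(t, c, w)
        y = A * _bump(t, c + lag, w)
    else:
        base = A * _smoothed_noise(rng, spec.length, spec.smooth_window)
        x = base.copy()
        y = base.copy() if spec.family == 5 else -base
    x = x + rng.normal(0.0, spec.noise_sd, spec.length)
    y = y + rng.normal(0.0, spec.noise_sd, spec.length)
    return x, y
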