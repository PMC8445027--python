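"""Derived time series: SIP velocities, accelerations and haptic deltas.

Velocities are backward differences of SIP positions divided by dt, and
accelerations backward differences of velocities, both with first-sample
padding (the first row repeats the second) so every derived series keeps the
length of the position stream and all channels stay step-aligned.  An
optional centered moving average can smooth positions before differencing.
Magnitudes are normalized by the dataset-wide maximum so that all velocity
and acceleration magnitudes lie in [0, 1]; vector components are scaled by
the same constant, preserving signs and orderings.

Derivatives are invalidated across episode resets (the teleport of ball and
arms back to the start pose is not motion), by holding the velocity across
the reset step and zeroing the acceleration there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import Episode

CONDITIONS = ("none", "lower", "upper", "either")


@dataclass
class DerivedSignals:
    """Per-episode derived channels, all length T (step-aligned)."""

    v: np.ndarray  # (T, 7, 2) normalized velocity vectors
    a: np.ndarray  # (T, 7, 2) normalized acceleration vectors
    dv: np.ndarray  # (T, 7) normalized speed derivative d|v|/dt (tangential)
    dh: np.ndarray  # (T, 7) haptic deltas
    vmag: np.ndarray  # (T, 7)
    amag: np.ndarray  # (T, 7)
    norm_info: dict

    def accel_channels(self, component: str = "dspeed") -> np.ndarray:
        """(T, 7) acceleration channel matrix.

        "dspeed" (default) is the signed speed derivative d|v|/dt: negative
        when an entity slows down, positive when it speeds up, independent
        of the direction of travel — the natural signal for "one point
        loses acceleration while the other gains it".  "x"/"y"/"mag" select
        acceleration-vector components or magnitude.
        """
        if component == "dspeed":
            return self.dv
        return _component(self.a, self.amag, component)

    def vel_channels(self, component: str = "x") -> np.ndarray:
        return _component(self.v, self.vmag, component)


@dataclass
class ContactMask:
    condition: str
    mask: np.ndarray  # (T,) bool


def _component(vec: np.ndarray, mag: np.ndarray, component: str) -> np.ndarray:
    if component == "x":
        return vec[:, :, 0]
    if component == "y":
        return vec[:, :, 1]
    if component == "mag":
        return mag
    raise ValueError("component must be 'x', 'y' or 'mag'")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    if window % 2 == 0:
        raise ValueError("smoothing_window must be odd")
    kernel = np.ones(window) / window
    pad = window // 2
    out = np.empty_like(x)
    flat = x.reshape(x.shape[0], -1)
    oflat = out.reshape(x.shape[0], -1)
    for j in range(flat.shape[1]):
        padded = np.concatenate(
            [np.full(pad, flat[0, j]), flat[:, j], np.full(pad, flat[-1, j])]
        )
        oflat[:, j] = np.convolve(padded, kernel, mode="valid")
    return out


def _backward_diff(x: np.ndarray, dt: float, reset_times) -> np.ndarray:
    d = np.empty_like(x)
    d[1:] = (x[1:] - x[:-1]) / dt
    d[0] = d[1]
    for r in reset_times:
        # the jump into the reset step is a teleport, not motion
        d[r] = d[r + 1] if r + 1 < len(x) else 0.0
    return d


def derive_signals(
    episode: Episode,
    smoothing_window: int = 1,
    norm: dict | None = None,
) -> DerivedSignals:
    """Turn one episode into normalized velocity/acceleration/haptic-delta series.

    When `norm` (a dict with keys v_scale, a_scale) is given it is used as
    the normalization constant instead of this episode's own maxima; use
    :func:`derive_dataset` for a shared, dataset-wide normalization.
    """
    T = episode.n_steps
    if T < 3:
        raise ValueError("too short: need at least 3 steps")
    dt = episode.config.dt
    pos = _smooth(episode.positions, smoothing_window)
    resets = list(episode.reset_times)

    v = _backward_diff(pos, dt, resets)
    a = _backward_diff(v, dt, resets)
    for r in resets:
        a[r] = 0.0
        if r + 1 < T:
            a[r + 1] = 0.0
    a[0] = a[1]

    dh = np.empty_like(episode.haptics)
    dh[1:] = episode.haptics[1:] - episode.haptics[:-1]
    dh[0] = dh[1]
    for r in resets:
        dh[r] = 0.0

    vmag = np.hypot(v[:, :, 0], v[:, :, 1])
    amag = np.hypot(a[:, :, 0], a[:, :, 1])
    dv = np.empty_like(vmag)
    dv[1:] = (vmag[1:] - vmag[:-1]) / dt
    dv[0] = dv[1]
    for r in resets:
        dv[r] = 0.0
        if r + 1 < T:
            dv[r + 1] = 0.0
    if norm is None:
        v_scale = float(vmag.max()) or 1.0
        a_scale = float(amag.max()) or 1.0
        ds_scale = float(np.abs(dv).max()) or 1.0
    else:
        v_scale = float(norm["v_scale"]) or 1.0
        a_scale = float(norm["a_scale"]) or 1.0
        ds_scale = float(norm.get("ds_scale", 1.0)) or 1.0
    return DerivedSignals(
        v=v / v_scale,
        a=a / a_scale,
        dv=dv / ds_scale,
        dh=dh,
        vmag=vmag / v_scale,
        amag=amag / a_scale,
        norm_info={"v_scale": v_scale, "a_scale": a_scale, "ds_scale": ds_scale},
    )


def derive_dataset(episodes: list, smoothing_window: int = 1) -> list:
    """Derive signals for a list of episodes under one shared normalization.

    The normalization constant is the maximum velocity/acceleration magnitude
    over the whole dataset, keeping cross-episode comparability for the
    pairwise measure matrices.
    """
    raw = [
        derive_signals(ep, smoothing_window, norm={"v_scale": 1.0, "a_scale": 1.0, "ds_scale": 1.0})
        for ep in episodes
    ]
    v_scale = max((float(d.vmag.max()) for d in raw), default=1.0) or 1.0
    a_scale = max((float(d.amag.max()) for d in raw), default=1.0) or 1.0
    ds_scale = max((float(np.abs(d.dv).max()) for d in raw), default=1.0) or 1.0
    out = []
    for d in raw:
        out.append(
            DerivedSignals(
                v=d.v / v_scale,
                a=d.a / a_scale,
                dv=d.dv / ds_scale,
                dh=d.dh,
                vmag=d.vmag / v_scale,
                amag=d.amag / a_scale,
                norm_info={"v_scale": v_scale, "a_scale": a_scale, "ds_scale": ds_scale},
            )
        )
    return out


def contact_mask(episode: Episode, condition: str, h_threshold: float = 0.1) -> ContactMask:
    """Boolean step mask for a haptic contact condition.

    "lower"/"upper": that arm and the ball register haptics simultaneously;
    "none": no haptic anywhere; "either": lower OR upper.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    h = episode.haptics
    ball = h[:, 6] >= h_threshold
    lower = (h[:, 0:3].max(axis=1) >= h_threshold) & ball
    upper = (h[:, 3:6].max(axis=1) >= h_threshold) & ball
    if condition == "lower":
        mask = lower
    elif condition == "upper":
        mask = upper
    elif condition == "either":
        mask = lower | upper
    else:
        mask = np.all(h < h_threshold, axis=1)
    return ContactMask(condition=condition, mask=mask)
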