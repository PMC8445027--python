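"""Dual-arm / sliding-ball simulator.

Two velocity-controlled 3-DOF planar arms face each other across a
horizontal rail on which a ball slides between two end boxes.  Motion of the
arms is kinematic (a command is a per-step joint angle change, clipped to the
joint speed limit); the ball is passive and moves only when an arm segment
touches it.  Contact transfers the x component of the contact-point velocity
to the ball as an impulse, and the contacting arm recoils (its applied joint
speed is scaled down while touching), so that the pusher visibly loses speed
while the ball gains it.  The ball then decays under rail friction and is
reset to the middle (arms re-posed) whenever it slides past a box edge.

Seven sensory interest points (SIPs) are tracked: s0..s2 on the lower arm
(s0 = end effector), s3..s5 on the upper arm (s3 = end effector), s6 = ball
center.  Each SIP carries a simulated haptic value in [0, 1] computed from
its distance to the nearest contact point.  Motors are indexed m0..m5 with
m2/m5 the base joints (the joint that moves the whole arm) and m0/m3 the
distal joints.

Reported SIP positions include a small Gaussian observation noise emulating
visual feature-extraction jitter; haptics and dynamics use true geometry.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .config import WorldConfig

#: channel names of the seven sensory interest points
SIP_NAMES = ("s0", "s1", "s2", "s3", "s4", "s5", "s6")
MOTOR_NAMES = ("m0", "m1", "m2", "m3", "m4", "m5")

POLICY_KINDS = (
    "constant_push",
    "staggered_push",
    "random_push",
    "random",
    "static",
    "babbling",
    "goal_directed",
)

_TWO_PI = 2.0 * math.pi


@dataclass
class WorldState:
    """Instantaneous simulator state."""

    joint_angles: np.ndarray  # (6,) motor order m0..m5 (unwrapped radians)
    ball_x: float
    ball_vx: float
    t: int = 0
    #: per-arm speed fraction currently absorbed by contact recoil
    recoil_level: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.recoil_level is None:
            self.recoil_level = np.zeros(2)


@dataclass
class PolicySpec:
    """Specification of an arm controller.

    kind-specific params (all optional):
      activation   - push magnitude for constant_push (default 1.0)
      block        - hold length in steps for the switching policies (default 10)
      hold_range   - (lo, hi) inclusive hold-duration range for babbling (10, 40)
      gain         - proportional gain of goal_directed servoing (default 3.0)
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}; expected one of {POLICY_KINDS}")


@dataclass
class Episode:
    """One simulated run: SIP streams, motor stream and event logs.

    positions[t, i] is the observed 2D position of SIP i at step t,
    haptics[t, i] its haptic value, motors[t] the joint angle changes applied
    on the transition into step t (row 0 is zero).
    """

    positions: np.ndarray  # (T, 7, 2) observed SIP positions
    haptics: np.ndarray  # (T, 7) in [0, 1]
    motors: np.ndarray  # (T, 6) applied delta-m
    ball_vx: np.ndarray  # (T,) true ball velocity
    contact_flags: np.ndarray  # (T, 2) bool, arm (0=lower, 1=upper) touched ball
    contact_events: list  # (t, (sip_i, 6)) nearest arm SIP per contact
    reset_times: list
    meta: dict
    config: WorldConfig

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# kinematics and contact geometry
# ---------------------------------------------------------------------------


def _arm_chain(angles6: np.ndarray, arm: int, config: WorldConfig):
    """Joint origins (base, elbow, wrist) and tip of one arm.

    Returns (origins, tip): origins is a list of the three joint pivot
    positions in proximal order; tip is the end-effector position.
    """
    l1, l2, l3 = config.link_lengths
    if arm == 0:
        base = np.asarray(config.arm_base_positions[0], dtype=float)
        th = (angles6[2], angles6[1], angles6[0])  # proximal order
    else:
        base = np.asarray(config.arm_base_positions[1], dtype=float)
        th = (angles6[5], angles6[4], angles6[3])
    phi1 = th[0]
    phi2 = phi1 + th[1]
    phi3 = phi2 + th[2]
    p1 = base + l1 * np.array([math.cos(phi1), math.sin(phi1)])
    p2 = p1 + l2 * np.array([math.cos(phi2), math.sin(phi2)])
    tip = p2 + l3 * np.array([math.cos(phi3), math.sin(phi3)])
    return [base, p1, p2], tip


def sip_positions(state: WorldState, config: WorldConfig) -> np.ndarray:
    """True positions of the 7 SIPs for a state, shape (7, 2)."""
    out = np.empty((7, 2))
    for arm in range(2):
        origins, tip = _arm_chain(state.joint_angles, arm, config)
        base = 3 * arm
        out[base + 0] = tip
        out[base + 1] = origins[2]
        out[base + 2] = origins[1]
    out[6] = (state.ball_x, config.rail_y)
    return out


def _closest_on_segment(a: np.ndarray, b: np.ndarray, p: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-18:
        return a
    s = float((p - a) @ ab) / denom
    s = min(1.0, max(0.0, s))
    return a + s * ab


def _detect_contacts(angles6: np.ndarray, ball_x: float, config: WorldConfig):
    """Capsule(arm segment)-circle(ball) contacts.

    Returns a list of dicts with keys arm, seg (0 proximal..2 distal),
    point (closest point on the segment axis), dist, origins (joint pivots).
    """
    center = np.array([ball_x, config.rail_y])
    r_sum = config.ball_radius + config.arm_radius
    contacts = []
    for arm in range(2):
        origins, tip = _arm_chain(angles6, arm, config)
        pts = [origins[0], origins[1], origins[2], tip]
        for seg in range(3):
            q = _closest_on_segment(pts[seg], pts[seg + 1], center)
            d = float(np.hypot(*(center - q)))
            if d <= r_sum:
                contacts.append(
                    {"arm": arm, "seg": seg, "point": q, "dist": d, "origins": origins}
                )
    return contacts


def _point_velocity(contact: dict, dtheta_proximal: np.ndarray, dt: float) -> np.ndarray:
    """Velocity of a point riding on link `seg` from joint rates (units/s)."""
    q = contact["point"]
    v = np.zeros(2)
    for j in range(contact["seg"] + 1):
        w = dtheta_proximal[j] / dt
        r = q - contact["origins"][j]
        v += w * np.array([-r[1], r[0]])
    return v


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------


def init_state(config: WorldConfig) -> WorldState:
    angles = np.asarray(config.init_joint_angles, dtype=float)
    mid = 0.5 * (config.rail_extent[0] + config.rail_extent[1])
    return WorldState(joint_angles=angles, ball_x=mid, ball_vx=0.0, t=0)


def _profile6(config: WorldConfig) -> np.ndarray:
    """Per-joint factors in motor order m0..m5 (distal, middle, base) x2."""
    return np.asarray(config.joint_profile * 2, dtype=float)


def _clamp_travel(angles: np.ndarray, config: WorldConfig) -> np.ndarray:
    """Clamp joints to their mechanical travel around the initial pose."""
    init = np.asarray(config.init_joint_angles)
    travel = config.joint_travel * _profile6(config)
    return np.clip(angles, init - travel, init + travel)


def _proximal(cmd6: np.ndarray, arm: int) -> np.ndarray:
    if arm == 0:
        return np.array([cmd6[2], cmd6[1], cmd6[0]])
    return np.array([cmd6[5], cmd6[4], cmd6[3]])


def step(state: WorldState, command: np.ndarray, config: WorldConfig):
    """Advance the world by one step.

    `command` holds 6 joint angle changes (rad/step, motor order m0..m5); it
    is clipped to the joint speed limit.  Returns (new_state, info) where
    info records the contacts resolved during the transition and the joint
    changes actually applied (after clipping and contact recoil).
    """
    command = np.asarray(command, dtype=float)
    if command.shape != (6,) or not np.all(np.isfinite(command)):
        raise ValueError("command must be 6 finite joint velocity values")
    lim = config.joint_speed_limit * _profile6(config)
    cmd = np.clip(command, -lim, lim)

    # recoil levels recover gradually between contacts, so a struck arm
    # regains speed over several steps instead of one sharp re-acceleration
    level = state.recoil_level * (1.0 - config.recoil_recovery)
    applied = cmd * np.repeat(1.0 - level, 3)
    angles = _clamp_travel(state.joint_angles + applied, config)
    applied = angles - state.joint_angles
    contacts = _detect_contacts(angles, state.ball_x, config)
    touched = {c["arm"] for c in contacts}

    vx = state.ball_vx
    bx = state.ball_x
    r_sum = config.ball_radius + config.arm_radius
    kicked = set()
    for c in contacts:
        center = np.array([bx, config.rail_y])
        n = center - c["point"]
        d = float(np.hypot(*n))
        if d < 1e-12:
            n = np.array([math.copysign(1.0, bx - c["point"][0]), 0.0])
            d = 0.0
        else:
            n = n / d
        u = _point_velocity(c, _proximal(applied, c["arm"]), config.dt)
        # 1D elastic bounce of a light ball off the (comparatively heavy)
        # arm, along the rail: fires when the contact normal has a real x
        # component and the contact point is catching up with the ball in
        # the push direction.  A purely vertical graze imparts nothing; a
        # resting ball struck by a static arm stays at rest (u = 0, vx = 0).
        if abs(n[0]) > 0.2 and (u[0] - vx) * math.copysign(1.0, n[0]) > 0.0:
            e = config.restitution
            dv = (1.0 + e) * u[0] - e * vx - vx
            vx += dv
            if abs(dv) > 0.05:
                kicked.add(c["arm"])
        else:
            # grazing contact: tangential drag couples the ball toward the
            # rubbing point's velocity (a touch always transfers a little)
            dv = config.contact_drag * (u[0] - vx)
            vx += dv
            if abs(dv) > 0.05:
                kicked.add(c["arm"])
        pen = r_sum - d
        if pen > 0.0 and abs(n[0]) > 1e-9:
            # relax penetration gradually; a hard snap would read as a
            # spurious reversal in the differentiated ball position
            bx += 0.3 * pen * math.copysign(1.0, n[0])

    if kicked and config.contact_recoil > 0.0:
        # Newton's third law, crudely: an arm that just transferred momentum
        # loses speed on the same instant (the contact set and the ball
        # impulse keep the pre-recoil geometry and velocity)
        for arm in kicked:
            level[arm] = config.contact_recoil
        angles = _clamp_travel(state.joint_angles + cmd * np.repeat(1.0 - level, 3), config)
        applied = angles - state.joint_angles

    vx *= 1.0 - config.friction
    bx += vx * config.dt

    new_state = WorldState(
        joint_angles=angles, ball_x=bx, ball_vx=vx, t=state.t + 1, recoil_level=level
    )
    info = {"contacts": contacts, "applied": applied, "touched": touched}
    return new_state, info


def compute_haptics(sips: np.ndarray, contacts: list, config: WorldConfig) -> np.ndarray:
    """Haptic value per SIP: 1 - d/haptic_radius to the nearest contact point.

    Touch is felt only by the bodies involved in a contact: an arm's SIPs
    respond to that arm's own contacts, the ball SIP to any contact.  Zero
    everywhere when no contact exists this step.
    """
    h = np.zeros(len(sips))
    if not contacts:
        return h
    for c in contacts:
        q = c["point"]
        arm = c["arm"]
        for i in list(range(3 * arm, 3 * arm + 3)) + [6]:
            d = float(np.hypot(sips[i, 0] - q[0], sips[i, 1] - q[1]))
            h[i] = max(h[i], 1.0 - d / config.haptic_radius)
    return np.clip(h, 0.0, 1.0)


# ---------------------------------------------------------------------------
# policies
# ---------------------------------------------------------------------------


def _push_direction(
    state: WorldState, arm: int, config: WorldConfig, through: float = 0.0
) -> np.ndarray:
    """Joint-space direction (returned in motor-local order, i.e.
    [m0-like, m1-like, m2-like]) that moves the end effector toward the ball.

    Computed as J^T e: the gradient of tip-to-ball distance in joint space.
    With `through` > 0 the target lies that far beyond the ball (along the
    push direction), so a pushing arm keeps driving at full activation
    instead of easing off when the tip reaches the ball line.
    """
    origins, tip = _arm_chain(state.joint_angles, arm, config)
    ball = np.array([state.ball_x, config.rail_y])
    target = ball
    if through > 0.0:
        # aim `through` units past the ball along the tip-to-ball line: a
        # collision course that keeps pushing once the tip reaches the ball
        d = ball - tip
        norm = float(np.hypot(*d))
        if norm > 1e-9:
            target = ball + (through / norm) * d
    e = target - tip
    g_prox = np.empty(3)
    for j in range(3):
        r = tip - origins[j]
        g_prox[j] = float(np.array([-r[1], r[0]]) @ e)  # d tip / d theta_j . e
    # proximal order (base, elbow, distal) -> motor-local order (distal..base)
    return g_prox[::-1]


def _push_activation(v: np.ndarray, gain: float = 3.0) -> np.ndarray:
    """Saturated proportional activation along a joint-space direction.

    Far from alignment the activation saturates at +-1 ("constant motor
    activation"); near alignment it shrinks proportionally, avoiding the
    bang-bang chattering a hard sign rule would produce (jerky motion floods
    the acceleration channels with artifacts).
    """
    return np.clip(gain * v, -1.0, 1.0)


class _Policy:
    """Stateful per-arm controller returning activations in [-1, 1]^3."""

    def __init__(self, spec: PolicySpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        p = spec.params
        self.block = int(p.get("block", 10))
        self.activation = float(p.get("activation", 1.0))
        self.gain = float(p.get("gain", 3.0))
        self.push_through = float(p.get("push_through", 0.4))
        lo, hi = p.get("hold_range", (10, 40))
        self.hold_range = (int(lo), int(hi))
        self._held = np.zeros(3)
        self._until = np.zeros(3, dtype=int)  # babbling per-joint timers
        self._block_until = 0
        self._block_state = None

    def act(self, state: WorldState, arm: int, t: int, config: WorldConfig) -> np.ndarray:
        kind = self.spec.kind
        if kind == "static":
            return np.zeros(3)
        if kind == "babbling":
            for j in range(3):
                if t >= self._until[j]:
                    self._held[j] = self.rng.uniform(-1.0, 1.0)
                    self._until[j] = t + self.rng.integers(
                        self.hold_range[0], self.hold_range[1] + 1
                    )
            return self._held.copy()
        if kind == "goal_directed":
            g = _push_direction(state, arm, config)
            return np.clip(self.gain * g, -1.0, 1.0)
        if kind == "constant_push":
            return self.activation * _push_activation(
                _push_direction(state, arm, config, through=self.push_through)
            )
        # block-switching kinds
        if t >= self._block_until:
            self._block_until = t + self.block
            if kind == "staggered_push":
                self._block_state = self.rng.random() < 0.5
            elif kind == "random_push":
                self._block_state = float(self.rng.uniform(0.0, 1.0))
            elif kind == "random":
                self._block_state = self.rng.uniform(-1.0, 1.0, size=3)
        if kind == "staggered_push":
            if not self._block_state:
                return np.zeros(3)
            return self.activation * _push_activation(
                _push_direction(state, arm, config, through=self.push_through)
            )
        if kind == "random_push":
            return self._block_state * _push_activation(
                _push_direction(state, arm, config, through=self.push_through)
            )
        if kind == "random":
            return np.asarray(self._block_state, dtype=float).copy()
        raise AssertionError(kind)


# ---------------------------------------------------------------------------
# episodes and datasets
# ---------------------------------------------------------------------------


def _config_hash(config: WorldConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_episode(
    policy_lower: PolicySpec,
    policy_upper: PolicySpec,
    n_steps: int,
    seed: int,
    config: WorldConfig | None = None,
) -> Episode:
    """Run one episode; bit-identical for identical (seed, policies, config).

    Each arm's policy draws from its own child RNG stream so that, e.g., two
    babbling arms are statistically independent (a shared stream would induce
    an artificial inter-arm correlation).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    config = config or WorldConfig()
    ss = np.random.SeedSequence(seed)
    ss_lo, ss_up, ss_noise = ss.spawn(3)
    rng_lo = np.random.default_rng(
        policy_lower.seed if policy_lower.seed is not None else ss_lo
    )
    rng_up = np.random.default_rng(
        policy_upper.seed if policy_upper.seed is not None else ss_up
    )
    rng_noise = np.random.default_rng(ss_noise)

    pol_lo = _Policy(policy_lower, rng_lo)
    pol_up = _Policy(policy_upper, rng_up)
    lim = config.joint_speed_limit

    positions = np.empty((n_steps, 7, 2))
    haptics = np.zeros((n_steps, 7))
    motors = np.zeros((n_steps, 6))
    ball_vx = np.zeros(n_steps)
    contact_flags = np.zeros((n_steps, 2), dtype=bool)
    contact_events: list = []
    reset_times: list = []

    state = init_state(config)
    sips = sip_positions(state, config)
    positions[0] = sips
    for t in range(1, n_steps):
        act = np.empty(6)
        act[0:3] = pol_lo.act(state, 0, t - 1, config)
        act[3:6] = pol_up.act(state, 1, t - 1, config)
        state, info = step(state, act * lim, config)

        if not (config.rail_extent[0] <= state.ball_x <= config.rail_extent[1]):
            state = init_state(config)
            state.t = t
            reset_times.append(t)
            info = {"contacts": [], "applied": info["applied"], "touched": set()}

        sips = sip_positions(state, config)
        positions[t] = sips
        motors[t] = info["applied"]
        ball_vx[t] = state.ball_vx
        haptics[t] = compute_haptics(sips, info["contacts"], config)
        for c in info["contacts"]:
            arm = c["arm"]
            contact_flags[t, arm] = True
            arm_sips = sips[3 * arm : 3 * arm + 3]
            nearest = int(
                np.argmin(np.hypot(*(arm_sips - c["point"]).T))
            )
            contact_events.append((t, (3 * arm + nearest, 6)))

    positions = positions + rng_noise.normal(0.0, config.sip_noise_sd, positions.shape)

    meta = {
        "policy_lower": {"kind": policy_lower.kind, "params": policy_lower.params},
        "policy_upper": {"kind": policy_upper.kind, "params": policy_upper.params},
        "seed": int(seed),
        "n_steps": int(n_steps),
        "config_hash": _config_hash(config),
    }
    return Episode(
        positions=positions,
        haptics=haptics,
        motors=motors,
        ball_vx=ball_vx,
        contact_flags=contact_flags,
        contact_events=contact_events,
        reset_times=reset_times,
        meta=meta,
        config=config,
    )


def generate_dataset(recipe: dict, seed: int, config: WorldConfig | None = None) -> list:
    """Generate one of the two canonical datasets.

    recipe = {"kind": "babbling", "n_steps": N}
        One long episode with both arms babbling independently (used for the
        correlation analysis; the reference analysis used 50,000 steps).

    recipe = {"kind": "at_repetitions", "n_repetitions": R, "steps_per_episode": T}
        R short episodes; per episode one arm (chosen with probability 0.5)
        performs a goal-directed approach to the ball while the other moves
        randomly with sustained commands.  Used for the AT/GC/TE matrices
        (the reference analysis used 200 repetitions).
    """
    config = config or WorldConfig()
    kind = recipe.get("kind")
    ss = np.random.SeedSequence(seed)
    if kind == "babbling":
        n = int(recipe.get("n_steps", 10000))
        ep_seed = int(ss.generate_state(1)[0] % (2**31))
        ep = run_episode(
            PolicySpec("babbling"), PolicySpec("babbling"), n, ep_seed, config
        )
        ep.meta["recipe"] = "babbling"
        return [ep]
    if kind == "at_repetitions":
        reps = int(recipe.get("n_repetitions", 200))
        n = int(recipe.get("steps_per_episode", 300))
        chooser = np.random.default_rng(ss.spawn(1)[0])
        episodes = []
        for k in range(reps):
            goal_arm = int(chooser.random() < 0.5)
            pols = [PolicySpec("babbling"), PolicySpec("babbling")]
            pols[goal_arm] = PolicySpec("goal_directed")
            ep_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
            ep = run_episode(pols[0], pols[1], n, ep_seed, config)
            ep.meta["recipe"] = "at_repetitions"
            ep.meta["goal_arm"] = goal_arm
            episodes.append(ep)
        return episodes
    raise ValueError("recipe kind must be 'babbling' or 'at_repetitions'")
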