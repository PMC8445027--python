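"""World configuration for the dual-arm / sliding-ball setup.

Two 3-DOF planar arms face each other across a horizontal rail.  A ball is
constrained to slide along the rail between two end boxes; when it passes
under a box it is reset to the middle.  Seven sensory interest points (SIPs)
are tracked: three per arm (end effector, elbow, shoulder-side joint) and the
ball center.  Each SIP also carries a simulated haptic value derived from its
distance to the nearest contact point.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field


@dataclass
class WorldConfig:
    """Geometry, dynamics and sensing parameters of the simulated world.

    All lengths are in world units, angles in radians, time in seconds.
    The arm bases sit below and above the rail; the default link lengths
    (1.0, 0.8, 0.6) let either end effector comfortably reach the rail.
    Joint speed and travel grow toward the end effector (a wrist is faster
    and freer than a shoulder), which also gives each chain the
    proximo-distal correlation ordering of a real arm.
    """

    link_lengths: tuple[float, float, float] = (1.0, 0.8, 0.6)
    #: bases of (lower, upper) arm; arms face each other across the rail
    arm_base_positions: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, -1.9),
        (0.0, 1.9),
    )
    rail_y: float = 0.0
    rail_extent: tuple[float, float] = (-1.5, 1.5)
    ball_radius: float = 0.12
    #: half thickness of an arm link for capsule-circle contact tests
    arm_radius: float = 0.05
    dt: float = 0.05
    #: max |joint angle change| per step (rad/step); commands are clipped
    #: here.  Small enough that a full-speed end effector (~0.12 units/step)
    #: cannot tunnel through the ball's contact envelope in one step.
    joint_speed_limit: float = 0.05
    #: fraction of ball velocity lost per step; the rail is low-friction so
    #: a launched ball coasts (a strong decay reads as a continuous false
    #: "transfer" out of the ball against any jittering channel)
    friction: float = 0.005
    #: distance at which a simulated haptic signal decays to 0
    haptic_radius: float = 0.5
    #: fraction of the contacting arm's joint speed absorbed while touching
    #: the ball (reaction of the push: the pusher loses speed on impact)
    contact_recoil: float = 0.6
    #: per-step fractional recovery of an arm's speed after contact recoil
    #: (1.0 = the arm regains full speed the step after contact ends)
    recoil_recovery: float = 1.0
    #: tangential coupling of a grazing contact (fraction of the velocity
    #: difference transferred per step while rubbing)
    contact_drag: float = 0.3
    #: restitution of the arm-ball impulse; > 0 sends the ball away faster
    #: than the striking point, so a push is a clean tap rather than a grind
    restitution: float = 0.8
    #: max |deviation| of each joint from its initial angle (rad): the
    #: mechanical travel range of the joint, scaled per joint by joint_profile
    joint_travel: float = 1.2
    #: per-joint scaling (distal, middle, base) of speed limit and travel:
    #: distal joints are fast and free, the base joint slow and limited
    joint_profile: tuple[float, float, float] = (1.0, 0.3, 0.45)
    #: std of Gaussian observation noise on reported SIP positions
    #: (visual feature-extraction jitter)
    sip_noise_sd: float = 0.001
    #: initial joint angles, motor order m0..m5 (m2/m5 are the base joints)
    init_joint_angles: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.init_joint_angles is None:
            # lower tip poised left of the ball just below the rail; upper tip
            # right of the ball just above it, so the arms push in opposite
            # x directions (mirror-symmetric start).
            self.init_joint_angles = tuple(_DEFAULT_POSE)
        self.validate()

    def validate(self) -> None:
        if not all(l > 0 for l in self.link_lengths) or len(self.link_lengths) != 3:
            raise ValueError("link_lengths must be 3 positive lengths")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not 0.0 <= self.friction <= 1.0:
            raise ValueError("friction must be in [0, 1]")
        if not self.rail_extent[0] < self.rail_extent[1]:
            raise ValueError("rail_extent must be nondegenerate")
        if self.ball_radius <= 0 or self.haptic_radius <= 0:
            raise ValueError("radii must be > 0")
        if self.joint_speed_limit <= 0:
            raise ValueError("joint_speed_limit must be > 0")
        if not 0.0 <= self.contact_recoil <= 1.0:
            raise ValueError("contact_recoil must be in [0, 1]")
        if not 0.0 < self.recoil_recovery <= 1.0:
            raise ValueError("recoil_recovery must be in (0, 1]")
        if self.joint_travel <= 0:
            raise ValueError("joint_travel must be > 0")
        if len(self.joint_profile) != 3 or not all(p > 0 for p in self.joint_profile):
            raise ValueError("joint_profile must be 3 positive factors")
        if not 0.0 <= self.contact_drag <= 1.0:
            raise ValueError("contact_drag must be in [0, 1]")
        if self.restitution < 0.0:
            raise ValueError("restitution must be >= 0")
        if len(self.init_joint_angles) != 6:
            raise ValueError("init_joint_angles must have 6 entries")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        d = dict(d)
        for key in ("link_lengths", "rail_extent", "init_joint_angles", "joint_profile"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "arm_base_positions" in d:
            d["arm_base_positions"] = tuple(tuple(p) for p in d["arm_base_positions"])
        return cls(**d)


# Default start pose (motor order m0..m5; m0/m3 distal, m2/m5 base).  The
# lower arm's tip sits left of the ball just below the rail with its last
# link pointing up-right, so a push drives the ball rightward; the upper arm
# is the point mirror (tip right of the ball above the rail, pushing left).
_DEFAULT_POSE = (
    -1.5650,  # m0 lower distal
    -0.5310,  # m1 lower elbow
    2.4000,  # m2 lower base (sin stays positive over the whole travel)
    -1.5650,  # m3 upper distal
    -0.5310,  # m4 upper elbow
    2.4000 + math.pi,  # m5 upper base: point mirror of the lower arm
)
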