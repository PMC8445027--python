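"""World model: passivity of the ball, determinism, contacts, haptics."""

import numpy as np
import pytest

from atgraph.config import WorldConfig
from atgraph.simulator import (
    PolicySpec,
    POLICY_KINDS,
    compute_haptics,
    generate_dataset,
    init_state,
    run_episode,
    sip_positions,
    step,
)


def test_step_rejects_nonfinite_command(world):
    state = init_state(world)
    cmd = np.zeros(6)
    cmd[3] = np.nan
    with pytest.raises(ValueError, match="finite"):
        step(state, cmd, world)


def test_command_clipped_to_joint_speed_limit(world):
    state = init_state(world)
    new, info = step(state, np.full(6, 10.0), world)
    limits = world.joint_speed_limit * np.asarray(world.joint_profile * 2)
    assert np.all(np.abs(info["applied"]) <= limits + 1e-12)


def test_static_world_is_passive(static_episode):
    """Two static arms: no contact ever, ball velocity identically zero."""
    assert static_episode.contact_flags.sum() == 0
    assert not static_episode.contact_events
    assert np.all(static_episode.ball_vx == 0.0)
    assert np.all(static_episode.haptics == 0.0)


def test_ball_speed_increases_only_near_contact(push_episode):
    """|ball_vx| may grow only within one step of a logged contact."""
    vx = np.abs(push_episode.ball_vx)
    contact = push_episode.contact_flags.any(axis=1)
    near = contact.copy()
    near[1:] |= contact[:-1]
    resets = set(push_episode.reset_times)
    grew = np.where(vx[1:] > vx[:-1] + 1e-12)[0] + 1
    for t in grew:
        assert near[t] or t in resets, f"speed grew at t={t} without contact"


def test_seeded_episodes_are_bit_identical():
    a = run_episode(PolicySpec("babbling"), PolicySpec("random"), 150, 9)
    b = run_episode(PolicySpec("babbling"), PolicySpec("random"), 150, 9)
    c = run_episode(PolicySpec("babbling"), PolicySpec("random"), 150, 10)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.motors, b.motors)
    assert a.reset_times == b.reset_times
    assert not np.array_equal(a.positions, c.positions)


def test_constant_push_contacts_ball_and_resets(push_episode):
    """A pushing arm reaches the ball, moves it past a box edge, and the
    world re-centers the ball on the next step."""
    assert push_episode.contact_flags[:, 0].any()
    assert any(pair[1] == 6 for _, pair in push_episode.contact_events)
    assert np.abs(push_episode.ball_vx).max() > 0
    assert push_episode.reset_times
    cfg = push_episode.config
    mid = 0.5 * (cfg.rail_extent[0] + cfg.rail_extent[1])
    for r in push_episode.reset_times:
        assert abs(push_episode.positions[r, 6, 0] - mid) < 10 * cfg.sip_noise_sd


def test_ball_stays_on_rail(push_episode):
    cfg = push_episode.config
    tol = 10 * cfg.sip_noise_sd
    x6 = push_episode.positions[:, 6, 0]
    assert np.all(x6 >= cfg.rail_extent[0] - tol)
    assert np.all(x6 <= cfg.rail_extent[1] + tol)
    assert np.allclose(push_episode.positions[:, 6, 1], cfg.rail_y, atol=tol)


def test_haptics_zero_without_contact_and_bounded(world, push_episode):
    sips = sip_positions(init_state(world), world)
    assert np.all(compute_haptics(sips, [], world) == 0.0)
    h = push_episode.haptics
    assert np.all((h >= 0.0) & (h <= 1.0))
    # h > 0 only at steps with a contact
    contact = push_episode.contact_flags.any(axis=1)
    assert np.all(h[~contact] == 0.0)


def test_haptic_decays_with_distance_to_contact(world):
    """Of two SIPs on the touching body, the nearer one feels more."""
    contact = {"arm": 0, "point": np.array([0.0, 0.0])}
    sips = np.zeros((7, 2))
    sips[0] = (0.05, 0.0)  # near
    sips[1] = (0.3, 0.0)  # farther
    sips[2] = (5.0, 0.0)  # out of haptic range
    h = compute_haptics(sips, [contact], world)
    assert h[0] > h[1] > 0.0
    assert h[2] == 0.0
    # exact at the contact point
    sips[0] = (0.0, 0.0)
    assert compute_haptics(sips, [contact], world)[0] == pytest.approx(1.0)


@pytest.mark.parametrize("kind", POLICY_KINDS)
def test_every_policy_kind_runs(kind):
    ep = run_episode(PolicySpec(kind), PolicySpec("static"), 60, 4)
    assert ep.n_steps == 60
    if kind == "static":
        moved = np.ptp(ep.positions[:, :6, :], axis=0)
        assert moved.max() < 10 * ep.config.sip_noise_sd


def test_unknown_policy_kind_rejected():
    with pytest.raises(ValueError, match="unknown policy"):
        PolicySpec("sprint")


def test_generate_dataset_recipes():
    babble = generate_dataset({"kind": "babbling", "n_steps": 500}, seed=1)
    assert len(babble) == 1 and babble[0].n_steps == 500
    reps = generate_dataset(
        {"kind": "at_repetitions", "n_repetitions": 4, "steps_per_episode": 80}, seed=1
    )
    assert len(reps) == 4
    assert all(ep.meta["goal_arm"] in (0, 1) for ep in reps)
    again = generate_dataset(
        {"kind": "at_repetitions", "n_repetitions": 4, "steps_per_episode": 80}, seed=1
    )
    for a, b in zip(reps, again):
        assert np.array_equal(a.positions, b.positions)
    with pytest.raises(ValueError, match="recipe"):
        generate_dataset({"kind": "mystery"}, seed=1)


def test_run_episode_requires_two_steps(world):
    with pytest.raises(ValueError, match=">= 2"):
        run_episode(PolicySpec("static"), PolicySpec("static"), 1, 0, world)


def test_config_validation():
    with pytest.raises(ValueError):
        WorldConfig(friction=1.5)
    with pytest.raises(ValueError):
        WorldConfig(rail_extent=(1.0, -1.0))
    with pytest.raises(ValueError):
        WorldConfig(dt=0.0)
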