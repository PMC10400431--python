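"""Ball-maze kinematics simulator.

Emulates the 100 Hz motion-sensor record of a mouse navigating a floating
spherical maze toward a hidden goal: an Ornstein-Uhlenbeck speed process
whose set point alternates between rest and movement bouts, and a
wrapped-normal heading random walk whose mean increment drifts toward the
goal in proportion to ``goal_bias``. Positions are tracked in a 2-D virtual
plane (arc-length coordinates on the ball); the goal is a disk whose radius
is the arc subtended by the stated solid-angle cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..behavior import BehaviorTrace, GoalGeometry, classify_frames, detect_rewards
from ..utils import wrap_deg, wrap_signed_deg
from ._truth import GroundTruth


@dataclass
class BehaviorSimConfig:
    duration_s: float = 800.0
    sample_rate: float = 100.0
    goal_center_xy: tuple = (0.45, 0.45)  # maze coords, m
    goal_solid_angle_deg: float = 30.0
    ball_radius_m: float = 1.2192
    # OU speed process: set point alternates between bout states
    speed_tau_s: float = 0.5
    move_speed_mps: float = 0.07
    rest_speed_mps: float = 0.005
    speed_sigma: float = 0.02  # OU diffusion, m/s per sqrt(s)
    bout_mean_rest_s: float = 2.0
    bout_mean_move_s: float = 4.0
    heading_persistence: float = 50.0  # von Mises kappa of heading increments
    goal_bias: float = 0.0  # in [0,1]; steering gain toward the goal
    turn_gain: float = 0.03  # fraction of bearing error corrected per frame
    sensor_noise_mps: float = 0.002
    arena_radius_m: float = 1.5  # soft boundary of the reachable cap
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("duration_s and sample_rate must be positive")
        if not (0 < self.goal_solid_angle_deg <= 180):
            raise ValueError("goal_solid_angle_deg must be in (0, 180]")
        if not (0 <= self.goal_bias <= 1):
            raise ValueError("goal_bias must be in [0, 1]")


def simulate_behavior(config: BehaviorSimConfig) -> tuple[BehaviorTrace, GroundTruth]:
    """Simulate one session; returns the sensor-level trace and ground truth.

    Ground-truth frame states are the rest/movement threshold rules applied
    to the noiseless speed, so a classifier using the same thresholds on the
    (lightly noisy) sensor trace should agree almost everywhere.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.sample_rate))
    dt = 1.0 / config.sample_rate
    t = np.arange(n) * dt

    # rest/movement bout intent as a two-state semi-Markov process
    intent = np.zeros(n, dtype=bool)
    i, state = 0, False  # start at rest
    while i < n:
        mean = config.bout_mean_move_s if state else config.bout_mean_rest_s
        dur = max(1, int(round(rng.exponential(mean) * config.sample_rate)))
        intent[i : i + dur] = state
        i += dur
        state = not state

    target = np.where(intent, config.move_speed_mps, config.rest_speed_mps)
    speed = np.empty(n)
    speed[0] = target[0]
    a = dt / config.speed_tau_s
    dw = rng.standard_normal(n) * config.speed_sigma * np.sqrt(dt)
    for k in range(1, n):
        speed[k] = speed[k - 1] + a * (target[k] - speed[k - 1]) + dw[k]
    np.clip(speed, 0.0, None, out=speed)

    gx, gy = config.goal_center_xy
    heading = np.empty(n)
    heading[0] = rng.uniform(0, 360)
    x = np.empty(n)
    y = np.empty(n)
    # start well away from the goal
    ang0 = rng.uniform(0, 2 * np.pi)
    x[0] = -gx + 0.9 * config.arena_radius_m * np.cos(ang0)
    y[0] = -gy + 0.9 * config.arena_radius_m * np.sin(ang0)

    kappa = config.heading_persistence
    for k in range(1, n):
        # bearing toward the goal (origin of relative coords)
        bearing = np.rad2deg(np.arctan2(-y[k - 1], -x[k - 1]))
        err = wrap_signed_deg(bearing - heading[k - 1])
        mu = config.goal_bias * config.turn_gain * err
        # soft arena boundary: steer back toward the maze center
        ax, ay = x[k - 1] + gx, y[k - 1] + gy
        if np.hypot(ax, ay) > config.arena_radius_m:
            back = np.rad2deg(np.arctan2(-ay, -ax))
            mu += 0.3 * wrap_signed_deg(back - heading[k - 1])
        if np.isinf(kappa):
            inc = mu
        else:
            inc = mu + np.rad2deg(rng.vonmises(0.0, kappa))
        heading[k] = wrap_deg(heading[k - 1] + inc)
        step = speed[k] * dt
        x[k] = x[k - 1] + step * np.cos(np.deg2rad(heading[k]))
        y[k] = y[k - 1] + step * np.sin(np.deg2rad(heading[k]))

    rl = speed * np.cos(np.deg2rad(heading))
    fb = speed * np.sin(np.deg2rad(heading))
    noise = config.sensor_noise_mps
    fb_obs = fb + rng.standard_normal(n) * noise
    rl_obs = rl + rng.standard_normal(n) * noise

    goal = GoalGeometry(config.ball_radius_m, config.goal_solid_angle_deg)
    trace = BehaviorTrace(
        time_s=t,
        fb_speed=fb_obs,
        rl_speed=rl_obs,
        x=x,
        y=y,
        sample_rate=config.sample_rate,
        goal_offset_xy=(gx, gy),
    )

    clean = BehaviorTrace(
        time_s=t,
        fb_speed=fb,
        rl_speed=rl,
        x=x,
        y=y,
        sample_rate=config.sample_rate,
        goal_offset_xy=(gx, gy),
    )
    states_true = classify_frames(clean)
    md_true = np.where(states_true.is_movement, heading, np.nan)
    rewards, _, _ = detect_rewards(clean, goal)

    truth = GroundTruth(
        frame_state_true=states_true.state,
        md_true=md_true,
        goal_center_xy=(gx, gy),
        reward_times_true=rewards,
    )
    return trace, truth
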