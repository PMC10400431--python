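"""Behavioral state extraction and performance metrics on the ball maze.

A head-fixed mouse navigates a floating spherical treadmill toward a hidden
goal location. The ball's motion sensor yields 100 Hz forward-backward and
right-left translational speeds, from which we derive per-frame rest/movement
states, the instantaneous movement direction (MD), reward events under a 3-s
refractory rule, and session-level performance metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .utils import circ_dist_deg, loess_smooth, wrap_deg, wrap_signed_deg

REST_SPEED = 0.02  # m/s; below this (and low accel) a frame is rest
REST_ACCEL = 0.2  # m/s^2 magnitude bound for rest
MOVE_SPEED = 0.03  # m/s; above this a non-rest frame is movement
SHORT_BOUT_S = 1.0  # uncategorized bouts shorter than this, rest-flanked -> rest
REWARD_REFRACTORY_S = 3.0


@dataclass
class GoalGeometry:
    """Hidden goal: a spherical cap on the ball, given by its solid-angle aperture."""

    ball_radius_m: float = 1.2192  # 8-ft-diameter ball
    solid_angle_deg: float = 30.0  # full aperture of the goal cap

    @property
    def cap_half_angle_deg(self) -> float:
        return self.solid_angle_deg / 2.0

    @property
    def radius_m(self) -> float:
        """Goal radius as arc length on the ball surface."""
        return self.ball_radius_m * np.deg2rad(self.cap_half_angle_deg)


@dataclass
class BehaviorTrace:
    """Kinematic record of one session, sampled uniformly.

    ``x``/``y`` are 2-D virtual coordinates (m) relative to the goal center;
    ``fb_speed``/``rl_speed`` are signed translational speeds whose arctangent
    defines the movement direction.
    """

    time_s: np.ndarray
    fb_speed: np.ndarray
    rl_speed: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float
    speed: np.ndarray = field(default=None)
    accel: np.ndarray = field(default=None)
    # maze coords of the goal center; quadrant occupancy is computed in maze
    # coords (x + gx, y + gy), which reduce to goal-centered quadrants when
    # the offset is unknown
    goal_offset_xy: tuple = (0.0, 0.0)

    def __post_init__(self):
        for name in ("time_s", "fb_speed", "rl_speed", "x", "y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.speed is None:
            self.speed = np.hypot(self.fb_speed, self.rl_speed)
        else:
            self.speed = np.asarray(self.speed, dtype=float)
        if self.accel is None:
            self.accel = np.gradient(self.speed, self.time_s)
        else:
            self.accel = np.asarray(self.accel, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.all(np.isfinite(self.speed)):
            raise ValueError("non-finite speed values")

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    def to_frame(self, states=None, md=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.time_s,
                "fb_speed": self.fb_speed,
                "rl_speed": self.rl_speed,
                "speed": self.speed,
                "accel": self.accel,
                "x": self.x,
                "y": self.y,
            }
        )
        if states is not None:
            df["state"] = states.state
        if md is not None:
            df["md_deg"] = md
        return df


@dataclass
class FrameStates:
    """Exhaustive per-frame rest/movement labels plus the bout partition."""

    state: np.ndarray  # array of 'rest' / 'movement'
    bouts: list  # (start, end_exclusive, label) tiling the session

    @property
    def is_movement(self) -> np.ndarray:
        return self.state == "movement"

    @property
    def is_rest(self) -> np.ndarray:
        return self.state == "rest"


@dataclass
class BehaviorMetrics:
    n_success: int
    latency_s: float
    quadrant_occupancy: np.ndarray  # 4 fractions, sum 1
    goal_proximity_deg: float
    movement_accuracy_pct: float  # NaN when no movement frames
    cumulative_turning_deg: float
    turning_series_deg: np.ndarray


def smooth_kinematics(trace: BehaviorTrace, span_s: float = 0.5) -> BehaviorTrace:
    """LOWESS-smooth the kinematic channels with a 500-ms window.

    Speed magnitude and acceleration are recomputed from the smoothed
    signed speeds; endpoints are handled by the shrinking-window behaviour
    of the local regression.
    """
    if trace.n_frames < trace.sample_rate:
        raise ValueError("need at least 1 s of data to smooth")
    span = max(3, int(round(span_s * trace.sample_rate)))
    fb = loess_smooth(trace.fb_speed, span)
    rl = loess_smooth(trace.rl_speed, span)
    speed = loess_smooth(trace.speed, span)
    accel = np.gradient(speed, trace.time_s)
    return replace(trace, fb_speed=fb, rl_speed=rl, speed=speed, accel=accel)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous runs of equal values: (start, end_exclusive, value)."""
    n = labels.size
    if n == 0:
        return []
    edges = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [n]))
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


def classify_frames(trace: BehaviorTrace) -> FrameStates:
    """Label every frame rest or movement.

    Rules: rest if speed < 0.02 m/s and |accel| < 0.2 m/s^2; movement if
    speed > 0.03 m/s and not rest. Uncategorized bouts are resolved by their
    flanking states: rest on both sides and shorter than 1 s -> rest; both
    sides movement, or the two sides differing -> movement. A bout rest-
    flanked on both sides but lasting >= 1 s never crossed the movement
    threshold and is labeled rest. A session-edge bout follows its single
    flank (rest if the whole session is uncategorized).
    """
    speed = trace.speed
    accel = np.abs(trace.accel)
    # 0 = rest, 1 = movement, -1 = uncategorized
    lab = np.full(trace.n_frames, -1, dtype=np.int8)
    rest = (speed < REST_SPEED) & (accel < REST_ACCEL)
    lab[rest] = 0
    lab[(speed > MOVE_SPEED) & ~rest] = 1

    short = int(np.ceil(SHORT_BOUT_S * trace.sample_rate))
    for s, e, v in _runs(lab):
        if v != -1:
            continue
        left = lab[s - 1] if s > 0 else None
        right = lab[e] if e < lab.size else None
        if left is None and right is None:
            lab[s:e] = 0
        elif left is None or right is None:
            lab[s:e] = left if right is None else right
        elif left == 0 and right == 0:
            # < 1 s -> rest by the stated rule; >= 1 s -> rest as well,
            # since the speed never crossed the movement threshold
            lab[s:e] = 0
        else:
            lab[s:e] = 1

    state = np.where(lab == 1, "movement", "rest")
    bouts = [(s, e, "movement" if v else "rest") for s, e, v in _runs(lab)]
    return FrameStates(state=state, bouts=bouts)


def movement_direction(trace: BehaviorTrace, states: FrameStates) -> np.ndarray:
    """Per-frame movement direction in degrees [0, 360).

    MD = atan2(forward-backward speed, right-left speed); defined on
    movement frames only, NaN elsewhere and on zero-speed movement frames.
    """
    md = np.full(trace.n_frames, np.nan)
    mov = states.is_movement
    fb, rl = trace.fb_speed, trace.rl_speed
    nonzero = mov & ((fb != 0) | (rl != 0))
    md[nonzero] = wrap_deg(np.rad2deg(np.arctan2(fb[nonzero], rl[nonzero])))
    return md


def detect_rewards(
    trace: BehaviorTrace, goal: GoalGeometry | None = None
) -> tuple[np.ndarray, int, np.ndarray]:
    """Reward events under the 3-s refractory rule.

    A reward is delivered whenever the animal is on the goal location and at
    least 3 s have elapsed since the last reward; a stay inside the goal thus
    yields refractory-spaced rewards, and a re-entry within 3 s yields none.

    Returns (reward_times_s, n_success, latency_s per reward). Latencies are
    measured from the session start for the first reward and from the
    previous reward thereafter.
    """
    goal = goal or GoalGeometry()
    dist = np.hypot(trace.x, trace.y)
    in_goal = dist <= goal.radius_m
    reward_times = []
    last = -np.inf
    for t, g in zip(trace.time_s, in_goal):
        if g and (t - last) >= REWARD_REFRACTORY_S:
            reward_times.append(t)
            last = t
    reward_times = np.asarray(reward_times)
    if reward_times.size:
        latencies = np.diff(np.concatenate(([trace.time_s[0]], reward_times)))
    else:
        latencies = np.asarray([])
    return reward_times, int(reward_times.size), latencies


def goal_angle_halfwidth(trace: BehaviorTrace, goal: GoalGeometry) -> np.ndarray:
    """Half-width (deg) of the angular window subtending the goal cap from
    the current position; 180 deg when the animal is inside the goal."""
    dist = np.hypot(trace.x, trace.y)
    half = np.full(trace.n_frames, 180.0)
    outside = dist > goal.radius_m
    half[outside] = np.rad2deg(np.arcsin(np.clip(goal.radius_m / dist[outside], 0, 1)))
    return half


def behavior_metrics(
    trace: BehaviorTrace,
    states: FrameStates,
    md: np.ndarray,
    reward_times: np.ndarray,
    latencies: np.ndarray,
    goal: GoalGeometry | None = None,
) -> BehaviorMetrics:
    """Session-level performance metrics.

    movement_accuracy: percent of movement frames whose MD points within the
    goal window (the angular window subtending the goal cap from the current
    position). goal_proximity: mean great-circle angular distance to the goal
    center. quadrant_occupancy: fraction of frames in each maze quadrant.
    cumulative_turning: integral of signed MD change over movement frames
    (CCW positive).
    """
    goal = goal or GoalGeometry()
    mov = states.is_movement

    bearing = wrap_deg(np.rad2deg(np.arctan2(-trace.y, -trace.x)))
    half = goal_angle_halfwidth(trace, goal)
    valid = mov & np.isfinite(md)
    if valid.sum() > 0:
        hit = circ_dist_deg(md[valid], bearing[valid]) <= half[valid]
        accuracy = 100.0 * hit.mean()
    else:
        accuracy = np.nan

    dist = np.hypot(trace.x, trace.y)
    proximity = float(np.mean(np.rad2deg(dist / goal.ball_radius_m)))

    gx, gy = trace.goal_offset_xy
    qx, qy = (trace.x + gx) >= 0, (trace.y + gy) >= 0
    occ = np.array(
        [
            np.mean(qx & qy),
            np.mean(~qx & qy),
            np.mean(~qx & ~qy),
            np.mean(qx & ~qy),
        ]
    )

    turning = np.zeros(trace.n_frames)
    md_mov = md[valid]
    if md_mov.size >= 2:
        dmd = wrap_signed_deg(np.diff(md_mov))
        series = np.concatenate(([0.0], np.cumsum(dmd)))
        turning[np.flatnonzero(valid)] = series
        # hold the running total between movement frames
        turning = pd.Series(np.where(valid, turning, np.nan)).ffill().fillna(0.0).to_numpy()
        total = float(series[-1])
    else:
        total = 0.0

    return BehaviorMetrics(
        n_success=int(np.asarray(reward_times).size),
        latency_s=float(np.mean(latencies)) if np.asarray(latencies).size else np.nan,
        quadrant_occupancy=occ,
        goal_proximity_deg=proximity,
        movement_accuracy_pct=accuracy,
        cumulative_turning_deg=total,
        turning_series_deg=turning,
    )
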