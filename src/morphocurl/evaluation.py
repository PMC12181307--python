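"""Evaluation protocols: velocity errors, perturbation ladder, ramps, gait.

Protocols mirror the training-free robustness assessments: external pushes
at the torso COM every 4 s lasting 1 s with alternating direction, ramped
target-velocity traces (0 for 100 steps, linear 1.2 -> 3.4 over 700, hold
3.4 for 200; the decrease protocol reversed with an abrupt final drop to 0),
and gait-cycle summaries (joint angles and vertical ground reaction force
resampled to % gait cycle, cycles segmented at heel strike).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

RAMP_LENGTH = 1000
WALK_SPEED = 1.2
MAX_SPEED = 3.4


@dataclass
class RolloutRecord:
    """Per-step time series of one evaluation episode (SI units)."""

    dt: float
    horizon: int
    vx: np.ndarray
    rewards: Optional[np.ndarray] = None
    joint_angles: Optional[Dict[str, np.ndarray]] = None  # e.g. "hip_l" -> rad
    grf: Optional[Dict[str, np.ndarray]] = None           # "left"/"right" -> N
    body_weight: Optional[float] = None
    events: List[str] = field(default_factory=list)

    @property
    def achieved_fraction(self) -> float:
        return len(self.vx) / self.horizon


# ---------------------------------------------------------------------------
# velocity error


def velocity_error(rollout: RolloutRecord, v_star: float, task: str) -> float:
    """Velocity tracking error.

    balance: mean |v_x| divided by the achieved episode-length fraction, so
    early falls are penalized rather than rewarded for short exposure.
    gait: mean |v_x - v*| / v*, dimensionless, comparable across bodies.
    """
    if len(rollout.vx) == 0:
        raise ValueError("rollout has no velocity trace")
    if task == "balance":
        return float(np.mean(np.abs(rollout.vx)) / rollout.achieved_fraction)
    if task in ("walking", "running"):
        if v_star <= 0:
            raise ValueError("gait velocity error needs v* > 0 (wrong branch?)")
        return float(np.mean(np.abs(rollout.vx - v_star)) / v_star)
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# perturbation protocol


@dataclass
class PerturbationProtocol:
    """Pushes at the torso COM: every ``onset_interval`` s, ``duration`` s each.

    Direction alternates after a seeded initial sign.  In the planar model
    only the x (sagittal) axis exists; requesting z raises.
    """

    axis: str = "x"
    onset_interval: float = 4.0
    duration: float = 1.0
    force_magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis not in ("x", "z"):
            raise ValueError("axis must be x or z")
        if not self.onset_interval > self.duration > 0:
            raise ValueError("require onset_interval > duration > 0")

    def initial_direction(self) -> int:
        return 1 if np.random.default_rng(self.seed).integers(2) else -1

    def force_at(self, t: float, magnitude: Optional[float] = None) -> float:
        """Signed force at time t: onsets at t = k * onset_interval, k >= 1."""
        mag = self.force_magnitude if magnitude is None else magnitude
        k = math.floor(t / self.onset_interval)
        if k < 1:
            return 0.0
        within = t - k * self.onset_interval
        if within >= self.duration:
            return 0.0
        sign = self.initial_direction() * (1 if k % 2 == 1 else -1)
        return sign * mag


def perturbation_test(
    policy: Callable[[np.ndarray], np.ndarray],
    env,
    protocol: PerturbationProtocol,
    ladder_step: float = 5.0,
    max_force: float = 200.0,
) -> float:
    """Largest push magnitude (N) survived for a full episode.

    Runs episodes of increasing force magnitude (ladder search in
    ``ladder_step`` increments) until the policy falls; deterministic for a
    deterministic policy and fixed protocol seed.  Returns 0 if even the
    unperturbed episode ends in a fall.
    """
    if protocol.axis == "z":
        raise ValueError("the planar model has no z axis; use axis='x'")
    magnitude = 0.0
    withstood = -1.0
    while magnitude <= max_force:
        obs = env.reset(seed=protocol.seed)
        fell = False
        done = False
        t = 0.0
        while not done:
            f = protocol.force_at(t, magnitude)
            obs, _, terminated, truncated, _ = env.step(policy(obs), ext_force=(f, 0.0))
            t += env.sim.dt
            fell = terminated
            done = terminated or truncated
        if fell:
            break
        withstood = magnitude
        magnitude += ladder_step
    return max(withstood, 0.0)


# ---------------------------------------------------------------------------
# velocity ramps


def velocity_ramp_protocol(direction: str) -> np.ndarray:
    """Per-step adult-scale target-velocity trace of length 1000.

    increase: 100 steps at 0, linear 1.2 -> 3.4 over 700 steps, 200 at 3.4.
    decrease: 100 steps at 3.4, linear 3.4 -> 1.2 over 700 steps, then an
    abrupt drop to 0 for the final 200 steps (not the mirror image of the
    increase protocol).
    """
    if direction == "increase":
        return np.concatenate(
            [
                np.zeros(100),
                np.linspace(WALK_SPEED, MAX_SPEED, 700),
                np.full(200, MAX_SPEED),
            ]
        )
    if direction == "decrease":
        return np.concatenate(
            [
                np.full(100, MAX_SPEED),
                np.linspace(MAX_SPEED, WALK_SPEED, 700),
                np.zeros(200),
            ]
        )
    raise ValueError("direction must be 'increase' or 'decrease'")


# ---------------------------------------------------------------------------
# gait metrics


HEEL_STRIKE_THRESHOLD = 0.05  # fraction of body weight, rising edge
CYCLE_POINTS = 101


def _detect_heel_strikes(grf: np.ndarray, body_weight: float) -> np.ndarray:
    above = grf > HEEL_STRIKE_THRESHOLD * body_weight
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return rising


def _resample_cycle(signal: np.ndarray, start: int, stop: int) -> np.ndarray:
    x = np.linspace(0.0, 1.0, stop - start)
    xi = np.linspace(0.0, 1.0, CYCLE_POINTS)
    return np.interp(xi, x, signal[start:stop])


def gait_metrics(rollout: RolloutRecord, window: float = 10.0) -> pd.DataFrame:
    """Per-gait-cycle mean and SD of joint angles and vertical GRF.

    Cycles are segmented at heel strike (vertical GRF rising through 5% of
    body weight), resampled to 101 points (% gait cycle), and pooled over
    both legs within the trailing ``window`` seconds.  Raises if fewer than
    two cycles are found.
    """
    if rollout.joint_angles is None or rollout.grf is None or rollout.body_weight is None:
        raise ValueError("rollout lacks joint angles / GRF / body weight")
    n_window = min(int(round(window / rollout.dt)), len(rollout.vx))
    start0 = len(rollout.vx) - n_window

    pooled: Dict[str, List[np.ndarray]] = {
        "hip": [], "knee": [], "ankle": [], "grf": []
    }
    for side, grf_key in (("l", "left"), ("r", "right")):
        grf = rollout.grf[grf_key][start0:]
        strikes = _detect_heel_strikes(grf, rollout.body_weight)
        for s0, s1 in zip(strikes[:-1], strikes[1:]):
            if s1 - s0 < 2:
                continue
            for joint in ("hip", "knee", "ankle"):
                sig = rollout.joint_angles[f"{joint}_{side}"][start0:]
                pooled[joint].append(_resample_cycle(sig, s0, s1))
            pooled["grf"].append(_resample_cycle(grf, s0, s1))

    n_cycles = len(pooled["grf"])
    if n_cycles < 2:
        raise ValueError(f"found {n_cycles} gait cycle(s); need at least 2")

    out = {"percent_cycle": np.linspace(0, 100, CYCLE_POINTS)}
    for key in ("hip", "knee", "ankle", "grf"):
        arr = np.stack(pooled[key])
        out[f"{key}_mean"] = arr.mean(axis=0)
        out[f"{key}_sd"] = arr.std(axis=0)
    df = pd.DataFrame(out)
    df.attrs["n_cycles"] = n_cycles
    return df
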