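"""Task rewards and observation construction for balance, walking, running.

Every performance measure is the same Gaussian-of-error kernel

    R = exp(-k ((a* - a)/s)^2),

with ``a`` the measured quantity, ``a*`` its target, ``k`` a sensitivity,
and ``s`` the Hof scale of the quantity (sqrt(g l0) for velocities, l0 for
positions, 1 for orientation), so rewards are identical for dynamically
similar states across body sizes.

The total reward is piecewise on the task:

* balance (v* = 0): sum of four unit-weight components — forward velocity,
  vertical velocity, lateral position, torso orientation — maximum 4.0;
* gait (v* > 0): 3.5 * R_forward + 0.5 * R_lateral, same maximum 4.0, with
  the forward sensitivity recomputed per morphology as k = 10 sqrt(l) / v*
  (l the leg-length ratio to the adult, v* the model-scaled target), which
  is stage-invariant for Froude-scaled targets.

In the planar model the lateral (z) channel is degenerate: R_lateral is
identically 1 and the lateral observation error identically 0.  Both are
kept in the schema for forward compatibility with a 3-D body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from morphocurl.hofnorm import HofScales


@dataclass
class RewardParams:
    """All reward constants; sensitivities k are dimensionless."""

    k_vx_b: float = 500.0
    k_vy_b: float = 500.0
    k_pz_b: float = 500.0
    k_oz_b: float = 500.0
    k_pz_g: float = 10.0
    c_vx_g: float = 3.5
    c_pz_g: float = 0.5
    v_star: float = 0.0       # model-scale target forward velocity, m/s
    leg_ratio: float = 1.0    # l0_model / l0_adult

    def __post_init__(self) -> None:
        for name in ("k_vx_b", "k_vy_b", "k_pz_b", "k_oz_b", "k_pz_g"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.c_vx_g < 0 or self.c_pz_g < 0:
            raise ValueError("gait weights must be >= 0")
        if self.v_star < 0:
            raise ValueError("v_star must be >= 0")

    @property
    def k_vx_g(self) -> float:
        """Forward-velocity sensitivity 10 sqrt(l)/v*, recomputed, never stored."""
        if self.v_star <= 0:
            raise ValueError("k_vx_g is defined only for gait targets (v* > 0)")
        return 10.0 * math.sqrt(self.leg_ratio) / self.v_star

    @property
    def is_balance(self) -> bool:
        return self.v_star == 0.0


def reward_component(a: float, a_star: float, k: float, s: float) -> float:
    """exp(-k ((a*-a)/s)^2): 1 iff on target, symmetric, in (0, 1]."""
    if s <= 0 or k <= 0:
        raise ValueError("require s > 0 and k > 0")
    e = (a_star - a) / s
    return math.exp(-k * e * e)


@dataclass
class TaskState:
    """The kinematic quantities the reward reads (SI units)."""

    vx: float           # forward COM velocity
    vy: float           # vertical COM velocity
    pitch: float        # torso orientation, rad
    pz: float = 0.0     # lateral position (identically 0 in the planar model)


def total_reward(state: TaskState, params: RewardParams, scales: HofScales) -> float:
    """Piecewise total reward; both branches share the maximum 4.0."""
    s_v = scales.velocity
    s_p = scales.length
    if params.is_balance:
        return (
            reward_component(state.vx, 0.0, params.k_vx_b, s_v)
            + reward_component(state.vy, 0.0, params.k_vy_b, s_v)
            + reward_component(state.pz, 0.0, params.k_pz_b, s_p)
            + reward_component(state.pitch, 0.0, params.k_oz_b, 1.0)
        )
    return params.c_vx_g * reward_component(
        state.vx, params.v_star, params.k_vx_g, s_v
    ) + params.c_pz_g * reward_component(state.pz, 0.0, params.k_pz_g, s_p)


MAX_TOTAL_REWARD = 4.0


# ---------------------------------------------------------------------------
# observations


@dataclass
class Observation:
    """Normalized sensor bundle handed to the learner at 100 Hz."""

    muscle_lengths: np.ndarray
    muscle_velocities: np.ndarray
    muscle_forces: np.ndarray
    torso_orientation: float
    torso_angular_velocity: float
    dof_angles: np.ndarray
    dof_angular_velocities: np.ndarray
    grf_left_vertical: float
    grf_right_vertical: float
    dvx: float
    dvy: float
    dz: float

    def vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.muscle_lengths,
                self.muscle_velocities,
                self.muscle_forces,
                [self.torso_orientation, self.torso_angular_velocity],
                self.dof_angles,
                self.dof_angular_velocities,
                [
                    self.grf_left_vertical,
                    self.grf_right_vertical,
                    self.dvx,
                    self.dvy,
                    self.dz,
                ],
            ]
        )

    @property
    def size(self) -> int:
        return self.vector().size


def build_observation(sim, params: RewardParams, scales: HofScales) -> Observation:
    """Assemble the Hof-normalized observation from simulator diagnostics.

    Muscle length/velocity/force use the Hof length, velocity, and force
    scales; joint and torso angles pass through in radians (already
    dimensionless); angular velocities divide by sqrt(g/l0); vertical GRFs
    divide by body weight.  Task errors are normalized target differences.
    Deterministic given the simulator state.
    """
    m = sim.model
    vcom = sim.com_velocity()
    rev = [d for d in range(3, m.n_dof) if m.dof_is_rev[d]]
    return Observation(
        muscle_lengths=sim._mlen / scales.length,
        muscle_velocities=sim._mvel / scales.velocity,
        muscle_forces=sim._mforce / scales.force,
        torso_orientation=sim.torso_pitch(),
        torso_angular_velocity=float(sim._w[sim._torso]) / scales.angular_velocity,
        dof_angles=sim.q[rev].copy(),
        dof_angular_velocities=sim.v[rev] / scales.angular_velocity,
        grf_left_vertical=float(sim._grf[0]) / scales.force,
        grf_right_vertical=float(sim._grf[1]) / scales.force,
        dvx=(float(vcom[0]) - params.v_star) / scales.velocity,
        dvy=float(vcom[1]) / scales.velocity,
        dz=0.0,
    )
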