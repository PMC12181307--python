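"""Environments: the muscle-actuated biped task and a 1-muscle toy pendulum.

Both follow the now-conventional episodic interface — ``reset(seed) -> obs``
and ``step(action) -> (obs, reward, terminated, truncated, info)`` — plus
the attributes the curriculum trainer needs (``obs_dim``, ``act_dim``,
``leg_ratio``, ``set_task``).  Actions are muscle excitations; anything
outside [0, 1] is clipped by the environment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from morphocurl.curriculum import TaskSpec
from morphocurl.dynamics import (
    DEFAULT_HORIZON,
    PlanarBiped,
    SimulationDiverged,
    check_termination,
    compile_model,
)
from morphocurl.morphology import MorphologySpec, bundled_morphology
from morphocurl.task_rewards import (
    RewardParams,
    TaskState,
    build_observation,
    total_reward,
)


class LocomotionEnv:
    """Balance/walk/run task on one morphology at 100 Hz, 1000-step horizon."""

    def __init__(
        self,
        spec: MorphologySpec,
        adult_leg_length: Optional[float] = None,
        horizon: int = DEFAULT_HORIZON,
        substeps: int = 10,
        reward_params: Optional[RewardParams] = None,
        constraints=None,
    ):
        self.spec = spec
        self.model = compile_model(spec, constraints)
        self.sim = PlanarBiped(self.model, substeps=substeps)
        self.horizon = horizon
        self.scales = spec.hof_scales()
        ref = adult_leg_length if adult_leg_length is not None else spec.leg_length
        self.leg_ratio = spec.leg_length / ref
        self.params = reward_params or RewardParams(leg_ratio=self.leg_ratio)
        self.act_dim = self.model.n_muscles
        self._rng = np.random.default_rng(0)
        self.obs_dim = self._observe().size

    def set_task(self, task: TaskSpec) -> None:
        self.params = RewardParams(
            v_star=task.v_star_model,
            leg_ratio=self.leg_ratio,
        )

    def _observe(self):
        return build_observation(self.sim, self.params, self.scales).vector()

    def reset(self, seed: Optional[int] = None) -> np.ndarray:
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self.sim.reset(rng=self._rng, jitter_deg=0.5)
        self._steps = 0
        return self._observe()

    def step(self, action: np.ndarray, ext_force=(0.0, 0.0)):
        """Advance one control step; ``ext_force`` is an optional (x, y)
        perturbation applied at the torso COM (used by robustness tests)."""
        u = np.clip(np.asarray(action, dtype=float), 0.0, 1.0)
        try:
            self.sim.step(u, ext_force=ext_force)
        except SimulationDiverged:
            return self._last_safe_obs(), 0.0, True, False, {"diverged": True}
        self._steps += 1
        vcom = self.sim.com_velocity()
        state = TaskState(
            vx=float(vcom[0]), vy=float(vcom[1]), pitch=self.sim.torso_pitch()
        )
        r = total_reward(state, self.params, self.scales)
        terminated = check_termination(self.sim) == "fallen"
        truncated = self._steps >= self.horizon
        return self._observe(), r, terminated, truncated, {}

    def _last_safe_obs(self) -> np.ndarray:
        return np.zeros(self.obs_dim)


def locomotion_env_factory(
    adult_leg_length: Optional[float] = None, **kwargs
):
    """Factory ``stage -> LocomotionEnv`` for the curriculum trainer."""
    if adult_leg_length is None:
        adult_leg_length = bundled_morphology("adult").leg_length

    def factory(stage: str) -> LocomotionEnv:
        return LocomotionEnv(
            bundled_morphology(stage), adult_leg_length=adult_leg_length, **kwargs
        )

    return factory


# ---------------------------------------------------------------------------
# toy pendulum


@dataclass
class PendulumParams:
    """Muscle-driven inverted pendulum, balanceable only by graded pulling.

    The rod balances at a target lean ``theta_star`` on the far side of
    vertical from the muscle: gravity pulls it over, the single muscle can
    only pull it back.  Overpulling past vertical is unrecoverable, so a
    random policy fails quickly while a graded policy can hold the target.
    """

    length: float = 1.0
    mass: float = 5.0
    com: float = 0.5
    gravity: float = 9.81
    moment_arm: float = 0.05
    f_max: float = 400.0
    tau_act: float = 0.01
    tau_deact: float = 0.04
    damping: float = 0.5
    theta_star: float = 0.15
    theta_fail_low: float = 0.0
    theta_fail_high: float = 0.6
    k_reward: float = 100.0
    dt: float = 0.01
    substeps: int = 2
    horizon: int = 200


class MusclePendulumEnv:
    """1-muscle inverted-pendulum balance task (closed-form dynamics)."""

    def __init__(self, params: Optional[PendulumParams] = None):
        self.p = params or PendulumParams()
        self.obs_dim = 4
        self.act_dim = 1
        self.leg_ratio = 1.0
        self._rng = np.random.default_rng(0)
        self.inertia = self.p.mass * self.p.length**2 / 3.0

    def set_task(self, task: TaskSpec) -> None:
        pass  # single balance task

    def _obs(self) -> np.ndarray:
        return np.array(
            [self.theta, self.omega / 5.0, self.a, self.theta - self.p.theta_star]
        )

    def reset(self, seed: Optional[int] = None) -> np.ndarray:
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self.theta = self.p.theta_star + self._rng.normal(0.0, 0.05)
        self.theta = float(np.clip(self.theta, 0.05, 0.4))
        self.omega = 0.0
        self.a = 0.0
        self._steps = 0
        return self._obs()

    def step(self, action):
        p = self.p
        u = float(np.clip(np.asarray(action, dtype=float).ravel()[0], 0.0, 1.0))
        tau = p.tau_act if u > self.a else p.tau_deact
        self.a = u + (self.a - u) * math.exp(-p.dt / tau)
        dt = p.dt / p.substeps
        for _ in range(p.substeps):
            torque = (
                p.mass * p.gravity * p.com * math.sin(self.theta)
                - p.moment_arm * p.f_max * self.a
                - p.damping * self.omega
            )
            self.omega += dt * torque / self.inertia
            self.theta += dt * self.omega
        self._steps += 1
        err = self.theta - p.theta_star
        r = math.exp(-p.k_reward * err * err)
        terminated = not (p.theta_fail_low < self.theta < p.theta_fail_high)
        truncated = self._steps >= p.horizon
        return self._obs(), r, terminated, truncated, {}


def pendulum_check_config(seed: int = 0):
    """Frozen conditions of the scaled-down pendulum learning check.

    A 50k-step budget with 128-unit networks and 25 batches per 250
    environment steps; these are the study conditions under which trained
    MPO is compared against the uniform-random excitation baseline.
    """
    from morphocurl.mpo import MPOConfig

    return MPOConfig(
        hidden_layers=(128, 128),
        initial_steps=2000,
        buffer_size=100_000,
        batch_size=128,
        steps_between_batches=250,
        batches_per_update=25,
        polyak_tau=0.02,
        seed=seed,
    )
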