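"""Exploration analysis: white-noise workspace coverage and the DEP baseline.

The toy experiment quantifies how body morphology shapes exploration: the
pelvis is fixed in space, one leg is immobilized, the frontal-plane
placeholder muscles are disabled, and i.i.d. uniform white-noise excitations
are applied to the nine sagittal muscles of the free leg.  The swinging
foot's center-of-mass position (relative to the hip) and velocity are
recorded, Hof-normalized, and summarized as occupancy fractions on a fixed
normalized grid plus convex-hull areas.  Because a lighter leg under
stage-invariant normalized muscle strength accelerates faster, the
ontogenetically scaled 4-year-old covers the largest normalized workspace,
the uniformly scaled 4-year-old less, and the adult the least.

Differential extrinsic plasticity (DEP) is included as an exploration
baseline: a control matrix C is driven toward the outer product of
time-lagged muscle-length-velocity signals, tau * dC/dt = ldot_t ldot_{t-dt}^T - C,
and read out through a normalized linear-sigmoid map onto muscle
excitations.  This is a minimal variant of the published controller family,
not a reproduction of any full DEP-RL stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from morphocurl.dynamics import (
    CompiledModel,
    Constraints,
    PlanarBiped,
    SimulationDiverged,
    compile_model,
    FRONTAL_MUSCLES,
)
from morphocurl.morphology import MorphologySpec

DEFAULT_EPISODES = 50
DEFAULT_STEPS = 1000
POSITION_BOUNDS = (-1.25, 1.25)  # foot COM rel. hip, in leg lengths (reach <= ~1.1)
VELOCITY_BOUNDS = (-0.25, 0.25)  # in sqrt(g l0), sized to the sub-saturation regime
DEFAULT_GRID = 50


def toy_constraints(free_leg: str = "left") -> Constraints:
    """Fixed pelvis, contralateral leg immobilized, frontal muscles disabled."""
    other = "right" if free_leg == "left" else "left"
    return Constraints(
        fix_pelvis=True,
        immobilize_leg=other,
        disable_muscles=FRONTAL_MUSCLES,
    )


@dataclass
class RolloutSeries:
    """Hof-normalized foot-COM samples from white-noise rollouts."""

    position: np.ndarray   # (n_samples, 2), leg lengths
    velocity: np.ndarray   # (n_samples, 2), sqrt(g l0)
    n_episodes: int
    steps_per_episode: int
    truncated_episodes: int = 0


@dataclass
class CoverageResult:
    occupancy_fraction_position: float
    occupancy_fraction_velocity: float
    hull_area_position: float
    hull_area_velocity: float
    n_samples: int


def run_white_noise_rollouts(
    spec: MorphologySpec,
    constraints: Optional[Constraints] = None,
    n_episodes: int = DEFAULT_EPISODES,
    steps_per_episode: int = DEFAULT_STEPS,
    noise_amplitude: float = 0.3,
    seed: int = 0,
    substeps: int = 20,
    free_leg: str = "left",
) -> RolloutSeries:
    """Apply per-step i.i.d. uniform excitations and record the free foot.

    Excitations are drawn uniformly from [0, noise_amplitude] per muscle per
    control step ("pure white noise").  The default amplitude 0.3 keeps the
    limb below joint-range saturation: at full amplitude every morphology is
    driven stop-to-stop and coverage measures range geometry instead of
    dynamics (a ceiling effect).  Episodes that diverge numerically
    are truncated at the last valid sample and counted.  Deterministic for
    a given seed.
    """
    if constraints is None:
        constraints = toy_constraints(free_leg)
    model = compile_model(spec, constraints)
    sim = PlanarBiped(model, substeps=substeps)
    rng = np.random.default_rng(seed)
    scales = spec.hof_scales()
    foot = model.body_index(f"foot_{free_leg[0]}")
    hip_dof = f"hip_{free_leg[0]}"

    pos_chunks: List[np.ndarray] = []
    vel_chunks: List[np.ndarray] = []
    truncated = 0
    nm = model.n_muscles
    for _ in range(n_episodes):
        sim.reset(jitter_deg=0.0)
        # hip anchor is stationary (pelvis fixed): locate it once per episode
        hip = _hip_position(sim, model, hip_dof)
        u_all = rng.uniform(0.0, noise_amplitude, size=(steps_per_episode, nm))
        pos = np.empty((steps_per_episode, 2))
        vel = np.empty((steps_per_episode, 2))
        k = 0
        try:
            for t in range(steps_per_episode):
                sim.step(u_all[t])
                pos[k] = sim._com[foot] - hip
                vel[k] = sim._vcom[foot]
                k += 1
        except SimulationDiverged:
            truncated += 1
        pos_chunks.append(pos[:k] / scales.length)
        vel_chunks.append(vel[:k] / scales.velocity)

    return RolloutSeries(
        position=np.concatenate(pos_chunks, axis=0),
        velocity=np.concatenate(vel_chunks, axis=0),
        n_episodes=n_episodes,
        steps_per_episode=steps_per_episode,
        truncated_episodes=truncated,
    )


def _hip_position(sim: PlanarBiped, model: CompiledModel, hip_dof: str) -> np.ndarray:
    # the thigh frame origin is the hip joint; with the pelvis fixed and the
    # base unrotated it sits at base position + reference offset
    from morphocurl._geometry import reference_origins

    thigh = model.dof_body[model.dof_index(hip_dof)]
    origins = reference_origins(model.spec)
    return np.array([sim.q[0], sim.q[1]]) + origins[model.body_names[thigh]]


def _hull_area(samples: np.ndarray) -> float:
    uniq = np.unique(samples, axis=0)
    if uniq.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(uniq).volume)
    except QhullError:
        return 0.0


def workspace_coverage(
    series: RolloutSeries,
    grid_resolution: int = DEFAULT_GRID,
    position_bounds: Tuple[float, float] = POSITION_BOUNDS,
    velocity_bounds: Tuple[float, float] = VELOCITY_BOUNDS,
) -> CoverageResult:
    """Occupancy fractions on a fixed normalized grid plus convex-hull areas.

    The grid is identical for every morphology, so occupancy fractions are
    directly comparable across stages; samples outside the bounds are
    ignored for occupancy but still contribute to the hulls.
    """
    if series.position.shape[0] == 0:
        raise ValueError("empty series")

    def occupancy(samples: np.ndarray, bounds: Tuple[float, float]) -> float:
        H, _, _ = np.histogram2d(
            samples[:, 0], samples[:, 1],
            bins=grid_resolution, range=(bounds, bounds),
        )
        return float((H > 0).sum() / H.size)

    return CoverageResult(
        occupancy_fraction_position=occupancy(series.position, position_bounds),
        occupancy_fraction_velocity=occupancy(series.velocity, velocity_bounds),
        hull_area_position=_hull_area(series.position),
        hull_area_velocity=_hull_area(series.velocity),
        n_samples=int(series.position.shape[0]),
    )


# ---------------------------------------------------------------------------
# DEP baseline


@dataclass
class DEPState:
    """State of the differential-extrinsic-plasticity rule.

    ``C`` is the (n x n) control matrix, ``tau`` the learning time constant,
    ``delta_t`` the sensor delay, and ``buffer`` holds past muscle-length
    velocities so the lagged term is available.
    """

    C: np.ndarray
    tau: float
    delta_t: float
    dt: float
    buffer: List[np.ndarray] = field(default_factory=list)

    @property
    def lag_steps(self) -> int:
        return max(1, int(round(self.delta_t / self.dt)))


def dep_init(n_muscles: int, tau: float = 0.04, delta_t: float = 0.01, dt: float = 0.01) -> DEPState:
    return DEPState(C=np.zeros((n_muscles, n_muscles)), tau=tau, delta_t=delta_t, dt=dt)


def dep_update(state: DEPState, ldot_t: np.ndarray, dt: Optional[float] = None) -> DEPState:
    """Euler step of tau * dC/dt = ldot_t ldot_{t-dt}^T - C.

    Requires enough buffered history to form the lagged outer product.
    """
    dt = state.dt if dt is None else dt
    ldot_t = np.asarray(ldot_t, dtype=float)
    lag = state.lag_steps
    if len(state.buffer) < lag:
        state.buffer.append(ldot_t.copy())
        raise ValueError(
            f"insufficient history: need {lag} past samples, have {len(state.buffer) - 1}"
        )
    ldot_lag = state.buffer[-lag]
    target = np.outer(ldot_t, ldot_lag)
    state.C = state.C + (dt / state.tau) * (target - state.C)
    state.buffer.append(ldot_t.copy())
    if len(state.buffer) > lag + 1:
        state.buffer.pop(0)
    return state


def dep_action(
    state: DEPState,
    ldot: np.ndarray,
    gain: float = 10.0,
    bias: Union[float, np.ndarray] = 0.0,
) -> np.ndarray:
    """Read the control matrix out onto muscle excitations in [0, 1].

    The current velocity signal is direction-normalized (invariant to
    positive rescaling), mapped through C, squashed by a logistic sigmoid
    with the given gain, and clipped.
    """
    ldot = np.asarray(ldot, dtype=float)
    norm = np.linalg.norm(ldot)
    x = ldot / norm if norm > 0 else ldot
    z = gain * (state.C @ x) + bias
    return np.clip(1.0 / (1.0 + np.exp(-z)), 0.0, 1.0)
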