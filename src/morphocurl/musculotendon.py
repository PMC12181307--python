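"""Hill-type muscle-tendon dynamics: activation low-pass and force generation.

The muscle is a phenomenological Hill model with a rigid tendon: fiber length
is the straight-line path length minus tendon slack, so no internal muscle
ODE besides activation is integrated.  Active force is the product of a
Gaussian force-length curve (peak at normalized length 1), a hyperbolic
force-velocity curve (1 at zero velocity, 0 at maximal shortening, eccentric
plateau at 1.5), and activation; an exponential passive element engages
beyond optimal length.  Muscles only pull: total force is clamped at zero.

Activation follows a first-order low-pass of the neural excitation with
asymmetric time constants (default tau_act = 10 ms, tau_deact = 40 ms,
standard biomechanics values), integrated exactly per control step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

# Hill curve shape constants (documented defaults; see docs/methods.md)
FL_WIDTH = 0.45          # Gaussian width of the active force-length curve
FV_MAX_NORM = 10.0       # maximal shortening velocity, optimal fiber lengths / s
FV_CURVATURE = 0.25      # hyperbola curvature of the concentric branch
FV_ECC_PLATEAU = 1.5     # eccentric force plateau
PE_STRAIN = 0.6          # passive strain at which passive force reaches F_max
PE_SHAPE = 4.0           # passive exponential shape factor


@dataclass
class MuscleState:
    """Instantaneous state of one muscle-tendon unit."""

    activation: float
    fiber_length: float
    fiber_velocity: float
    force: float


def activation_step(
    a: ArrayLike, u: ArrayLike, dt: float, tau_act: ArrayLike, tau_deact: ArrayLike
) -> ArrayLike:
    """Advance activation toward excitation ``u`` over ``dt``.

    First-order dynamics da/dt = (u - a)/tau with tau = tau_act while
    excitation exceeds activation and tau_deact otherwise, integrated with
    the exact exponential step ``a' = u + (a - u) exp(-dt/tau)``; output is
    clipped to [0, 1].  The map is a contraction: |a' - u| <= |a - u|.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = np.asarray(a, dtype=float)
    u = np.asarray(u, dtype=float)
    tau = np.where(u > a, tau_act, tau_deact)
    out = u + (a - u) * np.exp(-dt / tau)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def force_length(lnorm: ArrayLike) -> ArrayLike:
    """Active force-length curve: Gaussian with peak 1 at lnorm = 1."""
    lnorm = np.asarray(lnorm, dtype=float)
    out = np.exp(-(((lnorm - 1.0) / FL_WIDTH) ** 2))
    return float(out) if out.ndim == 0 else out


def force_velocity(vnorm: ArrayLike) -> ArrayLike:
    """Force-velocity curve over normalized fiber velocity (lengthening > 0).

    ``vnorm`` is fiber velocity in optimal fiber lengths per second divided
    by the maximal shortening velocity, clamped to [-1, 1].  Returns 0 at
    maximal shortening, 1 isometrically, and saturates toward the eccentric
    plateau when lengthening.  The eccentric hyperbola is slope-matched to
    the concentric branch at v = 0 (C1 continuity), which also keeps the
    effective small-motion damping finite and integrator-friendly.
    """
    v = np.clip(np.asarray(vnorm, dtype=float), -1.0, 1.0)
    v_neg = np.minimum(v, 0.0)  # concentric branch only ever sees v <= 0
    conc = (1.0 + v_neg) / (1.0 - v_neg / FV_CURVATURE)
    # concentric slope at 0 is 1 + 1/FV_CURVATURE = 5; eccentric
    # 1.5 - 0.5/(1 + c v) has slope 0.5 c at 0, so c = 10 matches
    ecc_c = (1.0 + 1.0 / FV_CURVATURE) / (FV_ECC_PLATEAU - 1.0)
    ecc = FV_ECC_PLATEAU - (FV_ECC_PLATEAU - 1.0) / (1.0 + ecc_c * v)
    out = np.where(v < 0.0, conc, ecc)
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def passive_force(lnorm: ArrayLike) -> ArrayLike:
    """Exponential parallel-elastic force, zero at/below optimal length."""
    lnorm = np.asarray(lnorm, dtype=float)
    strain = np.maximum(lnorm - 1.0, 0.0)
    out = (np.exp(PE_SHAPE * strain / PE_STRAIN) - 1.0) / (np.exp(PE_SHAPE) - 1.0)
    return float(out) if out.ndim == 0 else out


def muscle_force(
    a: ArrayLike,
    normalized_fiber_length: ArrayLike,
    normalized_fiber_velocity: ArrayLike,
    F_max: ArrayLike,
    *,
    include_passive: bool = True,
) -> ArrayLike:
    """Total tensile force F_max * (a * f_L * f_V + f_passive), >= 0."""
    F_max = np.asarray(F_max, dtype=float)
    if np.any(F_max <= 0):
        raise ValueError("F_max must be > 0")
    active = (
        np.asarray(a, dtype=float)
        * force_length(normalized_fiber_length)
        * force_velocity(normalized_fiber_velocity)
    )
    total = active
    if include_passive:
        total = total + passive_force(normalized_fiber_length)
    out = np.maximum(F_max * total, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def muscle_sensors(state: MuscleState, scales) -> tuple:
    """Hof-normalized (length, velocity, force) triplet for observations."""
    from morphocurl.hofnorm import hof_normalize

    return (
        hof_normalize(state.fiber_length, "length", scales),
        hof_normalize(state.fiber_velocity, "velocity", scales),
        hof_normalize(state.force, "force", scales),
    )
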