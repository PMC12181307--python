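"""Ontogenetic and uniform body scaling between developmental stages.

Two ways of producing a child body from the adult:

* **uniform** — every segment length is multiplied by a single height ratio
  and the adult's per-segment mass *fractions* are kept, so only overall size
  and mass change;
* **ontogenetic** — each segment gets its own length ratio and the mass
  distribution is replaced by an age-specific fraction table (young children
  carry proportionally heavier torsos and lighter legs).

Both modes redistribute a prescribed target total mass, rescale moments of
inertia as ``I * (m_new/m_old) * (L_new/L_old)**2``, shorten muscle optimal
fiber and tendon slack lengths with the length of the path they span, and
scale maximal isometric muscle forces with body weight so that the
Hof-normalized force ``F/(m g)`` is stage-invariant.  Contact and joint-stop
stiffnesses keep their dimensionless values (``k l0/(m g)`` for
translational, ``k/(m g l0)`` for torsional), and velocity-bearing damping
coefficients keep theirs, so a passively settling child body traces the same
normalized trajectory as the adult — the operational meaning of dynamic
similarity.  Target velocities scale with the square root of the leg-length
ratio (equal Froude number ``v**2/(g l0)``).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import yaml

from morphocurl._geometry import muscle_path_length, standing_leg_length
from morphocurl.morphology import (
    MorphologySpec,
    MuscleSpec,
    validate_morphology,
)


@dataclass
class ScalingLaw:
    """Parameters of one adult-to-child scaling step.

    ``height_ratio`` drives uniform mode; ``per_segment_length_ratio`` and
    ``mass_fraction_table`` drive ontogenetic mode.  ``force_length_exponent``
    optionally multiplies F_max by (leg-length ratio)**exponent on top of the
    default weight-proportional scaling (0 keeps F/(m g) invariant).
    """

    mode: str  # "ontogenetic" | "uniform"
    target_total_mass: float
    stage: str = ""
    height_ratio: Optional[float] = None
    per_segment_length_ratio: Optional[Dict[str, float]] = None
    mass_fraction_table: Optional[Dict[str, float]] = None
    force_length_exponent: float = 0.0
    constant_absolute_stiffness: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("ontogenetic", "uniform"):
            raise ValueError(f"mode must be ontogenetic|uniform, got {self.mode!r}")
        if not self.target_total_mass > 0:
            raise ValueError("target_total_mass must be > 0")
        if self.mode == "uniform":
            if self.height_ratio is None or not 0 < self.height_ratio <= 1:
                raise ValueError("uniform mode needs height_ratio in (0, 1]")
        else:
            if not self.per_segment_length_ratio or not self.mass_fraction_table:
                raise ValueError(
                    "ontogenetic mode needs per_segment_length_ratio and mass_fraction_table"
                )
            for name, r in self.per_segment_length_ratio.items():
                if not 0 < r <= 1:
                    raise ValueError(f"length ratio for {name!r} must be in (0, 1], got {r}")
            total = sum(self.mass_fraction_table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mass fractions must sum to 1 (tol 1e-9), got {total}")


def load_scaling_law(path) -> ScalingLaw:
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return ScalingLaw(
        mode=doc["mode"],
        target_total_mass=float(doc["target_total_mass"]),
        stage=str(doc.get("stage", "")),
        height_ratio=float(doc["height_ratio"]) if "height_ratio" in doc else None,
        per_segment_length_ratio=doc.get("per_segment_length_ratio"),
        mass_fraction_table=doc.get("mass_fraction_table"),
        force_length_exponent=float(doc.get("force_length_exponent", 0.0)),
        constant_absolute_stiffness=bool(doc.get("constant_absolute_stiffness", False)),
    )


def bundled_scaling_law(stage: str) -> ScalingLaw:
    """Load a shipped law: onto4y, uni4y, onto12y, or uni12y."""
    ref = resources.files("morphocurl.data") / f"law_{stage}.yaml"
    with resources.as_file(ref) as p:
        return load_scaling_law(p)


# ---------------------------------------------------------------------------
# elementary scaling rules


def scale_stiffness(
    k_adult: float, m_ratio: float, l_ratio: float, *, constant_absolute: bool = False
) -> float:
    """Translational stiffness preserving dimensionless k*l0/(m*g).

    ``k_new = k_adult * m_ratio / l_ratio``; with ``constant_absolute`` the
    adult value is returned unchanged.
    """
    if not (m_ratio > 0 and l_ratio > 0):
        raise ValueError("ratios must be > 0")
    if constant_absolute:
        return float(k_adult)
    return float(k_adult * m_ratio / l_ratio)


def scale_torsional_stiffness(
    k_adult: float, m_ratio: float, l_ratio: float, *, constant_absolute: bool = False
) -> float:
    """Torsional stiffness (N m/rad) preserving dimensionless k/(m*g*l0)."""
    if constant_absolute:
        return float(k_adult)
    return float(k_adult * m_ratio * l_ratio)


def scale_target_velocity(v_adult: float, leg_length_ratio: float) -> float:
    """Froude-preserving velocity: ``v_child = v_adult * sqrt(l)``."""
    if not leg_length_ratio > 0:
        raise ValueError("leg_length_ratio must be > 0")
    return float(v_adult * math.sqrt(leg_length_ratio))


def scale_muscles(
    adult_muscles: Sequence[MuscleSpec],
    length_ratio_of_spanned_path: Union[float, Dict[str, float]],
    mass_ratio: float,
    length_scale_ratio: float = 1.0,
    *,
    force_length_exponent: float = 0.0,
) -> List[MuscleSpec]:
    """Scale muscle-tendon parameters for a resized body.

    Optimal fiber length and tendon slack length shrink with the length of
    the spanned path (scalar, or per-muscle mapping); maximal isometric force
    scales with ``mass_ratio`` (times an optional power of the overall length
    ratio), keeping the Hof-normalized force F/(m g) invariant by default.
    Activation/deactivation time constants are chemistry, not geometry, and
    stay untouched.
    """
    if not mass_ratio > 0 or not length_scale_ratio > 0:
        raise ValueError("ratios must be > 0")
    force_factor = mass_ratio * length_scale_ratio**force_length_exponent
    out: List[MuscleSpec] = []
    for m in adult_muscles:
        if isinstance(length_ratio_of_spanned_path, dict):
            lr = length_ratio_of_spanned_path[m.name]
        else:
            lr = float(length_ratio_of_spanned_path)
        if not lr > 0:
            raise ValueError(f"path length ratio for {m.name!r} must be > 0")
        scaled = copy.deepcopy(m)
        scaled.optimal_fiber_length = m.optimal_fiber_length * lr
        scaled.tendon_slack_length = m.tendon_slack_length * lr
        scaled.max_isometric_force = m.max_isometric_force * force_factor
        out.append(scaled)
    return out


# ---------------------------------------------------------------------------
# whole-body scaling


def _segment_ratio(law: ScalingLaw, name: str) -> float:
    if law.mode == "uniform":
        return float(law.height_ratio)
    table = law.per_segment_length_ratio
    assert table is not None
    if name not in table:
        raise ValueError(f"per_segment_length_ratio missing segment {name!r}")
    return float(table[name])


def _mass_fraction(law: ScalingLaw, adult: MorphologySpec, name: str) -> float:
    if law.mode == "uniform":
        return adult.segment(name).mass / adult.total_mass
    table = law.mass_fraction_table
    assert table is not None
    if name not in table:
        raise ValueError(f"mass_fraction_table missing segment {name!r}")
    return float(table[name])


def _apply_law(adult: MorphologySpec, law: ScalingLaw) -> MorphologySpec:
    spec = copy.deepcopy(adult)
    spec.stage = law.stage or adult.stage
    m_ratio = law.target_total_mass / adult.total_mass

    # geometry: lengths, COMs, attachment points scale with the owning
    # segment's ratio; joint anchors with the parent segment's ratio
    ratio = {s.name: _segment_ratio(law, s.name) for s in adult.segments}
    for s in spec.segments:
        r = ratio[s.name]
        old_mass = adult.segment(s.name).mass
        new_mass = law.target_total_mass * _mass_fraction(law, adult, s.name)
        s.length *= r
        s.com_offset *= r
        s.axis = tuple(s.axis)
        if s.com_point is not None:
            s.com_point = (s.com_point[0] * r, s.com_point[1] * r)
        seg_m_ratio = new_mass / old_mass if old_mass > 0 else m_ratio
        s.moment_of_inertia *= seg_m_ratio * r * r
        s.mass = new_mass
    for j in spec.joints:
        r = ratio[j.parent]
        j.parent_anchor = (j.parent_anchor[0] * r, j.parent_anchor[1] * r)
    for m in spec.muscles:
        for p in m.path:
            r = ratio[p.segment]
            p.point = (p.point[0] * r, p.point[1] * r)
    for c in spec.contacts:
        r = ratio[c.segment]
        c.location = (c.location[0] * r, c.location[1] * r)

    spec.leg_length = standing_leg_length(spec)
    l_ratio = spec.leg_length / adult.leg_length
    spec.total_mass = float(sum(s.mass for s in spec.segments))

    # muscle-tendon parameters follow the spanned path length in the
    # reference posture, forces follow body weight
    path_ratio = {
        m.name: muscle_path_length(spec, m.name) / muscle_path_length(adult, m.name)
        for m in adult.muscles
    }
    spec.muscles = scale_muscles(
        spec.muscles,
        path_ratio,
        m_ratio,
        l_ratio,
        force_length_exponent=law.force_length_exponent,
    )

    # stiffness/damping keep their dimensionless values
    sqrt_l = math.sqrt(l_ratio)
    for c in spec.contacts:
        c.stiffness = scale_stiffness(
            c.stiffness, m_ratio, l_ratio, constant_absolute=law.constant_absolute_stiffness
        )
        if not law.constant_absolute_stiffness:
            c.damping = c.damping / sqrt_l  # c_d (s/m) ~ 1/velocity scale
            c.mu_viscous = c.mu_viscous / sqrt_l
            c.friction_vreg = c.friction_vreg * sqrt_l  # m/s ~ velocity scale
    for j in spec.joints:
        j.limit_stiffness = scale_torsional_stiffness(
            j.limit_stiffness, m_ratio, l_ratio,
            constant_absolute=law.constant_absolute_stiffness,
        )
        if not law.constant_absolute_stiffness:
            # N m s/rad: torque scale (m g l0) times time scale sqrt(l0/g)
            j.limit_damping *= m_ratio * l_ratio * sqrt_l
            j.damping *= m_ratio * l_ratio * sqrt_l

    validate_morphology(spec)
    return spec


def scale_uniform(adult: MorphologySpec, law: ScalingLaw) -> MorphologySpec:
    """Uniformly scaled body: common length ratio, adult mass distribution."""
    if law.mode != "uniform":
        raise ValueError(f"scale_uniform needs a uniform-mode law, got {law.mode!r}")
    return _apply_law(adult, law)


def scale_ontogenetic(adult: MorphologySpec, law: ScalingLaw) -> MorphologySpec:
    """Ontogenetically scaled body: per-segment ratios, age-specific masses."""
    if law.mode != "ontogenetic":
        raise ValueError(f"scale_ontogenetic needs an ontogenetic-mode law, got {law.mode!r}")
    return _apply_law(adult, law)


def scale_morphology(adult: MorphologySpec, law: ScalingLaw) -> MorphologySpec:
    """Dispatch on ``law.mode``."""
    if law.mode == "uniform":
        return scale_uniform(adult, law)
    return scale_ontogenetic(adult, law)
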