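"""Morphology configurations: domain types, validation, YAML I/O, summaries.

A morphology file fully describes one planar sagittal musculoskeletal body at
one developmental stage: rigid segments, the joints connecting them, Hill-type
muscle-tendon units routed as straight-line paths with optional via points,
and spherical ground-contact points on the feet.

Conventions
-----------
* SI units throughout; planar frame: x forward, y up, rotations about z.
* Each body frame's origin sits at its proximal joint (the floating-base
  pelvis frame sits at the pelvis center).  All points (muscle attachments,
  contact locations, joint anchors, COM) are expressed in the body frame at
  the reference standing posture, in which every joint coordinate is zero.
* Left/right bookkeeping is by name suffix: segments, joints, and muscles of
  the left leg end in ``_l``, the right leg in ``_r``.
* The bundled adult body carries eleven muscles per leg; the two
  frontal-plane muscles (adductor, abductor) are planar placeholders with
  small sagittal moment arms and can be disabled for constrained setups.

The on-disk format is a single YAML document per morphology with a versioned
``schema_version`` key; see the bundled fixtures under ``morphocurl/data``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

SCHEMA_VERSION = 1

STAGES = ("adult", "onto4y", "uni4y", "onto12y", "uni12y")


class MorphologyError(ValueError):
    """Raised when a morphology file cannot be parsed or fails validation."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("morphology validation failed:\n  " + "\n  ".join(self.problems))


@dataclass
class SegmentSpec:
    """One rigid body segment.

    ``axis`` is the unit direction of the segment's long axis in the
    reference posture; the COM sits at ``com_offset`` metres along it from
    the frame origin unless an explicit 2-D ``com_point`` is given (used for
    the feet, whose COM is off-axis).
    """

    name: str
    length: float
    mass: float
    moment_of_inertia: float
    com_offset: float
    parent_joint: Optional[str]
    axis: Tuple[float, float] = (0.0, -1.0)
    com_point: Optional[Tuple[float, float]] = None

    def com(self) -> np.ndarray:
        if self.com_point is not None:
            return np.asarray(self.com_point, dtype=float)
        return self.com_offset * np.asarray(self.axis, dtype=float)


@dataclass
class JointSpec:
    """Connection between two segments.

    ``parent_anchor`` locates the joint in the parent frame (reference
    posture).  ``joint_type`` is ``revolute`` or ``fixed`` (weld).  Revolute
    joints carry a soft range-of-motion stop (torsional spring-damper engaged
    beyond ``range_rad``) and light in-range viscous damping.
    """

    name: str
    parent: str
    child: str
    parent_anchor: Tuple[float, float]
    joint_type: str = "revolute"
    range_rad: Tuple[float, float] = (-math.pi, math.pi)
    limit_stiffness: float = 1000.0
    limit_damping: float = 20.0
    damping: float = 1.0


@dataclass
class MusclePathPoint:
    segment: str
    point: Tuple[float, float]


@dataclass
class MuscleSpec:
    """Hill-type muscle-tendon unit routed along straight path segments.

    ``path`` lists origin, optional via points, and insertion.  The tendon is
    rigid by default, so fiber length is path length minus tendon slack.
    """

    name: str
    path: List[MusclePathPoint]
    optimal_fiber_length: float
    tendon_slack_length: float
    max_isometric_force: float
    activation_time_constant: float = 0.01
    deactivation_time_constant: float = 0.04

    @property
    def origin(self) -> MusclePathPoint:
        return self.path[0]

    @property
    def insertion(self) -> MusclePathPoint:
        return self.path[-1]


@dataclass
class ContactSpec:
    """Spherical (point) ground contact with Hunt-Crossley normal force.

    ``damping`` is the dimensionless multiplier ``c_d`` of the dissipative
    term ``k * d^p * (1 + c_d * d_dot)``; friction is a regularized Coulomb
    cone with static/dynamic coefficients plus a viscous term (s/m).
    """

    segment: str
    location: Tuple[float, float]
    stiffness: float
    damping: float = 1.0
    mu_static: float = 0.9
    mu_dynamic: float = 0.8
    mu_viscous: float = 0.6
    friction_vreg: float = 0.01  # m/s, tanh regularization of Coulomb friction


@dataclass
class MorphologySpec:
    """Full parametric description of one body at one developmental stage."""

    stage: str
    segments: List[SegmentSpec]
    joints: List[JointSpec]
    muscles: List[MuscleSpec]
    contacts: List[ContactSpec]
    total_mass: float
    leg_length: float
    gravity: float = 9.81
    schema_version: int = SCHEMA_VERSION

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"no segment named {name!r}")

    def muscle(self, name: str) -> MuscleSpec:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"no muscle named {name!r}")

    def muscles_per_leg(self) -> Dict[str, int]:
        counts = {"l": 0, "r": 0}
        for m in self.muscles:
            if m.name.endswith("_l"):
                counts["l"] += 1
            elif m.name.endswith("_r"):
                counts["r"] += 1
        return counts

    def contacts_per_foot(self) -> Dict[str, int]:
        counts = {"foot_l": 0, "foot_r": 0}
        for c in self.contacts:
            if c.segment in counts:
                counts[c.segment] += 1
        return counts

    def hof_scales(self):
        from morphocurl.hofnorm import HofScales

        return HofScales(m=self.total_mass, g=self.gravity, l0=self.leg_length)


# ---------------------------------------------------------------------------
# validation


def _finite(x) -> bool:
    try:
        return math.isfinite(float(x))
    except (TypeError, ValueError):
        return False


def validate_morphology(spec: MorphologySpec) -> None:
    """Check every invariant; raise :class:`MorphologyError` listing failures."""
    problems: List[str] = []

    if spec.stage not in STAGES:
        problems.append(f"stage: {spec.stage!r} not one of {STAGES}")
    if not (_finite(spec.total_mass) and spec.total_mass > 0):
        problems.append(f"total_mass: must be finite and > 0, got {spec.total_mass!r}")
    if not (_finite(spec.leg_length) and spec.leg_length > 0):
        problems.append(f"leg_length: must be finite and > 0, got {spec.leg_length!r}")
    if not (_finite(spec.gravity) and spec.gravity > 0):
        problems.append(f"gravity: must be finite and > 0, got {spec.gravity!r}")

    seg_names = set()
    for i, s in enumerate(spec.segments):
        where = f"segments[{i}] ({s.name})"
        if s.name in seg_names:
            problems.append(f"{where}.name: duplicate")
        seg_names.add(s.name)
        if not (_finite(s.length) and s.length > 0):
            problems.append(f"{where}.length: must be > 0, got {s.length!r}")
        if not (_finite(s.mass) and s.mass >= 0):
            problems.append(f"{where}.mass: must be >= 0, got {s.mass!r}")
        if not (_finite(s.moment_of_inertia) and s.moment_of_inertia >= 0):
            problems.append(f"{where}.moment_of_inertia: must be >= 0, got {s.moment_of_inertia!r}")

    if all(_finite(s.mass) for s in spec.segments) and _finite(spec.total_mass):
        msum = sum(float(s.mass) for s in spec.segments)
        if abs(msum - spec.total_mass) > 1e-9:
            problems.append(
                f"total_mass: {spec.total_mass!r} != sum of segment masses {msum!r} (tol 1e-9)"
            )

    joint_names = set()
    for i, j in enumerate(spec.joints):
        where = f"joints[{i}] ({j.name})"
        joint_names.add(j.name)
        if j.joint_type not in ("revolute", "fixed"):
            problems.append(f"{where}.joint_type: {j.joint_type!r} not revolute|fixed")
        for ref in (j.parent, j.child):
            if ref not in seg_names:
                problems.append(f"{where}: unknown segment {ref!r}")
        if j.joint_type == "revolute" and not j.range_rad[0] <= j.range_rad[1]:
            problems.append(f"{where}.range_rad: lower bound exceeds upper")

    for i, s in enumerate(spec.segments):
        if s.parent_joint is not None and s.parent_joint not in joint_names:
            problems.append(f"segments[{i}] ({s.name}).parent_joint: unknown joint {s.parent_joint!r}")

    for i, m in enumerate(spec.muscles):
        where = f"muscles[{i}] ({m.name})"
        if len(m.path) < 2:
            problems.append(f"{where}.path: needs origin and insertion")
        for k, p in enumerate(m.path):
            if p.segment not in seg_names:
                problems.append(f"{where}.path[{k}].segment: unknown segment {p.segment!r}")
        if len(m.path) >= 2 and m.path[0].segment == m.path[-1].segment:
            problems.append(f"{where}: origin and insertion on same segment (spans no joint)")
        for fname in (
            "optimal_fiber_length",
            "tendon_slack_length",
            "max_isometric_force",
            "activation_time_constant",
            "deactivation_time_constant",
        ):
            v = getattr(m, fname)
            if not (_finite(v) and v > 0):
                problems.append(f"{where}.{fname}: must be > 0, got {v!r}")

    for i, c in enumerate(spec.contacts):
        where = f"contacts[{i}] ({c.segment})"
        if c.segment not in seg_names:
            problems.append(f"{where}.segment: unknown segment {c.segment!r}")
        if not (_finite(c.stiffness) and c.stiffness > 0):
            problems.append(f"{where}.stiffness: must be > 0, got {c.stiffness!r}")
        if not (_finite(c.damping) and c.damping >= 0):
            problems.append(f"{where}.damping: must be >= 0, got {c.damping!r}")
        if not c.mu_static >= c.mu_dynamic >= 0:
            problems.append(f"{where}: requires mu_static >= mu_dynamic >= 0")

    counts = spec.muscles_per_leg()
    if counts["l"] != counts["r"]:
        problems.append(f"muscles: left leg has {counts['l']} muscles, right {counts['r']}")
    for foot, n in spec.contacts_per_foot().items():
        if {s.name for s in spec.segments} >= {foot} and n != 3:
            problems.append(f"contacts: {foot} has {n} contact points, expected exactly 3")

    if problems:
        raise MorphologyError(problems)


# ---------------------------------------------------------------------------
# YAML I/O


def _tup(x) -> Tuple[float, float]:
    return (float(x[0]), float(x[1]))


def _spec_from_dict(doc: dict, source: str = "<dict>") -> MorphologySpec:
    problems: List[str] = []
    if not isinstance(doc, dict):
        raise MorphologyError([f"{source}: top level must be a mapping"])
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise MorphologyError(
            [f"schema_version: expected {SCHEMA_VERSION}, got {version!r}"]
        )

    def need(d: dict, key: str, where: str):
        if key not in d:
            problems.append(f"{where}.{key}: missing")
            return None
        return d[key]

    segments = []
    for i, s in enumerate(doc.get("segments", [])):
        where = f"segments[{i}]"
        try:
            segments.append(
                SegmentSpec(
                    name=str(need(s, "name", where)),
                    length=float(need(s, "length", where)),
                    mass=float(need(s, "mass", where)),
                    moment_of_inertia=float(need(s, "moment_of_inertia", where)),
                    com_offset=float(s.get("com_offset", 0.0)),
                    parent_joint=s.get("parent_joint"),
                    axis=_tup(s.get("axis", (0.0, -1.0))),
                    com_point=_tup(s["com_point"]) if s.get("com_point") is not None else None,
                )
            )
        except (TypeError, ValueError) as e:
            problems.append(f"{where}: {e}")

    joints = []
    for i, j in enumerate(doc.get("joints", [])):
        where = f"joints[{i}]"
        try:
            joints.append(
                JointSpec(
                    name=str(need(j, "name", where)),
                    parent=str(need(j, "parent", where)),
                    child=str(need(j, "child", where)),
                    parent_anchor=_tup(need(j, "parent_anchor", where)),
                    joint_type=str(j.get("joint_type", "revolute")),
                    range_rad=_tup(j.get("range_rad", (-math.pi, math.pi))),
                    limit_stiffness=float(j.get("limit_stiffness", 1000.0)),
                    limit_damping=float(j.get("limit_damping", 20.0)),
                    damping=float(j.get("damping", 1.0)),
                )
            )
        except (TypeError, ValueError) as e:
            problems.append(f"{where}: {e}")

    muscles = []
    for i, m in enumerate(doc.get("muscles", [])):
        where = f"muscles[{i}]"
        try:
            path = [
                MusclePathPoint(segment=str(p["segment"]), point=_tup(p["point"]))
                for p in need(m, "path", where) or []
            ]
            muscles.append(
                MuscleSpec(
                    name=str(need(m, "name", where)),
                    path=path,
                    optimal_fiber_length=float(need(m, "optimal_fiber_length", where)),
                    tendon_slack_length=float(need(m, "tendon_slack_length", where)),
                    max_isometric_force=float(need(m, "max_isometric_force", where)),
                    activation_time_constant=float(m.get("activation_time_constant", 0.01)),
                    deactivation_time_constant=float(m.get("deactivation_time_constant", 0.04)),
                )
            )
        except (TypeError, ValueError, KeyError) as e:
            problems.append(f"{where}: {e}")

    contacts = []
    for i, c in enumerate(doc.get("contacts", [])):
        where = f"contacts[{i}]"
        try:
            contacts.append(
                ContactSpec(
                    segment=str(need(c, "segment", where)),
                    location=_tup(need(c, "location", where)),
                    stiffness=float(need(c, "stiffness", where)),
                    damping=float(c.get("damping", 1.0)),
                    mu_static=float(c.get("mu_static", 0.9)),
                    mu_dynamic=float(c.get("mu_dynamic", 0.8)),
                    mu_viscous=float(c.get("mu_viscous", 0.6)),
                    friction_vreg=float(c.get("friction_vreg", 0.01)),
                )
            )
        except (TypeError, ValueError) as e:
            problems.append(f"{where}: {e}")

    if problems:
        raise MorphologyError(problems)

    spec = MorphologySpec(
        stage=str(doc.get("stage", "")),
        segments=segments,
        joints=joints,
        muscles=muscles,
        contacts=contacts,
        total_mass=float(doc.get("total_mass", float("nan"))),
        leg_length=float(doc.get("leg_length", float("nan"))),
        gravity=float(doc.get("gravity", 9.81)),
        schema_version=int(version),
    )
    validate_morphology(spec)
    return spec


def _spec_to_dict(spec: MorphologySpec) -> dict:
    doc = {
        "schema_version": spec.schema_version,
        "stage": spec.stage,
        "gravity": spec.gravity,
        "total_mass": spec.total_mass,
        "leg_length": spec.leg_length,
        "segments": [],
        "joints": [],
        "muscles": [],
        "contacts": [],
    }
    for s in spec.segments:
        d = {
            "name": s.name,
            "length": s.length,
            "mass": s.mass,
            "moment_of_inertia": s.moment_of_inertia,
            "com_offset": s.com_offset,
            "parent_joint": s.parent_joint,
            "axis": list(s.axis),
        }
        if s.com_point is not None:
            d["com_point"] = list(s.com_point)
        doc["segments"].append(d)
    for j in spec.joints:
        doc["joints"].append(
            {
                "name": j.name,
                "parent": j.parent,
                "child": j.child,
                "parent_anchor": list(j.parent_anchor),
                "joint_type": j.joint_type,
                "range_rad": list(j.range_rad),
                "limit_stiffness": j.limit_stiffness,
                "limit_damping": j.limit_damping,
                "damping": j.damping,
            }
        )
    for m in spec.muscles:
        doc["muscles"].append(
            {
                "name": m.name,
                "path": [{"segment": p.segment, "point": list(p.point)} for p in m.path],
                "optimal_fiber_length": m.optimal_fiber_length,
                "tendon_slack_length": m.tendon_slack_length,
                "max_isometric_force": m.max_isometric_force,
                "activation_time_constant": m.activation_time_constant,
                "deactivation_time_constant": m.deactivation_time_constant,
            }
        )
    for c in spec.contacts:
        doc["contacts"].append(
            {
                "segment": c.segment,
                "location": list(c.location),
                "stiffness": c.stiffness,
                "damping": c.damping,
                "mu_static": c.mu_static,
                "mu_dynamic": c.mu_dynamic,
                "mu_viscous": c.mu_viscous,
                "friction_vreg": c.friction_vreg,
            }
        )
    return doc


def load_morphology(path) -> MorphologySpec:
    """Load and validate a morphology YAML file."""
    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise MorphologyError([f"{path}: YAML parse error: {e}"]) from e
    return _spec_from_dict(doc, source=str(path))


def write_morphology(spec: MorphologySpec, path) -> None:
    """Validate ``spec`` and write it as YAML; refuses to write invalid specs."""
    validate_morphology(spec)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False, default_flow_style=None)


def bundled_morphology(stage: str) -> MorphologySpec:
    """Load one of the shipped fixtures: adult, onto4y, uni4y, onto12y, uni12y."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    ref = resources.files("morphocurl.data") / f"{stage}.yaml"
    with resources.as_file(ref) as p:
        return load_morphology(p)


# ---------------------------------------------------------------------------
# summaries


def summarize_morphology(spec: MorphologySpec, reference: MorphologySpec) -> pd.DataFrame:
    """Per-segment mass fractions and length ratios against a reference body.

    Returns a DataFrame indexed by segment name with columns
    ``mass``, ``mass_fraction``, ``ref_mass_fraction``, ``length``,
    ``length_ratio`` (spec length / reference length).
    """
    names = [s.name for s in spec.segments]
    ref_names = [s.name for s in reference.segments]
    if set(names) != set(ref_names):
        only_spec = sorted(set(names) - set(ref_names))
        only_ref = sorted(set(ref_names) - set(names))
        raise ValueError(
            f"segment sets differ: only in spec {only_spec}, only in reference {only_ref}"
        )
    ref_by_name = {s.name: s for s in reference.segments}
    rows = []
    for s in spec.segments:
        r = ref_by_name[s.name]
        rows.append(
            {
                "segment": s.name,
                "mass": s.mass,
                "mass_fraction": s.mass / spec.total_mass,
                "ref_mass_fraction": r.mass / reference.total_mass,
                "length": s.length,
                "length_ratio": s.length / r.length,
            }
        )
    df = pd.DataFrame(rows).set_index("segment")
    assert abs(df["mass_fraction"].sum() - 1.0) < 1e-9
    return df
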