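"""Regenerate the bundled morphology fixtures and scaling-law files.

The adult planar biped is defined here from standard adult anthropometry
(1.80 m, 75 kg; segment masses and radii of gyration from classic gait
tables), with eleven muscles per leg (nine sagittal actuators plus planar
placeholder adductor/abductor).  Tendon slack lengths are chosen so each
muscle sits at optimal fiber length in the reference standing posture.  The
child fixtures are produced by the package's own scaling module from the
bundled anthropometric law files, so the shipped YAML is exactly what
``scale_uniform`` / ``scale_ontogenetic`` emit.

Run from the repository root:  python scripts/make_fixtures.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from morphocurl._geometry import muscle_path_length, standing_leg_length
from morphocurl.morphology import (
    ContactSpec,
    JointSpec,
    MorphologySpec,
    MusclePathPoint,
    MuscleSpec,
    SegmentSpec,
    write_morphology,
)
from morphocurl.scaling import load_scaling_law, scale_morphology

DATA = Path(__file__).resolve().parents[1] / "src" / "morphocurl" / "data"

GRAVITY = 9.81
ADULT_MASS = 75.0

# name -> (length, mass, inertia_coefficient I = c*m*L^2, axis, com_offset, com_point)
SEGMENTS = {
    "pelvis": (0.18, 10.65, 0.10, (0.0, 1.0), 0.0, None),
    "torso": (0.60, 40.20, 0.12, (0.0, 1.0), 0.33, None),
    "thigh": (0.441, 7.50, 0.104, (0.0, -1.0), 0.191, None),
    "shank": (0.443, 3.4875, 0.104, (0.0, -1.0), 0.192, None),
    "foot": (0.26, 1.0875, 0.06, (1.0, 0.0), 0.05, (0.05, -0.033)),
}

# Hips sit behind the body axis (humans stand with the ankle behind the COM
# line), which keeps the flat-foot center of pressure over the body COM.
HIP_ANCHOR = (-0.05, -0.09)    # in pelvis frame
LUMBAR_ANCHOR = (0.0, 0.09)
KNEE_ANCHOR = (0.0, -0.441)    # in thigh frame
ANKLE_ANCHOR = (0.0, -0.443)   # in shank frame

JOINT_RANGES = {  # rad, soft stops
    "hip": (-0.35, 2.09),
    "knee": (-2.30, 0.035),
    "ankle": (-0.90, 0.60),
}

# name -> (path [(segment, point)...], l_opt, F_max); pelvis attachment x
# values are expressed relative to the hip and shifted below.
#
# Maximal forces are chosen for agonist-antagonist torque balance at the
# reference posture under uniform activation (hip and knee net torque ~ 0,
# ankle moderately plantar-biased), preserving the over-actuated structure
# of the human leg rather than copying per-muscle human strengths.  An
# unbalanced set pins the unloaded limb against its joint stops, which
# degenerates both exploration and control.
MUSCLES = {
    "iliopsoas": ([("pelvis", (0.05, -0.02)), ("thigh", (0.02, -0.10))], 0.10, 2000.0),
    "glutmax": ([("pelvis", (-0.06, 0.00)), ("thigh", (-0.02, -0.12))], 0.15, 1500.0),
    "hamstrings": ([("pelvis", (-0.06, -0.02)), ("shank", (-0.03, -0.05))], 0.11, 1200.0),
    "rectfem": (
        [("pelvis", (0.04, -0.03)), ("thigh", (0.04, -0.40)), ("shank", (0.04, -0.06))],
        0.08,
        1400.0,
    ),
    "vasti": (
        [("thigh", (0.03, -0.15)), ("thigh", (0.045, -0.42)), ("shank", (0.04, -0.06))],
        0.09,
        1500.0,
    ),
    "bfsh": ([("thigh", (-0.025, -0.20)), ("shank", (-0.03, -0.05))], 0.12, 900.0),
    "gastroc": ([("thigh", (-0.03, -0.40)), ("foot", (-0.05, -0.03))], 0.06, 1800.0),
    "soleus": ([("shank", (-0.025, -0.10)), ("foot", (-0.05, -0.03))], 0.05, 1500.0),
    "tibant": (
        [("shank", (0.025, -0.18)), ("shank", (0.02, -0.40)), ("foot", (0.05, -0.005))],
        0.06,
        2200.0,
    ),
    # frontal-plane placeholders with small sagittal moment arms
    "adductor": ([("pelvis", (0.02, -0.10)), ("thigh", (0.01, -0.18))], 0.10, 1000.0),
    "abductor": ([("pelvis", (-0.03, -0.06)), ("thigh", (-0.01, -0.08))], 0.08, 1500.0),
}

CONTACT_POINTS = [(-0.05, -0.066), (0.12, -0.066), (0.19, -0.066)]  # heel + 2 forefoot
CONTACT_STIFFNESS = 11006.4
CONTACT_DAMPING = 1.0

LAWS = {
    "law_uni4y.yaml": {
        "mode": "uniform",
        "stage": "uni4y",
        "height_ratio": 0.572,
        "target_total_mass": 16.5,
    },
    "law_onto4y.yaml": {
        "mode": "ontogenetic",
        "stage": "onto4y",
        "target_total_mass": 16.5,
        "per_segment_length_ratio": {
            "torso": 0.62,
            "pelvis": 0.58,
            "thigh_l": 0.52,
            "thigh_r": 0.52,
            "shank_l": 0.52,
            "shank_r": 0.52,
            "foot_l": 0.58,
            "foot_r": 0.58,
        },
        "mass_fraction_table": {
            "torso": 0.585,
            "pelvis": 0.145,
            "thigh_l": 0.082,
            "thigh_r": 0.082,
            "shank_l": 0.040,
            "shank_r": 0.040,
            "foot_l": 0.013,
            "foot_r": 0.013,
        },
    },
    "law_uni12y.yaml": {
        "mode": "uniform",
        "stage": "uni12y",
        "height_ratio": 0.828,
        "target_total_mass": 40.0,
    },
    "law_onto12y.yaml": {
        "mode": "ontogenetic",
        "stage": "onto12y",
        "target_total_mass": 40.0,
        "per_segment_length_ratio": {
            "torso": 0.84,
            "pelvis": 0.80,
            "thigh_l": 0.81,
            "thigh_r": 0.81,
            "shank_l": 0.81,
            "shank_r": 0.81,
            "foot_l": 0.82,
            "foot_r": 0.82,
        },
        "mass_fraction_table": {
            "torso": 0.555,
            "pelvis": 0.143,
            "thigh_l": 0.094,
            "thigh_r": 0.094,
            "shank_l": 0.044,
            "shank_r": 0.044,
            "foot_l": 0.013,
            "foot_r": 0.013,
        },
    },
}


def build_adult() -> MorphologySpec:
    segments = []
    for name in ("pelvis", "torso"):
        L, m, c, axis, off, cp = SEGMENTS[name]
        segments.append(
            SegmentSpec(
                name=name,
                length=L,
                mass=m,
                moment_of_inertia=round(c * m * L * L, 6),
                com_offset=off,
                parent_joint=None if name == "pelvis" else "lumbar",
                axis=axis,
                com_point=cp,
            )
        )
    for side in ("l", "r"):
        for base in ("thigh", "shank", "foot"):
            L, m, c, axis, off, cp = SEGMENTS[base]
            parent_joint = {"thigh": "hip", "shank": "knee", "foot": "ankle"}[base]
            segments.append(
                SegmentSpec(
                    name=f"{base}_{side}",
                    length=L,
                    mass=m,
                    moment_of_inertia=round(c * m * L * L, 6),
                    com_offset=off,
                    parent_joint=f"{parent_joint}_{side}",
                    axis=axis,
                    com_point=cp,
                )
            )

    joints = [
        JointSpec(
            name="lumbar", parent="pelvis", child="torso",
            parent_anchor=LUMBAR_ANCHOR, joint_type="fixed",
        )
    ]
    for side in ("l", "r"):
        joints += [
            JointSpec(
                name=f"hip_{side}", parent="pelvis", child=f"thigh_{side}",
                parent_anchor=HIP_ANCHOR, range_rad=JOINT_RANGES["hip"],
            ),
            JointSpec(
                name=f"knee_{side}", parent=f"thigh_{side}", child=f"shank_{side}",
                parent_anchor=KNEE_ANCHOR, range_rad=JOINT_RANGES["knee"],
            ),
            JointSpec(
                name=f"ankle_{side}", parent=f"shank_{side}", child=f"foot_{side}",
                parent_anchor=ANKLE_ANCHOR, range_rad=JOINT_RANGES["ankle"],
            ),
        ]

    muscles = []
    for side in ("l", "r"):
        for name, (path, l_opt, f_max) in MUSCLES.items():
            pts = [
                MusclePathPoint(
                    segment=seg if seg in ("pelvis", "torso") else f"{seg}_{side}",
                    point=(pt[0] + HIP_ANCHOR[0], pt[1]) if seg == "pelvis" else pt,
                )
                for seg, pt in path
            ]
            muscles.append(
                MuscleSpec(
                    name=f"{name}_{side}",
                    path=pts,
                    optimal_fiber_length=l_opt,
                    tendon_slack_length=1.0,  # placeholder, fixed below
                    max_isometric_force=f_max,
                )
            )

    contacts = [
        ContactSpec(
            segment=f"foot_{side}",
            location=pt,
            stiffness=CONTACT_STIFFNESS,
            damping=CONTACT_DAMPING,
        )
        for side in ("l", "r")
        for pt in CONTACT_POINTS
    ]

    spec = MorphologySpec(
        stage="adult",
        segments=segments,
        joints=joints,
        muscles=muscles,
        contacts=contacts,
        total_mass=ADULT_MASS,
        leg_length=1.0,  # placeholder, fixed below
        gravity=GRAVITY,
    )
    spec.leg_length = round(standing_leg_length(spec), 6)
    # rigid tendon: slack so the fiber is at optimal length when standing
    for m in spec.muscles:
        L_ref = muscle_path_length(spec, m.name)
        m.tendon_slack_length = round(L_ref - m.optimal_fiber_length, 6)
    return spec


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    adult = build_adult()
    write_morphology(adult, DATA / "adult.yaml")
    print(f"adult: mass {adult.total_mass} kg, leg length {adult.leg_length} m")

    for fname, doc in LAWS.items():
        with (DATA / fname).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)

    for stage in ("uni4y", "onto4y", "uni12y", "onto12y"):
        law = load_scaling_law(DATA / f"law_{stage}.yaml")
        child = scale_morphology(adult, law)
        write_morphology(child, DATA / f"{stage}.yaml")
        print(f"{stage}: mass {child.total_mass} kg, leg length {child.leg_length:.4f} m")


if __name__ == "__main__":
    main()
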