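"""Reference-posture kinematics shared by scaling, fixtures, and the simulator.

In the reference (quiet standing) posture every joint coordinate is zero and
all body frames are axis-aligned, so world positions are plain translations:
a body's origin is its parent's origin plus the joint anchor, and any local
point maps to origin + point.  The pelvis (floating base) origin is placed at
(0, 0); the simulator later shifts the base so the feet rest on the ground.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from morphocurl.morphology import MorphologySpec


def body_order(spec: MorphologySpec) -> List[str]:
    """Segments ordered parent-before-child (the floating base first)."""
    parent_of: Dict[str, str] = {}
    for j in spec.joints:
        parent_of[j.child] = j.parent
    roots = [s.name for s in spec.segments if s.name not in parent_of]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root segment, found {roots}")
    order = [roots[0]]
    remaining = {s.name for s in spec.segments} - {roots[0]}
    while remaining:
        progressed = False
        for name in list(remaining):
            if parent_of.get(name) in order:
                order.append(name)
                remaining.discard(name)
                progressed = True
        if not progressed:
            raise ValueError(f"segments not reachable from root: {sorted(remaining)}")
    return order


def reference_origins(spec: MorphologySpec) -> Dict[str, np.ndarray]:
    """World origin of every body frame in the reference posture (pelvis at 0,0)."""
    joint_by_child = {j.child: j for j in spec.joints}
    origins: Dict[str, np.ndarray] = {}
    for name in body_order(spec):
        if name not in joint_by_child:
            origins[name] = np.zeros(2)
        else:
            j = joint_by_child[name]
            origins[name] = origins[j.parent] + np.asarray(j.parent_anchor, dtype=float)
    return origins


def reference_point(spec: MorphologySpec, segment: str, point) -> np.ndarray:
    return reference_origins(spec)[segment] + np.asarray(point, dtype=float)


def muscle_path_length(spec: MorphologySpec, muscle_name: str) -> float:
    """Straight-line path length of a muscle in the reference posture."""
    origins = reference_origins(spec)
    m = spec.muscle(muscle_name)
    pts = [origins[p.segment] + np.asarray(p.point, dtype=float) for p in m.path]
    return float(sum(np.linalg.norm(b - a) for a, b in zip(pts[:-1], pts[1:])))


def standing_leg_length(spec: MorphologySpec) -> float:
    """Hip-to-ground distance l0 in the reference posture.

    Measured from the left hip joint down to the lowest contact point.
    """
    origins = reference_origins(spec)
    hip = None
    for j in spec.joints:
        if j.name in ("hip_l", "hip"):
            hip = origins[j.parent] + np.asarray(j.parent_anchor, dtype=float)
    if hip is None:
        raise ValueError("no hip joint (hip_l) found")
    ground = min(
        origins[c.segment][1] + c.location[1] for c in spec.contacts
    )
    return float(hip[1] - ground)
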