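import math

import numpy as np
import pytest

from morphocurl.morphology import (
    ContactSpec,
    JointSpec,
    MorphologySpec,
    SegmentSpec,
    bundled_morphology,
)


@pytest.fixture(scope="session")
def adult_spec():
    return bundled_morphology("adult")


@pytest.fixture(scope="session")
def onto4y_spec():
    return bundled_morphology("onto4y")


@pytest.fixture(scope="session")
def uni4y_spec():
    return bundled_morphology("uni4y")


@pytest.fixture(scope="session")
def adult_model(adult_spec):
    from morphocurl.dynamics import compile_model

    return compile_model(adult_spec)


STATUE_JOINTS = ("hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r")


@pytest.fixture(scope="session")
def standing_frame_model(adult_spec):
    """Adult locked upright in a frame: only vertical motion remains."""
    from morphocurl.dynamics import Constraints, compile_model

    return compile_model(
        adult_spec,
        Constraints(fix_joints=("base_x", "base_rot") + STATUE_JOINTS),
    )


def single_rod_spec(
    length: float = 1.0,
    mass: float = 1.0,
    joint_damping: float = 0.0,
) -> MorphologySpec:
    """A single rod hanging from a revolute joint on a fixed base.

    COM mid-rod, slender-rod inertia; joint stops out of reach.  Used for
    the analytic physical-pendulum period check.
    """
    base = SegmentSpec(
        name="pelvis", length=0.1, mass=1.0, moment_of_inertia=0.01,
        com_offset=0.0, parent_joint=None,
    )
    rod = SegmentSpec(
        name="torso", length=length, mass=mass,
        moment_of_inertia=mass * length**2 / 12.0,
        com_offset=length / 2.0, parent_joint="lumbar", axis=(0.0, -1.0),
    )
    joint = JointSpec(
        name="lumbar", parent="pelvis", child="torso", parent_anchor=(0.0, 0.0),
        range_rad=(-math.pi, math.pi), limit_stiffness=0.0, limit_damping=0.0,
        damping=joint_damping,
    )
    return MorphologySpec(
        stage="adult", segments=[base, rod], joints=[joint], muscles=[],
        contacts=[], total_mass=base.mass + mass, leg_length=length,
    )
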