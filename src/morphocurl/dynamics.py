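"""Planar articulated rigid-body simulation of the muscle-actuated biped.

The simulator advances a kinematic tree (floating-base pelvis, welded
head-torso, two three-segment legs) in generalized coordinates with
semi-implicit Euler and physics substeps (default 10 substeps per 10 ms
control period — stiff ground contact, k ~ 1.1e4 N/m, needs the shorter
step).  Muscles are Hill-type path actuators with rigid tendons; ground
contact is a Hunt-Crossley normal force with a regularized Coulomb +
viscous friction cone; joints carry soft range stops.

Rollouts are pure functions of (model, initial state, excitation sequence):
no internal randomness.  Constrained setups (fixed pelvis, immobilized leg,
disabled muscles) reuse the same model with coordinates removed from the
integration, which is how the exploration toy experiment is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from morphocurl import _kernel
from morphocurl._geometry import body_order
from morphocurl.morphology import ContactSpec, MorphologySpec
from morphocurl.musculotendon import MuscleState

DEFAULT_DT = 0.01          # control period: 100 Hz
DEFAULT_SUBSTEPS = 10
DEFAULT_HORIZON = 1000     # steps per episode = 10 s
FALL_HEIGHT_FRACTION = 0.6
FALL_PITCH_MAX = math.radians(60.0)
HUNT_CROSSLEY_EXPONENT = 1.0


class SimulationDiverged(RuntimeError):
    """Raised when the state stops being finite; carries the last valid state."""

    def __init__(self, last_state):
        super().__init__("simulation diverged to non-finite state")
        self.last_state = last_state


@dataclass
class Constraints:
    """Optional mechanical constraints for reduced setups."""

    fix_pelvis: bool = False
    immobilize_leg: Optional[str] = None  # "left" | "right"
    disable_muscles: Sequence[str] = ()
    fix_joints: Sequence[str] = ()


@dataclass
class SimState:
    """Instantaneous mechanical + muscle state."""

    generalized_positions: np.ndarray
    generalized_velocities: np.ndarray
    muscle_states: List[MuscleState]
    time: float
    env_step: int


@dataclass
class ContactForce:
    point: np.ndarray
    normal_force: float
    tangential_force: float
    penetration: float


def contact_force(
    penetration: float,
    penetration_rate: float,
    tangential_speed: float,
    params: ContactSpec,
    exponent: float = HUNT_CROSSLEY_EXPONENT,
) -> ContactForce:
    """Hunt-Crossley normal force plus regularized friction-cone tangential.

    normal = max(0, k * d**p * (1 + c_d * d_dot)); the tangential force is
    dynamic Coulomb friction regularized by tanh plus a viscous term, capped
    by the cone mu_static*N + mu_viscous*|v_t|*N.
    """
    if penetration <= 0.0:
        return ContactForce(np.zeros(2), 0.0, 0.0, penetration)
    N = params.stiffness * penetration**exponent * (1.0 + params.damping * penetration_rate)
    N = max(N, 0.0)
    Ft = -N * params.mu_dynamic * math.tanh(tangential_speed / params.friction_vreg)
    Ft += -N * params.mu_viscous * tangential_speed
    cap = params.mu_static * N + params.mu_viscous * abs(tangential_speed) * N
    Ft = min(max(Ft, -cap), cap)
    return ContactForce(np.zeros(2), N, Ft, penetration)


# ---------------------------------------------------------------------------
# model compilation


@dataclass
class CompiledModel:
    """Flat-array form of a morphology, ready for the numba kernel."""

    spec: MorphologySpec
    body_names: List[str]
    dof_names: List[str]
    parent: np.ndarray
    jtype: np.ndarray
    dof_of_body: np.ndarray
    anchor: np.ndarray
    com_l: np.ndarray
    mass: np.ndarray
    inertia: np.ndarray
    affects: np.ndarray
    dof_body: np.ndarray
    aptr: np.ndarray
    adofs: np.ndarray
    free: np.ndarray
    qmin: np.ndarray
    qmax: np.ndarray
    klim: np.ndarray
    dlim: np.ndarray
    djnt: np.ndarray
    dof_is_rev: np.ndarray
    mptr: np.ndarray
    mbody: np.ndarray
    mpt: np.ndarray
    lopt: np.ndarray
    lslack: np.ndarray
    fmax: np.ndarray
    menabled: np.ndarray
    tau_act: np.ndarray
    tau_deact: np.ndarray
    cbody: np.ndarray
    cpt: np.ndarray
    cfoot: np.ndarray
    ck: np.ndarray
    ccd: np.ndarray
    cmus: np.ndarray
    cmud: np.ndarray
    cmuv: np.ndarray
    cvreg: np.ndarray
    cexp: np.ndarray
    muscle_names: List[str] = field(default_factory=list)
    base_standing_y: float = 0.0

    @property
    def n_dof(self) -> int:
        return len(self.dof_names)

    @property
    def n_muscles(self) -> int:
        return len(self.muscle_names)

    def body_index(self, name: str) -> int:
        return self.body_names.index(name)

    def dof_index(self, name: str) -> int:
        return self.dof_names.index(name)


_LEG_JOINTS = {"left": ("hip_l", "knee_l", "ankle_l"), "right": ("hip_r", "knee_r", "ankle_r")}
FRONTAL_MUSCLES = ("adductor_l", "abductor_l", "adductor_r", "abductor_r")


def apply_constraints(model: CompiledModel, constraints: Constraints) -> CompiledModel:
    """Return a copy with constrained DOFs frozen and muscles disabled."""
    free = model.free.copy()
    menabled = model.menabled.copy()
    if constraints.fix_pelvis:
        free[0] = free[1] = free[2] = False
    if constraints.immobilize_leg is not None:
        if constraints.immobilize_leg not in _LEG_JOINTS:
            raise ValueError(f"immobilize_leg must be left|right, got {constraints.immobilize_leg!r}")
        for jname in _LEG_JOINTS[constraints.immobilize_leg]:
            free[model.dof_index(jname)] = False
    for jname in constraints.fix_joints:
        if jname not in model.dof_names:
            raise ValueError(f"unknown joint {jname!r}")
        free[model.dof_index(jname)] = False
    for mname in constraints.disable_muscles:
        if mname not in model.muscle_names:
            raise ValueError(f"unknown muscle {mname!r}")
        menabled[model.muscle_names.index(mname)] = 0
    return replace(model, free=free, menabled=menabled)


def compile_model(
    spec: MorphologySpec, constraints: Optional[Constraints] = None
) -> CompiledModel:
    """Flatten a validated morphology into kernel arrays."""
    names = body_order(spec)
    idx = {n: i for i, n in enumerate(names)}
    joint_by_child = {j.child: j for j in spec.joints}

    nb = len(names)
    parent = np.full(nb, -1, dtype=np.int64)
    jtype = np.zeros(nb, dtype=np.int64)
    anchor = np.zeros((nb, 2))
    dof_names = ["base_x", "base_y", "base_rot"]
    dof_of_body = np.full(nb, -1, dtype=np.int64)
    rev_rows = []  # (dof index, joint spec)

    for i, name in enumerate(names):
        if name not in joint_by_child:
            continue
        j = joint_by_child[name]
        parent[i] = idx[j.parent]
        anchor[i] = j.parent_anchor
        if j.joint_type == "revolute":
            jtype[i] = 1
            dof_of_body[i] = len(dof_names)
            rev_rows.append((len(dof_names), j))
            dof_names.append(j.name)
        else:
            jtype[i] = 2

    n = len(dof_names)
    com_l = np.array([spec.segment(nm).com() for nm in names])
    mass = np.array([spec.segment(nm).mass for nm in names])
    inertia = np.array([spec.segment(nm).moment_of_inertia for nm in names])

    affects = np.zeros((nb, n), dtype=np.int64)
    affects[:, :3] = 1  # floating base moves everything
    for d, j in rev_rows:
        child = idx[j.child]
        for i in range(nb):
            k = i
            while k >= 0:
                if k == child:
                    affects[i, d] = 1
                    break
                k = parent[k]
    dof_body = np.zeros(n, dtype=np.int64)
    for d, j in rev_rows:
        dof_body[d] = idx[j.child]

    # CSR lists of the dofs that actually move each body (for kernel speed)
    aptr = [0]
    adofs: List[int] = []
    for i in range(nb):
        for d in range(n):
            if affects[i, d]:
                adofs.append(d)
        aptr.append(len(adofs))

    qmin = np.full(n, -np.inf)
    qmax = np.full(n, np.inf)
    klim = np.zeros(n)
    dlim = np.zeros(n)
    djnt = np.zeros(n)
    dof_is_rev = np.zeros(n, dtype=np.int64)
    for d, j in rev_rows:
        qmin[d], qmax[d] = j.range_rad
        klim[d] = j.limit_stiffness
        dlim[d] = j.limit_damping
        djnt[d] = j.damping
        dof_is_rev[d] = 1

    muscle_names = [m.name for m in spec.muscles]
    mptr = [0]
    mbody: List[int] = []
    mpt: List[Tuple[float, float]] = []
    for m in spec.muscles:
        for p in m.path:
            mbody.append(idx[p.segment])
            mpt.append(p.point)
        mptr.append(len(mbody))
    lopt = np.array([m.optimal_fiber_length for m in spec.muscles])
    lslack = np.array([m.tendon_slack_length for m in spec.muscles])
    fmax = np.array([m.max_isometric_force for m in spec.muscles])
    tau_act = np.array([m.activation_time_constant for m in spec.muscles])
    tau_deact = np.array([m.deactivation_time_constant for m in spec.muscles])

    cbody = np.array([idx[c.segment] for c in spec.contacts], dtype=np.int64)
    cpt = np.array([c.location for c in spec.contacts]) if spec.contacts else np.zeros((0, 2))
    cfoot = np.array(
        [1 if c.segment.endswith("_r") else 0 for c in spec.contacts], dtype=np.int64
    )
    ck = np.array([c.stiffness for c in spec.contacts])
    ccd = np.array([c.damping for c in spec.contacts])
    cmus = np.array([c.mu_static for c in spec.contacts])
    cmud = np.array([c.mu_dynamic for c in spec.contacts])
    cmuv = np.array([c.mu_viscous for c in spec.contacts])
    cvreg = np.array([c.friction_vreg for c in spec.contacts])
    cexp = np.full(len(spec.contacts), HUNT_CROSSLEY_EXPONENT)

    # standing base height: lowest contact point exactly on the ground
    from morphocurl._geometry import reference_origins

    origins = reference_origins(spec)
    if spec.contacts:
        lowest = min(origins[c.segment][1] + c.location[1] for c in spec.contacts)
    else:
        lowest = 0.0
    base_standing_y = -lowest

    model = CompiledModel(
        spec=spec,
        body_names=names,
        dof_names=dof_names,
        parent=parent,
        jtype=jtype,
        dof_of_body=dof_of_body,
        anchor=anchor,
        com_l=com_l,
        mass=mass,
        inertia=inertia,
        affects=affects,
        dof_body=dof_body,
        aptr=np.array(aptr, dtype=np.int64),
        adofs=np.array(adofs, dtype=np.int64),
        free=np.ones(n, dtype=np.bool_),
        qmin=qmin,
        qmax=qmax,
        klim=klim,
        dlim=dlim,
        djnt=djnt,
        dof_is_rev=dof_is_rev,
        mptr=np.array(mptr, dtype=np.int64),
        mbody=np.array(mbody, dtype=np.int64),
        mpt=np.array(mpt) if mpt else np.zeros((0, 2)),
        lopt=lopt,
        lslack=lslack,
        fmax=fmax,
        menabled=np.ones(len(spec.muscles), dtype=np.int64),
        tau_act=tau_act,
        tau_deact=tau_deact,
        cbody=cbody,
        cpt=cpt,
        cfoot=cfoot,
        ck=ck,
        ccd=ccd,
        cmus=cmus,
        cmud=cmud,
        cmuv=cmuv,
        cvreg=cvreg,
        cexp=cexp,
        muscle_names=muscle_names,
        base_standing_y=base_standing_y,
    )
    if constraints is not None:
        model = apply_constraints(model, constraints)
    return model


# ---------------------------------------------------------------------------
# simulator


@dataclass
class StepDiagnostics:
    """Per-control-step sensor readings (SI units, world frame)."""

    muscle_lengths: np.ndarray
    muscle_velocities: np.ndarray
    muscle_forces: np.ndarray
    body_com: np.ndarray
    body_vcom: np.ndarray
    body_angles: np.ndarray
    body_omegas: np.ndarray
    grf: np.ndarray  # (left, right) vertical


class PlanarBiped:
    """Stepped simulation of one compiled model at a fixed control rate."""

    def __init__(
        self,
        model: CompiledModel,
        dt: float = DEFAULT_DT,
        substeps: int = DEFAULT_SUBSTEPS,
    ):
        self.model = model
        self.dt = float(dt)
        self.substeps = int(substeps)
        n, nb, nm = model.n_dof, len(model.body_names), model.n_muscles
        self.q = np.zeros(n)
        self.v = np.zeros(n)
        self.act = np.zeros(nm)
        self.time = 0.0
        self.env_step = 0
        self._mlen = np.zeros(nm)
        self._mvel = np.zeros(nm)
        self._mforce = np.zeros(nm)
        self._grf = np.zeros(2)
        self._com = np.zeros((nb, 2))
        self._vcom = np.zeros((nb, 2))
        self._ang = np.zeros(nb)
        self._w = np.zeros(nb)
        self._torso = model.body_index("torso") if "torso" in model.body_names else 0

    def reset(
        self,
        rng: Optional[np.random.Generator] = None,
        jitter_deg: float = 0.5,
        q: Optional[np.ndarray] = None,
        v: Optional[np.ndarray] = None,
    ) -> SimState:
        """Standing posture with small seeded joint-angle jitter (sigma 0.5 deg).

        The base is lowered by the static contact penetration so the start
        is preloaded rather than bouncing on first contact.
        """
        m = self.model
        self.q[:] = 0.0
        self.v[:] = 0.0
        self.q[1] = m.base_standing_y
        if m.ck.size > 0:
            self.q[1] -= m.mass.sum() * m.spec.gravity / m.ck.sum()
        if q is not None:
            self.q[:] = q
        elif rng is not None and jitter_deg > 0:
            jitter = rng.normal(0.0, math.radians(jitter_deg), m.n_dof - 3)
            self.q[3:] += jitter * m.free[3:]
        if v is not None:
            self.v[:] = v
        self.v[~m.free] = 0.0
        self.act[:] = 0.0
        self.time = 0.0
        self.env_step = 0
        self._refresh_diagnostics()
        return self.state()

    def _refresh_diagnostics(self) -> None:
        # zero-duration kinematics pass: run with dt=0 is not supported by the
        # kernel, so evaluate via a tiny no-op step on copies
        q, v, act = self.q.copy(), self.v.copy(), self.act.copy()
        self._kernel_step(q, v, act, np.zeros(self.model.n_muscles), 1e-12, 1)

    def _kernel_step(self, q, v, act, u, dt, nsub, fext=(0.0, 0.0), fext_body=-1):
        m = self.model
        _kernel.control_step(
            q, v, act, np.asarray(u, dtype=float), dt, nsub, m.spec.gravity,
            m.parent, m.jtype, m.dof_of_body, m.anchor, m.com_l, m.mass, m.inertia,
            m.affects, m.dof_body, m.aptr, m.adofs, m.free,
            m.qmin, m.qmax, m.klim, m.dlim, m.djnt, m.dof_is_rev,
            m.mptr, m.mbody, m.mpt, m.lopt, m.lslack, m.fmax, m.menabled,
            m.tau_act, m.tau_deact,
            m.cbody, m.cpt, m.cfoot, m.ck, m.ccd, m.cmus, m.cmud, m.cmuv, m.cvreg, m.cexp,
            np.asarray(fext, dtype=float), fext_body,
            self._mlen, self._mvel, self._mforce, self._grf,
            self._com, self._vcom, self._ang, self._w,
        )

    def step(
        self,
        excitations: np.ndarray,
        ext_force: Tuple[float, float] = (0.0, 0.0),
    ) -> Tuple[SimState, StepDiagnostics]:
        """Advance one control period under the given muscle excitations."""
        u = np.asarray(excitations, dtype=float)
        if u.shape != (self.model.n_muscles,):
            raise ValueError(
                f"expected {self.model.n_muscles} excitations, got shape {u.shape}"
            )
        fext_body = self._torso if (ext_force[0] != 0.0 or ext_force[1] != 0.0) else -1
        try:
            self._kernel_step(
                self.q, self.v, self.act, u, self.dt, self.substeps, ext_force, fext_body
            )
        except np.linalg.LinAlgError as e:
            raise SimulationDiverged(self.state()) from e
        self.time += self.dt
        self.env_step += 1
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.v))):
            raise SimulationDiverged(self.state())
        return self.state(), self.diagnostics()

    def state(self) -> SimState:
        muscle_states = [
            MuscleState(
                activation=float(self.act[i]),
                fiber_length=float(self._mlen[i] - self.model.lslack[i]),
                fiber_velocity=float(self._mvel[i]),
                force=float(self._mforce[i]),
            )
            for i in range(self.model.n_muscles)
        ]
        return SimState(
            generalized_positions=self.q.copy(),
            generalized_velocities=self.v.copy(),
            muscle_states=muscle_states,
            time=self.time,
            env_step=self.env_step,
        )

    def diagnostics(self) -> StepDiagnostics:
        return StepDiagnostics(
            muscle_lengths=self._mlen.copy(),
            muscle_velocities=self._mvel.copy(),
            muscle_forces=self._mforce.copy(),
            body_com=self._com.copy(),
            body_vcom=self._vcom.copy(),
            body_angles=self._ang.copy(),
            body_omegas=self._w.copy(),
            grf=self._grf.copy(),
        )

    # convenience sensors ---------------------------------------------------

    def torso_height(self) -> float:
        return float(self._com[self._torso, 1])

    def torso_pitch(self) -> float:
        return float(self._ang[self._torso])

    def com(self) -> np.ndarray:
        m = self.model
        return (self._com * m.mass[:, None]).sum(axis=0) / m.mass.sum()

    def com_velocity(self) -> np.ndarray:
        m = self.model
        return (self._vcom * m.mass[:, None]).sum(axis=0) / m.mass.sum()


def check_termination(
    sim: PlanarBiped,
    h_frac: float = FALL_HEIGHT_FRACTION,
    pitch_max: float = FALL_PITCH_MAX,
) -> str:
    """'fallen' iff torso COM drops below h_frac*l0 or |pitch| exceeds pitch_max."""
    l0 = sim.model.spec.leg_length
    if sim.torso_height() < h_frac * l0:
        return "fallen"
    if abs(sim.torso_pitch()) > pitch_max:
        return "fallen"
    return "continue"


def settle(sim: PlanarBiped, steps: int = 300, relax: float = 0.0) -> None:
    """Run passive (zero-excitation) steps to let contact reach equilibrium.

    With ``relax`` in (0, 1) velocities are scaled by ``1 - relax`` after
    every control step — a numerical relaxation that drains kinetic energy
    and converges to a static equilibrium when one exists.  ``relax = 0``
    is plain physics.
    """
    u = np.zeros(sim.model.n_muscles)
    for _ in range(steps):
        sim.step(u)
        if relax > 0.0:
            sim.v *= 1.0 - relax
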