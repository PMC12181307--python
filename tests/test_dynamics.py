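import math

import numpy as np
import pytest

from morphocurl.dynamics import (
    Constraints,
    PlanarBiped,
    apply_constraints,
    check_termination,
    compile_model,
    contact_force,
    settle,
)
from morphocurl.morphology import ContactSpec

from conftest import STATUE_JOINTS, single_rod_spec


class TestContactForce:
    def test_no_penetration_no_force(self):
        params = ContactSpec(segment="foot_l", location=(0, 0), stiffness=11006.4)
        out = contact_force(-0.01, 0.5, 0.2, params)
        assert out.normal_force == 0.0 and out.tangential_force == 0.0

    def test_static_normal_is_k_delta(self):
        params = ContactSpec(segment="foot_l", location=(0, 0), stiffness=11006.4)
        out = contact_force(0.004, 0.0, 0.0, params)
        assert out.normal_force == pytest.approx(11006.4 * 0.004, rel=1e-12)

    def test_continuity_at_zero_penetration(self):
        params = ContactSpec(segment="foot_l", location=(0, 0), stiffness=11006.4)
        assert contact_force(1e-12, 0.0, 0.0, params).normal_force < 1e-6

    def test_friction_cone_bound_random_sweep(self):
        params = ContactSpec(segment="foot_l", location=(0, 0), stiffness=11006.4)
        rng = np.random.default_rng(7)
        for _ in range(500):
            d, dd, vt = rng.uniform(0, 0.05), rng.uniform(-2, 2), rng.uniform(-3, 3)
            out = contact_force(d, dd, vt, params)
            cap = params.mu_static * out.normal_force + (
                params.mu_viscous * abs(vt) * out.normal_force
            )
            assert abs(out.tangential_force) <= cap + 1e-9
            assert out.normal_force >= 0.0


class TestStep:
    def test_static_equilibrium_settling(self, standing_frame_model, adult_spec):
        """At rest on the ground in a standing frame, contact statics hold the
        body: COM height moves < 1 mm over 100 further steps and the total
        vertical GRF carries exactly body weight."""
        sim = PlanarBiped(standing_frame_model)
        sim.reset(jitter_deg=0.0)
        settle(sim, 200)
        h0 = sim.com()[1]
        settle(sim, 100)
        assert abs(sim.com()[1] - h0) < 1e-3
        assert sim._grf.sum() == pytest.approx(
            adult_spec.total_mass * adult_spec.gravity, rel=1e-3
        )

    def test_ballistic_flight_parabola(self, adult_model):
        sim = PlanarBiped(adult_model)
        sim.reset(jitter_deg=0.0)
        sim.q[1] += 1.0  # airborne, no contact
        sim._refresh_diagnostics()
        y0 = sim.com()[1]
        u = np.zeros(adult_model.n_muscles)
        t = 0.0
        dt_sub = sim.dt / sim.substeps
        for _ in range(30):
            sim.step(u)
            t += sim.dt
            expected = y0 - 0.5 * 9.81 * t**2
            # semi-implicit Euler lags the parabola by g*dt_sub*t/2
            assert abs(sim.com()[1] - expected) <= 0.6 * 9.81 * dt_sub * t + 1e-9

    def test_bitwise_determinism(self, adult_spec):
        def run():
            sim = PlanarBiped(compile_model(adult_spec))
            sim.reset(jitter_deg=0.0)
            rng = np.random.default_rng(11)
            for _ in range(40):
                sim.step(rng.uniform(0, 1, sim.model.n_muscles))
            return sim.q.copy(), sim.v.copy()

        q1, v1 = run()
        q2, v2 = run()
        assert np.array_equal(q1, q2) and np.array_equal(v1, v2)

    def test_wrong_excitation_length_rejected(self, adult_model):
        sim = PlanarBiped(adult_model)
        sim.reset(jitter_deg=0.0)
        with pytest.raises(ValueError, match="excitations"):
            sim.step(np.zeros(3))

    def test_passive_drop_energy_bounded(self, adult_spec):
        """Total mechanical energy never exceeds its initial value during a
        passive drop (contact and joint damping only dissipate)."""
        model = compile_model(
            adult_spec, Constraints(fix_joints=STATUE_JOINTS)
        )
        sim = PlanarBiped(model)
        sim.reset(jitter_deg=0.0)
        sim.q[1] += 0.05
        sim._refresh_diagnostics()

        def energy():
            m = model.mass
            v2 = (sim._vcom**2).sum(axis=1)
            ke = 0.5 * (m * v2).sum() + 0.5 * (model.inertia * sim._w**2).sum()
            pe = (m * 9.81 * sim._com[:, 1]).sum()
            return ke + pe

        e0 = energy()
        u = np.zeros(model.n_muscles)
        for _ in range(150):
            sim.step(u)
            assert energy() <= e0 + 1e-6


def test_single_rod_pendulum_period():
    """Small-amplitude period matches the physical-pendulum formula to 1%."""
    spec = single_rod_spec(length=1.0, mass=1.0)
    model = compile_model(spec, Constraints(fix_pelvis=True))
    sim = PlanarBiped(model, substeps=10)
    sim.reset(jitter_deg=0.0)
    d = model.dof_index("lumbar")
    sim.q[d] = math.radians(2.0)
    sim._refresh_diagnostics()

    # crossings of the equilibrium from below, linearly interpolated
    crossings = []
    prev = sim.q[d]
    t = 0.0
    u = np.zeros(0)
    for _ in range(600):
        sim.step(u)
        t += sim.dt
        cur = sim.q[d]
        if prev < 0 <= cur:
            frac = -prev / (cur - prev)
            crossings.append(t - sim.dt + frac * sim.dt)
        prev = cur
    assert len(crossings) >= 3
    measured = (crossings[-1] - crossings[0]) / (len(crossings) - 1)
    I_pivot = 1.0 / 12.0 + 0.25  # rod about its end
    expected = 2 * math.pi * math.sqrt(I_pivot / (1.0 * 9.81 * 0.5))
    assert measured == pytest.approx(expected, rel=0.01)


class TestConstraints:
    def test_fixed_pelvis_stays_put(self, adult_spec):
        model = compile_model(adult_spec, Constraints(fix_pelvis=True))
        sim = PlanarBiped(model)
        sim.reset(jitter_deg=0.0)
        base0 = sim.q[:3].copy()
        rng = np.random.default_rng(0)
        for _ in range(50):
            sim.step(rng.uniform(0, 1, model.n_muscles))
        assert np.array_equal(sim.q[:3], base0)

    def test_immobilized_leg_angles_constant(self, adult_spec):
        model = compile_model(
            adult_spec, Constraints(fix_pelvis=True, immobilize_leg="right")
        )
        sim = PlanarBiped(model)
        sim.reset(jitter_deg=0.0)
        idx = [model.dof_index(j) for j in ("hip_r", "knee_r", "ankle_r")]
        q0 = sim.q[idx].copy()
        rng = np.random.default_rng(1)
        for _ in range(50):
            sim.step(rng.uniform(0, 1, model.n_muscles))
        assert np.array_equal(sim.q[idx], q0)

    def test_disabled_muscle_produces_no_force(self, adult_spec):
        model = compile_model(
            adult_spec, Constraints(disable_muscles=("vasti_l",))
        )
        sim = PlanarBiped(model)
        sim.reset(jitter_deg=0.0)
        i = model.muscle_names.index("vasti_l")
        for _ in range(20):
            sim.step(np.ones(model.n_muscles))
            assert sim._mforce[i] == 0.0

    def test_unknown_names_rejected(self, adult_model):
        with pytest.raises(ValueError, match="unknown muscle"):
            apply_constraints(adult_model, Constraints(disable_muscles=("psoas_q",)))
        with pytest.raises(ValueError, match="unknown joint"):
            apply_constraints(adult_model, Constraints(fix_joints=("elbow_l",)))


class TestTermination:
    def test_upright_continues(self, adult_model):
        sim = PlanarBiped(adult_model)
        sim.reset(jitter_deg=0.0)
        assert check_termination(sim) == "continue"

    def test_low_torso_is_fallen(self, adult_model):
        sim = PlanarBiped(adult_model)
        sim.reset(jitter_deg=0.0)
        sim.q[1] -= 1.0 * adult_model.spec.leg_length  # torso below 0.6 l0
        sim._refresh_diagnostics()
        assert check_termination(sim) == "fallen"

    def test_exact_pitch_boundary_continues(self, adult_model):
        sim = PlanarBiped(adult_model)
        sim.reset(jitter_deg=0.0)
        sim.q[2] = math.radians(60.0)
        sim.q[1] += 1.0  # keep torso height out of the fall band
        sim._refresh_diagnostics()
        assert check_termination(sim) == "continue"
        sim.q[2] = math.radians(60.0) + 1e-9
        sim._refresh_diagnostics()
        assert check_termination(sim) == "fallen"
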