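import copy
import math

import numpy as np
import pytest

from morphocurl.dynamics import PlanarBiped, compile_model
from morphocurl.hofnorm import froude_number
from morphocurl.morphology import bundled_morphology
from morphocurl.scaling import (
    ScalingLaw,
    bundled_scaling_law,
    scale_muscles,
    scale_ontogenetic,
    scale_stiffness,
    scale_target_velocity,
    scale_uniform,
)


def identity_uniform_law(adult):
    return ScalingLaw(mode="uniform", height_ratio=1.0, target_total_mass=adult.total_mass)


class TestUniform:
    def test_identity_law_reproduces_adult(self, adult_spec):
        out = scale_uniform(adult_spec, identity_uniform_law(adult_spec))
        for a, b in zip(adult_spec.segments, out.segments):
            assert abs(a.length - b.length) < 1e-12
            assert abs(a.mass - b.mass) < 1e-12
            assert abs(a.moment_of_inertia - b.moment_of_inertia) < 1e-12
        for a, b in zip(adult_spec.muscles, out.muscles):
            assert abs(a.optimal_fiber_length - b.optimal_fiber_length) < 1e-12
            assert abs(a.max_isometric_force - b.max_isometric_force) < 1e-12

    def test_half_height_halves_lengths_keeps_fractions(self, adult_spec):
        law = ScalingLaw(mode="uniform", height_ratio=0.5, target_total_mass=20.0)
        out = scale_uniform(adult_spec, law)
        for a, b in zip(adult_spec.segments, out.segments):
            assert b.length == pytest.approx(a.length * 0.5, rel=1e-12)
            assert b.mass / out.total_mass == pytest.approx(
                a.mass / adult_spec.total_mass, abs=1e-12
            )
        assert out.leg_length == pytest.approx(adult_spec.leg_length * 0.5, rel=1e-9)

    def test_mass_conservation(self, adult_spec):
        law = ScalingLaw(mode="uniform", height_ratio=0.7, target_total_mass=33.3)
        out = scale_uniform(adult_spec, law)
        assert abs(sum(s.mass for s in out.segments) - 33.3) < 1e-9


class TestOntogenetic:
    def test_identity_tables_reproduce_adult(self, adult_spec):
        law = ScalingLaw(
            mode="ontogenetic",
            target_total_mass=adult_spec.total_mass,
            per_segment_length_ratio={s.name: 1.0 for s in adult_spec.segments},
            mass_fraction_table={
                s.name: s.mass / adult_spec.total_mass for s in adult_spec.segments
            },
        )
        out = scale_ontogenetic(adult_spec, law)
        for a, b in zip(adult_spec.segments, out.segments):
            assert abs(a.length - b.length) < 1e-12
            assert abs(a.mass - b.mass) < 1e-9

    def test_fraction_table_reproduced_and_mass_conserved(self, adult_spec):
        law = bundled_scaling_law("onto4y")
        out = scale_ontogenetic(adult_spec, law)
        assert abs(out.total_mass - law.target_total_mass) < 1e-9
        for s in out.segments:
            assert s.mass / out.total_mass == pytest.approx(
                law.mass_fraction_table[s.name], abs=1e-12
            )

    def test_missing_segment_in_table_is_named(self, adult_spec):
        law = bundled_scaling_law("onto4y")
        law = copy.deepcopy(law)
        del law.per_segment_length_ratio["foot_l"]
        with pytest.raises(ValueError, match="foot_l"):
            scale_ontogenetic(adult_spec, law)

    def test_both_child_variants_share_total_mass(self, onto4y_spec, uni4y_spec):
        assert onto4y_spec.total_mass == pytest.approx(uni4y_spec.total_mass, abs=1e-9)

    def test_bundled_children_match_regenerated(self, adult_spec, onto4y_spec, uni4y_spec):
        """The shipped child fixtures are exactly what the scaler emits."""
        for law_name, bundled in (("onto4y", onto4y_spec), ("uni4y", uni4y_spec)):
            law = bundled_scaling_law(law_name)
            fresh = (scale_ontogenetic if law.mode == "ontogenetic" else scale_uniform)(
                adult_spec, law
            )
            for a, b in zip(fresh.segments, bundled.segments):
                assert abs(a.length - b.length) < 1e-9
                assert abs(a.mass - b.mass) < 1e-9


class TestMuscleScaling:
    def test_unit_ratios_are_identity(self, adult_spec):
        out = scale_muscles(adult_spec.muscles, 1.0, 1.0, 1.0)
        for a, b in zip(adult_spec.muscles, out):
            assert b.max_isometric_force == pytest.approx(a.max_isometric_force)
            assert b.optimal_fiber_length == pytest.approx(a.optimal_fiber_length)

    def test_half_mass_halves_force_and_keeps_hof_force(self, adult_spec):
        out = scale_muscles(adult_spec.muscles, 1.0, 0.5, 1.0)
        g = adult_spec.gravity
        for a, b in zip(adult_spec.muscles, out):
            assert b.max_isometric_force == pytest.approx(a.max_isometric_force * 0.5)
            # F_hat = F/(m g) identical with half the body mass
            assert b.max_isometric_force / (0.5 * adult_spec.total_mass * g) == (
                pytest.approx(a.max_isometric_force / (adult_spec.total_mass * g))
            )

    def test_path_ratio_scales_both_length_parameters(self, adult_spec):
        out = scale_muscles(adult_spec.muscles, 0.8, 1.0, 1.0)
        for a, b in zip(adult_spec.muscles, out):
            assert b.optimal_fiber_length == pytest.approx(a.optimal_fiber_length * 0.8)
            assert b.tendon_slack_length == pytest.approx(a.tendon_slack_length * 0.8)
            assert b.activation_time_constant == a.activation_time_constant

    def test_scaled_posture_keeps_normalized_fiber_length(self, adult_spec, uni4y_spec):
        """At the geometrically scaled reference posture, l_fiber/l_opt matches."""
        for sim_spec in (adult_spec, uni4y_spec):
            model = compile_model(sim_spec)
            sim = PlanarBiped(model)
            sim.reset(jitter_deg=0.0)
            lnorm = (sim._mlen - model.lslack) / model.lopt
            if sim_spec is adult_spec:
                ref = lnorm
            else:
                np.testing.assert_allclose(lnorm, ref, atol=1e-6)


class TestStiffnessAndVelocity:
    def test_unit_ratios_unchanged(self):
        assert scale_stiffness(11006.4, 1.0, 1.0) == pytest.approx(11006.4)

    def test_quarter_mass_half_length_halves_stiffness(self):
        k = scale_stiffness(11006.4, 0.25, 0.5)
        assert k == pytest.approx(11006.4 / 2)
        # dimensionless k l0/(m g) equal before/after
        m, g, l0 = 75.0, 9.81, 0.95
        before = 11006.4 * l0 / (m * g)
        after = k * (l0 * 0.5) / (m * 0.25 * g)
        assert after == pytest.approx(before, rel=1e-12)

    def test_constant_absolute_flag(self):
        assert scale_stiffness(100.0, 0.3, 0.6, constant_absolute=True) == 100.0

    def test_adult_fixture_contact_stiffness(self, adult_spec):
        assert all(c.stiffness == 11006.4 for c in adult_spec.contacts)

    @pytest.mark.parametrize(
        "v,l,expected", [(1.2, 1.0, 1.2), (1.2, 0.64, 0.96), (3.4, 0.25, 1.7)]
    )
    def test_velocity_scaling_closed_form(self, v, l, expected):
        assert scale_target_velocity(v, l) == pytest.approx(expected, rel=1e-12)

    def test_froude_preserved(self, adult_spec):
        from morphocurl.hofnorm import HofScales

        rng = np.random.default_rng(3)
        for _ in range(50):
            v = rng.uniform(0.1, 4.0)
            lam = rng.uniform(0.2, 1.0)
            a = HofScales(m=70.0, g=9.81, l0=1.0)
            c = HofScales(m=70.0, g=9.81, l0=lam)
            assert froude_number(scale_target_velocity(v, lam), c) == pytest.approx(
                froude_number(v, a), rel=1e-12
            )


def test_drop_test_dynamic_similarity(adult_spec, uni4y_spec):
    """A uniformly scaled body dropped from the scaled height retraces the
    adult's Hof-normalized settling trajectory when integrated at the
    Froude-scaled time step — the operational meaning of dynamic similarity."""
    lam = uni4y_spec.leg_length / adult_spec.leg_length

    def drop(spec, dt):
        model = compile_model(spec)
        sim = PlanarBiped(model, dt=dt, substeps=10)
        sim.reset(jitter_deg=0.0)
        sim.q[1] += 0.05 * spec.leg_length  # drop height in body units
        sim._refresh_diagnostics()
        ys = []
        u = np.zeros(model.n_muscles)
        for _ in range(60):
            sim.step(u)
            ys.append(sim.com()[1] / spec.leg_length)
        return np.array(ys)

    adult_traj = drop(adult_spec, dt=0.01)
    child_traj = drop(uni4y_spec, dt=0.01 * math.sqrt(lam))
    np.testing.assert_allclose(child_traj, adult_traj, atol=2e-4)
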