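import math

import numpy as np
import pytest

from morphocurl.evaluation import (
    PerturbationProtocol,
    RolloutRecord,
    gait_metrics,
    perturbation_test,
    velocity_error,
    velocity_ramp_protocol,
)


class TestVelocityError:
    def _record(self, vx, horizon=1000):
        return RolloutRecord(dt=0.01, horizon=horizon, vx=np.asarray(vx, dtype=float))

    def test_perfect_tracking_is_zero(self):
        r = self._record(np.full(1000, 1.2))
        assert velocity_error(r, 1.2, "walking") == 0.0

    def test_half_speed_gives_half(self):
        r = self._record(np.full(1000, 0.6))
        assert velocity_error(r, 1.2, "walking") == pytest.approx(0.5)

    def test_balance_early_termination_bookkeeping(self):
        # terminated at half horizon with zero velocity: error stays 0 but
        # the episode-length fraction is recorded
        r = self._record(np.zeros(500), horizon=1000)
        assert velocity_error(r, 0.0, "balance") == 0.0
        assert r.achieved_fraction == 0.5
        # nonzero drift is penalized by the short episode
        r2 = self._record(np.full(500, 0.1), horizon=1000)
        assert velocity_error(r2, 0.0, "balance") == pytest.approx(0.2)

    def test_gait_mode_rejects_zero_target(self):
        with pytest.raises(ValueError, match="v\\*"):
            velocity_error(self._record(np.ones(10)), 0.0, "running")


class TestRampProtocol:
    def test_increase_structure(self):
        tr = velocity_ramp_protocol("increase")
        assert tr.shape == (1000,)
        assert np.all(tr[:100] == 0.0)
        assert tr[100] == pytest.approx(1.2)
        assert tr[799] == pytest.approx(3.4)
        assert np.all(tr[800:] == 3.4)
        # linear interior
        interior = tr[100:800]
        diffs = np.diff(interior)
        assert np.allclose(diffs, diffs[0], atol=1e-12)

    def test_decrease_structure(self):
        tr = velocity_ramp_protocol("decrease")
        assert np.all(tr[:100] == 3.4)
        assert tr[100] == pytest.approx(3.4)
        assert tr[799] == pytest.approx(1.2)
        assert np.all(tr[800:] == 0.0)

    def test_protocols_are_not_mirror_images(self):
        up = velocity_ramp_protocol("increase")
        down = velocity_ramp_protocol("decrease")
        assert not np.allclose(up, down[::-1])  # abrupt drop vs gradual start

    def test_unknown_direction(self):
        with pytest.raises(ValueError):
            velocity_ramp_protocol("sideways")


class TestPerturbationProtocol:
    def test_onsets_every_interval_lasting_duration(self):
        p = PerturbationProtocol(force_magnitude=30.0, seed=0)
        sign = p.initial_direction()
        for k in (1, 2, 3):
            t0 = 4.0 * k
            expected = sign * (1 if k % 2 == 1 else -1) * 30.0
            assert p.force_at(t0 + 0.0) == expected
            assert p.force_at(t0 + 0.99) == expected
            assert p.force_at(t0 + 1.01) == 0.0
        assert p.force_at(0.5) == 0.0  # no push before the first onset

    def test_alternating_direction(self):
        p = PerturbationProtocol(force_magnitude=10.0, seed=1)
        s1 = np.sign(p.force_at(4.5))
        s2 = np.sign(p.force_at(8.5))
        s3 = np.sign(p.force_at(12.5))
        assert s1 == -s2 == s3

    def test_initial_direction_is_seeded(self):
        signs = {PerturbationProtocol(seed=s).initial_direction() for s in range(20)}
        assert signs == {-1, 1}
        assert (
            PerturbationProtocol(seed=5).initial_direction()
            == PerturbationProtocol(seed=5).initial_direction()
        )

    def test_interval_must_exceed_duration(self):
        with pytest.raises(ValueError):
            PerturbationProtocol(onset_interval=1.0, duration=2.0)

    def test_z_axis_rejected_in_planar_model(self):
        with pytest.raises(ValueError, match="planar"):
            perturbation_test(lambda o: o, None, PerturbationProtocol(axis="z"))


@pytest.fixture(scope="module")
def statue_env(adult_spec):
    from morphocurl.dynamics import Constraints
    from morphocurl.envs import LocomotionEnv

    from conftest import STATUE_JOINTS

    return LocomotionEnv(
        adult_spec,
        horizon=100,
        constraints=Constraints(fix_joints=("base_x", "base_rot") + STATUE_JOINTS),
    )


class TestPerturbationLadder:
    def test_statue_withstands_up_to_cap(self, statue_env):
        """A frame-supported statue cannot fall: the ladder runs to its cap
        (degenerate upper bound for the search)."""
        policy = lambda obs: np.zeros(statue_env.act_dim)  # noqa: E731
        p = PerturbationProtocol(seed=0)
        out = perturbation_test(policy, statue_env, p, ladder_step=40.0, max_force=80.0)
        assert out == 80.0

    def test_ladder_deterministic_for_fixed_seed(self, statue_env):
        policy = lambda obs: np.zeros(statue_env.act_dim)  # noqa: E731
        p = PerturbationProtocol(seed=3)
        a = perturbation_test(policy, statue_env, p, ladder_step=50.0, max_force=50.0)
        b = perturbation_test(policy, statue_env, p, ladder_step=50.0, max_force=50.0)
        assert a == b


class TestGaitMetrics:
    def _synthetic_gait(self, period=1.0, window=10.0, dt=0.01, bw=735.75):
        n = int(window / dt)
        t = np.arange(n) * dt
        phase = 2 * np.pi * t / period
        grf_l = bw * np.clip(np.sin(phase), 0, None)
        grf_r = bw * np.clip(np.sin(phase + np.pi), 0, None)
        angles = {}
        for j, amp in (("hip", 0.4), ("knee", 0.7), ("ankle", 0.3)):
            angles[f"{j}_l"] = amp * np.sin(phase)
            angles[f"{j}_r"] = amp * np.sin(phase + np.pi)
        return RolloutRecord(
            dt=dt, horizon=n, vx=np.full(n, 1.2), joint_angles=angles,
            grf={"left": grf_l, "right": grf_r}, body_weight=bw,
        )

    def test_cycle_count_matches_constructed_period(self):
        period, window = 1.0, 10.0
        r = self._synthetic_gait(period, window)
        df = gait_metrics(r, window=window)
        # each leg strikes once per period; cycles are between strikes
        strikes_per_leg = math.floor(window / period)
        assert df.attrs["n_cycles"] == 2 * (strikes_per_leg - 1)
        assert len(df) == 101

    def test_symmetric_legs_give_identical_mean_curves(self):
        r = self._synthetic_gait()
        df = gait_metrics(r)
        # with perfectly antiphased identical legs, pooling both legs yields
        # SD ~ 0 across cycles for every signal
        assert df["hip_sd"].max() < 1e-9
        assert df["grf_sd"].max() < 1e-6

    def test_too_few_cycles_is_an_error(self):
        r = self._synthetic_gait(period=8.0, window=10.0)
        with pytest.raises(ValueError, match="cycle"):
            gait_metrics(r, window=10.0)

    def test_missing_channels_rejected(self):
        r = RolloutRecord(dt=0.01, horizon=10, vx=np.zeros(10))
        with pytest.raises(ValueError, match="lacks"):
            gait_metrics(r)
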