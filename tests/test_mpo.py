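import math

import numpy as np
import pytest

from morphocurl.mpo import (
    MLP,
    MPOAgent,
    MPOConfig,
    estep_kl,
    estep_weights,
    solve_dual,
)


# ---------------------------------------------------------------------------
# E-step


class TestEStep:
    def test_equal_q_gives_uniform_weights(self):
        Q = np.full((8, 20), 3.7)
        w, eta = estep_weights(Q, epsilon=0.1)
        np.testing.assert_allclose(w, 1.0 / 20, atol=1e-12)
        assert estep_kl(w) == pytest.approx(0.0, abs=1e-12)

    def test_large_eta_limit_is_uniform(self):
        Q = np.random.default_rng(0).normal(size=(4, 10))
        z = Q / 1e9
        w = np.exp(z - z.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(w, 0.1, atol=1e-9)

    def test_weights_are_a_distribution(self):
        Q = np.random.default_rng(1).normal(size=(16, 20)) * 5
        w, _ = estep_weights(Q, epsilon=0.1)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_two_action_tilt_matches_scalar_dual_oracle(self):
        """Brute-force 1-D minimization of the dual over eta reproduces the
        same temperature and weights as the packaged solver."""
        Q = np.array([[1.0, 0.0]])
        eps = 0.01

        def dual(eta):
            return eta * eps + eta * np.mean(
                np.log(np.mean(np.exp(Q / eta), axis=1))
            )

        grid = np.exp(np.linspace(-8, 8, 200_001))
        eta_oracle = grid[np.argmin([dual(e) for e in grid])]
        eta = solve_dual(Q, eps)
        assert eta == pytest.approx(eta_oracle, rel=1e-3)
        w, _ = estep_weights(Q, eps)
        w_oracle = np.exp(Q / eta_oracle)
        w_oracle /= w_oracle.sum()
        np.testing.assert_allclose(w, w_oracle, atol=1e-4)

    def test_sample_kl_respects_epsilon(self):
        rng = np.random.default_rng(2)
        for eps in (0.03, 0.1, 0.5):
            Q = rng.normal(size=(32, 20)) * 10
            w, _ = estep_weights(Q, eps)
            assert estep_kl(w) <= eps + 1e-3


# ---------------------------------------------------------------------------
# critic vs tabular value iteration


def two_state_mdp():
    """Deterministic 2-state chain with scalar action embeddings.

    Action a1 = 0.75 moves toward/keeps the rewarding state s1 (reward 1 for
    staying there); a0 = 0.25 resets to s0 with no reward.  The optimal
    policy is 'always a1'.
    """
    A0, A1 = 0.25, 0.75

    def step(s, a):
        if a == A1:
            return (1, 1.0) if s == 1 else (1, 0.0)
        return (0, 0.0)

    return A0, A1, step


def tabular_value_iteration(gamma, tol=1e-12):
    A0, A1, step = two_state_mdp()
    Q = np.zeros((2, 2))
    for _ in range(10_000):
        new = np.zeros_like(Q)
        for s in (0, 1):
            for ai, a in enumerate((A0, A1)):
                s2, r = step(s, a)
                new[s, ai] = r + gamma * Q[s2].max()
        if np.abs(new - Q).max() < tol:
            break
        Q = new
    return Q


@pytest.fixture(scope="module")
def converged_tabular_agent():
    """MPO critic trained on the 2-state chain under the fixed optimal policy."""
    gamma = 0.9
    A0, A1, step = two_state_mdp()
    cfg = MPOConfig(
        hidden_layers=(32, 32), gamma=gamma, lr_critic=1e-3,
        polyak_tau=0.05, batch_size=4, buffer_size=16, seed=0,
    )
    agent = MPOAgent(obs_dim=1, act_dim=1, config=cfg)
    # pin the policy to 'always a1': zero network, bias at a1, tiny covariance
    for W in agent.actor.W:
        W[...] = 0.0
    for b in agent.actor.b:
        b[...] = 0.0
    agent.actor.b[-1][...] = A1
    agent.log_std[...] = -10.0  # effectively deterministic evaluation policy

    obs = np.array([[0.0], [0.0], [1.0], [1.0]])
    act = np.array([[A0], [A1], [A0], [A1]])
    rew, nobs = [], []
    for s, a in zip((0, 0, 1, 1), (A0, A1, A0, A1)):
        s2, r = step(s, a)
        rew.append(r)
        nobs.append([float(s2)])
    batch = (obs, act, np.array(rew), np.array(nobs), np.zeros(4))
    for _ in range(6000):
        agent.critic_update(batch)
    return agent, batch, gamma


def test_critic_matches_tabular_value_iteration(converged_tabular_agent):
    agent, batch, gamma = converged_tabular_agent
    oracle = tabular_value_iteration(gamma)
    obs, act = batch[0], batch[1]
    q = agent.critic_eval(obs, act)
    expected = np.array([oracle[0, 0], oracle[0, 1], oracle[1, 0], oracle[1, 1]])
    np.testing.assert_allclose(q, expected, atol=1e-2)


def test_small_gamma_regresses_to_immediate_reward():
    A0, A1, step = two_state_mdp()
    cfg = MPOConfig(hidden_layers=(16, 16), gamma=1e-3, lr_critic=1e-3,
                    polyak_tau=0.1, batch_size=4, seed=1)
    agent = MPOAgent(1, 1, cfg)
    for W in agent.actor.W:
        W[...] = 0.0
    for b in agent.actor.b:
        b[...] = 0.0
    agent.actor.b[-1][...] = A1
    agent.log_std[...] = cfg.min_log_std
    obs = np.array([[0.0], [1.0]])
    act = np.array([[A1], [A1]])
    rew = np.array([0.0, 1.0])
    nobs = np.array([[1.0], [1.0]])
    batch = (obs, act, rew, nobs, np.zeros(2))
    for _ in range(3000):
        agent.critic_update(batch)
    np.testing.assert_allclose(agent.critic_eval(obs, act), rew, atol=5e-3)


def test_critic_loss_decreases_on_fixed_batch():
    cfg = MPOConfig(hidden_layers=(16, 16), batch_size=8, seed=2)
    agent = MPOAgent(2, 1, cfg)
    rng = np.random.default_rng(0)
    batch = (rng.normal(size=(8, 2)), rng.uniform(0, 1, (8, 1)),
             rng.normal(size=8), rng.normal(size=(8, 2)), np.zeros(8))
    first = agent.critic_update(batch)
    for _ in range(200):
        last = agent.critic_update(batch)
    assert last < first


# ---------------------------------------------------------------------------
# M-step


class TestMStep:
    def _agent(self, lr=3e-4, seed=0):
        cfg = MPOConfig(hidden_layers=(16, 16), lr_actor=lr, seed=seed,
                        m_step_iterations=20)
        return MPOAgent(obs_dim=2, act_dim=1, config=cfg)

    def test_mean_moves_toward_weighted_action(self):
        agent = self._agent(lr=1e-2)
        obs = np.zeros((4, 2))
        mu0 = agent.policy_mean(obs)[0, 0]
        target = mu0 + 0.3
        acts = np.full((4, 8, 1), target)
        w = np.full((4, 8), 1.0 / 8)
        agent.m_step(obs, acts, w)
        mu1 = agent.policy_mean(obs)[0, 0]
        assert abs(mu1 - target) < abs(mu0 - target)

    def test_zero_learning_rate_keeps_parameters(self):
        agent = self._agent(lr=0.0)
        before = [p.copy() for p in agent.actor.params]
        obs = np.random.default_rng(0).normal(size=(4, 2))
        acts = np.random.default_rng(1).uniform(0, 1, (4, 8, 1))
        w = np.full((4, 8), 1.0 / 8)
        agent.m_step(obs, acts, w)
        for p, q in zip(agent.actor.params, before):
            np.testing.assert_allclose(p, q, atol=1e-15)

    def test_trust_region_kl_bounded(self):
        agent = self._agent(lr=5e-2, seed=3)  # aggressive steps
        rng = np.random.default_rng(4)
        obs = rng.normal(size=(16, 2))
        mu_old = agent.policy_mean(obs).copy()
        ls_old = agent.log_std.copy()
        acts = rng.uniform(-2, 2, (16, 8, 1))
        w = rng.dirichlet(np.ones(8), size=16)
        out = agent.m_step(obs, acts, w)
        measured = agent._gaussian_kl(
            mu_old, ls_old, agent.policy_mean(obs), agent.log_std
        )
        assert measured <= agent.config.kl_limit + 1e-9
        assert out["m_step_kl"] == pytest.approx(measured, abs=1e-12)


def test_mlp_backward_matches_finite_differences():
    rng = np.random.default_rng(0)
    net = MLP([3, 8, 2], rng)
    x = rng.normal(size=(5, 3))
    dout = rng.normal(size=(5, 2))

    cache = []
    net.forward(x, cache)
    grads, _ = net.backward(cache, dout)

    def loss():
        return float((net.forward(x) * dout).sum())

    eps = 1e-6
    for p, g in zip(net.params, grads):
        idx = (0,) * p.ndim
        p[idx] += eps
        up = loss()
        p[idx] -= 2 * eps
        down = loss()
        p[idx] += eps
        assert (up - down) / (2 * eps) == pytest.approx(np.asarray(g)[idx], rel=1e-4, abs=1e-8)
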