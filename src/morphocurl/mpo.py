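"""Maximum a Posteriori Policy Optimisation (MPO), minimal numpy edition.

The learner alternates:

* **critic step** — one-step temporal-difference regression of Q(s, a) with
  a Polyak-averaged target network,
* **E-step** — a nonparametric KL-constrained policy improvement: per-state
  action samples are reweighted by exp(Q/eta*), with the temperature eta*
  found by minimizing the convex dual g(eta) = eta*epsilon +
  eta * E_s[log mean_a exp(Q(s,a)/eta)],
* **M-step** — supervised fitting of the Gaussian policy to the reweighted
  samples, kept near the previous policy by a KL trust region (backtracking
  projection onto the KL ball).

Networks are two-hidden-layer ReLU MLPs (256 units by default) written in
plain numpy with hand-rolled backprop and Adam; the policy is Gaussian with
a state-independent diagonal covariance.  Defaults follow the reference
hyperparameters: replay 1e6, batch 256, 1e6 initial steps, 30 batches every
1000 environment steps, 1-step returns, learning rates 3e-4 (actor, critic)
and 1e-2 (dual).  The learner is swappable: anything implementing
``act`` / ``observe`` / ``update`` / ``set_environment`` can replace it in
the training loop, which is agnostic to the underlying RL algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from morphocurl.curriculum import (
    Schedule,
    morphology_handover,
    phase_at,
    sample_target_velocity,
)


# ---------------------------------------------------------------------------
# tiny neural nets


class Adam:
    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class MLP:
    """Fully connected ReLU network with hand-rolled backprop."""

    def __init__(self, sizes, rng: np.random.Generator):
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.W.append(rng.normal(0, math.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def params(self):
        return self.W + self.b

    def copy_from(self, other: "MLP") -> None:
        for a, b in zip(self.params, other.params):
            a[...] = b

    def polyak_from(self, other: "MLP", tau: float) -> None:
        for a, b in zip(self.params, other.params):
            a *= 1 - tau
            a += tau * b

    def forward(self, x: np.ndarray, cache: Optional[list] = None) -> np.ndarray:
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < len(self.W) - 1:
                if cache is not None:
                    cache.append((h, z))
                h = np.maximum(z, 0.0)
            else:
                if cache is not None:
                    cache.append((h, z))
                h = z
        return h

    def backward(self, cache: list, dout: np.ndarray):
        """Gradients of sum(loss) given d loss/d output; returns (grads, dx)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        d = dout
        for i in reversed(range(len(self.W))):
            h, _ = cache[i]
            gW[i] = h.T @ d
            gb[i] = d.sum(axis=0)
            if i > 0:
                d = d @ self.W[i].T
                _, z_prev = cache[i - 1]
                d = d * (z_prev > 0)
        return gW + gb, d


# ---------------------------------------------------------------------------
# configuration


@dataclass
class MPOConfig:
    epsilon: float = 0.1
    gamma: float = 0.99
    buffer_size: int = 1_000_000
    batch_size: int = 256
    initial_steps: int = 1_000_000
    steps_between_batches: int = 1000
    batches_per_update: int = 30
    n_step: int = 1
    hidden_layers: Tuple[int, int] = (256, 256)
    lr_actor: float = 3e-4
    lr_critic: float = 3e-4
    lr_dual: float = 1e-2
    action_samples: int = 20
    m_step_iterations: int = 5
    kl_limit: float = 0.1          # M-step trust region KL(old || new)
    polyak_tau: float = 0.005
    init_log_std: float = -0.5
    min_log_std: float = -4.0
    max_log_std: float = 0.3
    act_low: float = 0.0        # box action bounds (muscle excitations)
    act_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        for name in ("buffer_size", "batch_size", "steps_between_batches",
                     "batches_per_update", "action_samples"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_step != 1:
            raise ValueError("only 1-step returns are implemented")


class ReplayBuffer:
    def __init__(self, capacity: int, obs_dim: int, act_dim: int):
        self.capacity = capacity
        self.obs = np.zeros((capacity, obs_dim))
        self.act = np.zeros((capacity, act_dim))
        self.rew = np.zeros(capacity)
        self.nobs = np.zeros((capacity, obs_dim))
        self.done = np.zeros(capacity)
        self.ptr = 0
        self.size = 0

    def add(self, o, a, r, no, d):
        i = self.ptr
        self.obs[i] = o
        self.act[i] = a
        self.rew[i] = r
        self.nobs[i] = no
        self.done[i] = float(d)
        self.ptr = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, rng: np.random.Generator, batch: int):
        idx = rng.integers(0, self.size, batch)
        return (self.obs[idx], self.act[idx], self.rew[idx], self.nobs[idx], self.done[idx])


# ---------------------------------------------------------------------------
# dual minimization (E-step temperature)


def solve_dual(Q: np.ndarray, epsilon: float) -> float:
    """eta* = argmin eta*eps + eta*mean_s[log mean_a exp(Q_sa/eta)].

    ``Q`` is (states, action samples).  The dual is convex in eta > 0; a
    bounded scalar search over log eta is robust for any Q scale.
    """
    Qs = Q - Q.max(axis=1, keepdims=True)

    def g(log_eta: float) -> float:
        eta = math.exp(log_eta)
        lse = np.log(np.mean(np.exp(Qs / eta), axis=1))
        return eta * epsilon + eta * float(np.mean(lse)) + float(np.mean(Q.max(axis=1)))

    res = minimize_scalar(g, bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"dual optimization failed in [e-10, e10]: {res}")
    return math.exp(res.x)


def estep_weights(Q: np.ndarray, epsilon: float) -> Tuple[np.ndarray, float]:
    """Per-state weights proportional to exp(Q/eta*), normalized to sum 1."""
    eta = solve_dual(Q, epsilon)
    z = (Q - Q.max(axis=1, keepdims=True)) / eta
    w = np.exp(z)
    w /= w.sum(axis=1, keepdims=True)
    return w, eta


def estep_kl(w: np.ndarray) -> float:
    """Sample-based KL(q || pi) when actions were sampled from pi."""
    K = w.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(w > 0, w * np.log(w * K), 0.0)
    return float(t.sum(axis=1).mean())


# ---------------------------------------------------------------------------
# the agent


class MPOAgent:
    """Gaussian-policy MPO over a replay buffer."""

    def __init__(self, obs_dim: int, act_dim: int, config: Optional[MPOConfig] = None):
        self.config = config or MPOConfig()
        c = self.config
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        self.rng = np.random.default_rng(c.seed)
        h = list(c.hidden_layers)
        self.actor = MLP([obs_dim] + h + [act_dim], self.rng)
        self.log_std = np.full(act_dim, c.init_log_std)
        self.critic = MLP([obs_dim + act_dim] + h + [1], self.rng)
        self.critic_target = MLP([obs_dim + act_dim] + h + [1], self.rng)
        self.critic_target.copy_from(self.critic)
        self.opt_actor = Adam([p.shape for p in self.actor.params] + [self.log_std.shape],
                              c.lr_actor)
        self.opt_critic = Adam([p.shape for p in self.critic.params], c.lr_critic)
        self.replay = ReplayBuffer(c.buffer_size, obs_dim, act_dim)
        self.env = None
        self.last_metrics: Dict[str, float] = {}

    # -- policy ------------------------------------------------------------

    def policy_mean(self, obs: np.ndarray) -> np.ndarray:
        return self.actor.forward(np.atleast_2d(obs))

    def act(self, obs: np.ndarray, deterministic: bool = False) -> np.ndarray:
        """Action clipped to the box bounds (the critic is only ever queried
        on-support, which prevents extrapolation runaway)."""
        c = self.config
        mu = self.policy_mean(obs)[0]
        if not deterministic:
            mu = mu + np.exp(self.log_std) * self.rng.standard_normal(self.act_dim)
        return np.clip(mu, c.act_low, c.act_high)

    def sample_actions(self, obs: np.ndarray, k: int) -> np.ndarray:
        """(B, k, act_dim) clipped samples from the current policy."""
        c = self.config
        mu = self.policy_mean(obs)[:, None, :]
        eps = self.rng.standard_normal((obs.shape[0], k, self.act_dim))
        return np.clip(
            mu + np.exp(self.log_std)[None, None, :] * eps, c.act_low, c.act_high
        )

    def observe(self, obs, act, rew, next_obs, done) -> None:
        self.replay.add(obs, act, rew, next_obs, done)

    def set_environment(self, env) -> None:
        self.env = env

    # -- critic ------------------------------------------------------------

    def critic_eval(self, obs: np.ndarray, act: np.ndarray, target: bool = False) -> np.ndarray:
        net = self.critic_target if target else self.critic
        return net.forward(np.concatenate([obs, act], axis=1))[:, 0]

    def critic_update(self, batch) -> float:
        """One TD(0) regression step with the target network; returns the loss."""
        obs, act, rew, nobs, done = batch
        c = self.config
        k = 4
        na = self.sample_actions(nobs, k)
        flat = np.concatenate(
            [np.repeat(nobs, k, axis=0), na.reshape(-1, self.act_dim)], axis=1
        )
        qn = self.critic_target.forward(flat)[:, 0].reshape(-1, k).mean(axis=1)
        y = rew + c.gamma * (1.0 - done) * qn
        cache: list = []
        q = self.critic.forward(np.concatenate([obs, act], axis=1), cache)[:, 0]
        err = q - y
        loss = float(np.mean(err**2))
        if not math.isfinite(loss):
            raise FloatingPointError(
                f"critic loss is not finite (q range {q.min()}..{q.max()})"
            )
        dout = (2.0 / len(err)) * err[:, None]
        grads, _ = self.critic.backward(cache, dout)
        self.opt_critic.step(self.critic.params, grads)
        self.critic_target.polyak_from(self.critic, c.polyak_tau)
        return loss

    # -- E-step ------------------------------------------------------------

    def e_step(self, obs: np.ndarray):
        """Sampled actions, normalized improvement weights, and eta*."""
        c = self.config
        acts = self.sample_actions(obs, c.action_samples)
        flat = np.concatenate(
            [np.repeat(obs, c.action_samples, axis=0), acts.reshape(-1, self.act_dim)],
            axis=1,
        )
        Q = self.critic.forward(flat)[:, 0].reshape(obs.shape[0], c.action_samples)
        w, eta = estep_weights(Q, c.epsilon)
        return acts, w, eta

    # -- M-step ------------------------------------------------------------

    def _gaussian_kl(self, mu_old, log_std_old, mu_new, log_std_new) -> float:
        var_o = np.exp(2 * log_std_old)
        var_n = np.exp(2 * log_std_new)
        per_dim = (
            log_std_new - log_std_old
            + (var_o + (mu_new - mu_old) ** 2) / (2 * var_n)
            - 0.5
        )
        return float(per_dim.sum(axis=-1).mean())

    def m_step(self, obs: np.ndarray, acts: np.ndarray, w: np.ndarray) -> Dict[str, float]:
        """Weighted maximum likelihood under a KL trust region to the old policy."""
        c = self.config
        old_params = [p.copy() for p in self.actor.params]
        old_log_std = self.log_std.copy()
        mu_old = self.policy_mean(obs)

        for _ in range(c.m_step_iterations):
            cache: list = []
            mu = self.actor.forward(obs, cache)
            std = np.exp(self.log_std)
            # d(-sum_k w logp)/dmu, summed over samples
            diff = acts - mu[:, None, :]
            dmu = -(w[:, :, None] * diff / std[None, None, :] ** 2).sum(axis=1)
            dmu /= obs.shape[0]
            grads, _ = self.actor.backward(cache, dmu)
            dls = -(w[:, :, None] * ((diff / std[None, None, :]) ** 2 - 1.0)).sum(
                axis=(0, 1)
            ) / obs.shape[0]
            self.opt_actor.step(self.actor.params + [self.log_std], grads + [dls])
            np.clip(self.log_std, c.min_log_std, c.max_log_std, out=self.log_std)

        # project back onto the KL ball by backtracking toward the old policy
        for _ in range(20):
            kl = self._gaussian_kl(mu_old, old_log_std, self.policy_mean(obs), self.log_std)
            if kl <= c.kl_limit:
                break
            for p, po in zip(self.actor.params, old_params):
                p += po
                p *= 0.5
            self.log_std += old_log_std
            self.log_std *= 0.5
        else:
            raise RuntimeError("M-step failed to satisfy the KL trust region")
        std = np.exp(self.log_std)
        if np.any(std < 1e-6):
            raise RuntimeError("policy covariance collapsed")
        return {"m_step_kl": kl}

    # -- combined update ---------------------------------------------------

    def update(self) -> Dict[str, float]:
        """One full MPO update: critic step, E-step, M-step on a replay batch."""
        c = self.config
        batch = self.replay.sample(self.rng, c.batch_size)
        critic_loss = self.critic_update(batch)
        obs = batch[0]
        acts, w, eta = self.e_step(obs)
        m = self.m_step(obs, acts, w)
        self.last_metrics = {
            "critic_loss": critic_loss,
            "eta": eta,
            "estep_kl": estep_kl(w),
            **m,
        }
        return self.last_metrics


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainEvent:
    env_step: int
    kind: str      # "phase" | "morphology"
    value: str


@dataclass
class TrainResult:
    episode_returns: List[float]
    episode_steps: List[int]
    episode_phases: List[str]
    episode_stages: List[str]
    events: List[TrainEvent]
    agent: MPOAgent


class RandomAgent:
    """Uniform-excitation baseline with the same interface as MPOAgent."""

    def __init__(self, obs_dim: int, act_dim: int, seed: int = 0,
                 low: float = 0.0, high: float = 1.0):
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        self.rng = np.random.default_rng(seed)
        self.low, self.high = low, high
        self.env = None

    def act(self, obs, deterministic: bool = False):
        return self.rng.uniform(self.low, self.high, self.act_dim)

    def observe(self, *args) -> None:
        pass

    def update(self) -> Dict[str, float]:
        return {}

    def set_environment(self, env) -> None:
        self.env = env


def train(
    env_factory: Callable[[str], object],
    schedule: Schedule,
    config: Optional[MPOConfig] = None,
    seed: int = 0,
    total_steps: Optional[int] = None,
    agent: Optional[object] = None,
) -> TrainResult:
    """Run curriculum training for ``total_steps`` environment steps.

    ``env_factory(stage)`` builds an environment for a morphology stage; the
    environment contract is ``reset(seed) -> obs``, ``step(a) -> (obs, r,
    terminated, truncated, info)``, plus ``obs_dim``, ``act_dim``,
    ``leg_ratio`` and ``set_task(TaskSpec)``.  Phase and morphology are read
    from the schedule at every episode start; morphology changes go through
    :func:`morphology_handover` (parameters and replay retained) and are
    logged as events, as are phase changes.
    """
    config = config or MPOConfig(seed=seed)
    total = total_steps if total_steps is not None else schedule.total_steps
    rng = np.random.default_rng(seed)

    phase, stage = phase_at(schedule, 0)
    env = env_factory(stage)
    if agent is None:
        agent = MPOAgent(env.obs_dim, env.act_dim, config)
    agent.set_environment(env)

    events = [TrainEvent(0, "phase", phase), TrainEvent(0, "morphology", stage)]
    returns: List[float] = []
    ep_steps: List[int] = []
    ep_phases: List[str] = []
    ep_stages: List[str] = []

    transitions = sorted(schedule.transition_steps)

    def next_transition(step: int) -> int:
        for t in transitions:
            if t > step:
                return t
        return total

    steps_done = 0
    since_update = 0
    while steps_done < total:
        new_phase, new_stage = phase_at(schedule, steps_done)
        if new_stage != stage:
            env = env_factory(new_stage)
            morphology_handover(agent, env)
            events.append(TrainEvent(steps_done, "morphology", new_stage))
            stage = new_stage
        if new_phase != phase:
            events.append(TrainEvent(steps_done, "phase", new_phase))
            phase = new_phase

        task = sample_target_velocity(phase, env.leg_ratio, rng)
        env.set_task(task)
        obs = env.reset(seed=int(rng.integers(0, 2**31 - 1)))
        ep_ret = 0.0
        done = False
        # episodes are truncated at curriculum breakpoints so phase and
        # morphology transitions happen at exactly the scheduled steps
        episode_cap = next_transition(steps_done)
        while not done and steps_done < min(total, episode_cap):
            if steps_done < config.initial_steps:
                a = rng.uniform(0.0, 1.0, env.act_dim)
            else:
                a = agent.act(obs)
            nobs, r, terminated, truncated, _ = env.step(a)
            agent.observe(obs, a, r, nobs, terminated)
            obs = nobs
            ep_ret += r
            steps_done += 1
            since_update += 1
            done = terminated or truncated
            if (
                steps_done >= config.initial_steps
                and since_update >= config.steps_between_batches
                and getattr(agent, "replay", None) is not None
                and agent.replay.size >= config.batch_size
            ):
                for _ in range(config.batches_per_update):
                    agent.update()
                since_update = 0
        returns.append(ep_ret)
        ep_steps.append(steps_done)
        ep_phases.append(phase)
        ep_stages.append(stage)

    return TrainResult(
        episode_returns=returns,
        episode_steps=ep_steps,
        episode_phases=ep_phases,
        episode_stages=ep_stages,
        events=events,
        agent=agent,
    )


# ---------------------------------------------------------------------------
# checkpointing


def save_agent(agent: MPOAgent, path) -> None:
    """Write actor/critic weights, covariance, and config to HDF5."""
    import json

    import h5py
    from dataclasses import asdict

    with h5py.File(path, "w") as f:
        f.attrs["obs_dim"] = agent.obs_dim
        f.attrs["act_dim"] = agent.act_dim
        f.attrs["config"] = json.dumps(asdict(agent.config))
        f.create_dataset("log_std", data=agent.log_std)
        for name, net in (("actor", agent.actor), ("critic", agent.critic),
                          ("critic_target", agent.critic_target)):
            g = f.create_group(name)
            for i, W in enumerate(net.W):
                g.create_dataset(f"W{i}", data=W)
            for i, b in enumerate(net.b):
                g.create_dataset(f"b{i}", data=b)


def load_agent(path) -> MPOAgent:
    """Restore an agent saved by :func:`save_agent` (replay not included)."""
    import json

    import h5py

    with h5py.File(path, "r") as f:
        cfg = MPOConfig(**json.loads(f.attrs["config"]))
        cfg.hidden_layers = tuple(cfg.hidden_layers)
        agent = MPOAgent(int(f.attrs["obs_dim"]), int(f.attrs["act_dim"]), cfg)
        agent.log_std[...] = f["log_std"][...]
        for name, net in (("actor", agent.actor), ("critic", agent.critic),
                          ("critic_target", agent.critic_target)):
            for i in range(len(net.W)):
                net.W[i][...] = f[name][f"W{i}"][...]
                net.b[i][...] = f[name][f"b{i}"][...]
    return agent
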