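"""Desk-scale benchmark experiments run by both the tests and the
reproduction script.

Two stochastic studies are bundled here so that their conditions are defined
exactly once:

* the white-noise workspace-coverage comparison across morphologies at the
  printed protocol scale (50 episodes of 1000 steps per body), summarized
  as position/velocity occupancy fractions and the across-seed count of the
  ordering Onto4y > Uni4y > adult, and
* the scaled-down learning check: MPO on the one-muscle inverted-pendulum
  balance task for 50k environment steps, compared against the uniform
  random-excitation baseline via the mean on-policy return over the last
  20% of episodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from morphocurl.curriculum import Breakpoint, Schedule
from morphocurl.envs import MusclePendulumEnv, pendulum_check_config
from morphocurl.exploration import run_white_noise_rollouts, workspace_coverage
from morphocurl.morphology import bundled_morphology
from morphocurl.mpo import RandomAgent, train

COVERAGE_STAGES = ("adult", "uni4y", "onto4y")
PENDULUM_STEPS = 50_000


@dataclass
class CoverageOrdering:
    """Occupancy fractions per stage/seed plus ordering success counts."""

    position: Dict[int, Dict[str, float]]
    velocity: Dict[int, Dict[str, float]]
    position_ordered_seeds: int
    velocity_ordered_seeds: int
    n_seeds: int


def coverage_ordering_experiment(
    seeds: Sequence[int],
    n_episodes: int = 50,
    steps_per_episode: int = 1000,
) -> CoverageOrdering:
    """Run the toy exploration experiment for each seed and morphology."""
    specs = {s: bundled_morphology(s) for s in COVERAGE_STAGES}
    pos: Dict[int, Dict[str, float]] = {}
    vel: Dict[int, Dict[str, float]] = {}
    okp = okv = 0
    for seed in seeds:
        pos[seed] = {}
        vel[seed] = {}
        for stage, spec in specs.items():
            series = run_white_noise_rollouts(
                spec, n_episodes=n_episodes, steps_per_episode=steps_per_episode,
                seed=seed,
            )
            cov = workspace_coverage(series)
            pos[seed][stage] = cov.occupancy_fraction_position
            vel[seed][stage] = cov.occupancy_fraction_velocity
        p, v = pos[seed], vel[seed]
        okp += p["onto4y"] > p["uni4y"] > p["adult"]
        okv += v["onto4y"] > v["uni4y"] > v["adult"]
    return CoverageOrdering(
        position=pos, velocity=vel,
        position_ordered_seeds=okp, velocity_ordered_seeds=okv,
        n_seeds=len(list(seeds)),
    )


@dataclass
class PendulumLearning:
    random_return: float
    trained_returns: Dict[int, float]

    @property
    def ratios(self) -> Dict[int, float]:
        return {s: r / self.random_return for s, r in self.trained_returns.items()}


def random_policy_return(seed: int = 0, episodes: int = 500) -> float:
    """Mean episode return of uniform random excitation on the pendulum.

    Averaged over enough episodes that the estimate's own sampling noise is
    small relative to the quantity (the 500-episode mean is stable to ~1%).
    """
    env = MusclePendulumEnv()
    agent = RandomAgent(env.obs_dim, env.act_dim, seed)
    rng = np.random.default_rng(seed)
    rets = []
    for _ in range(episodes):
        obs = env.reset(seed=int(rng.integers(2**31 - 1)))
        done, total = False, 0.0
        while not done:
            obs, r, term, trunc, _ = env.step(agent.act(obs))
            total += r
            done = term or trunc
        rets.append(total)
    return float(np.mean(rets))


def pendulum_learning_benchmark(
    seeds: Sequence[int], total_steps: int = PENDULUM_STEPS
) -> PendulumLearning:
    """Train MPO per seed; report last-20%-of-episodes mean returns."""
    baseline = random_policy_return(seed=0)
    trained: Dict[int, float] = {}
    schedule = Schedule(
        "NonCurr", [Breakpoint(0, "balance", "adult")], total_steps=total_steps
    )
    for seed in seeds:
        result = train(
            lambda stage: MusclePendulumEnv(),
            schedule,
            pendulum_check_config(seed),
            seed=seed,
            total_steps=total_steps,
        )
        rets = np.asarray(result.episode_returns)
        tail = rets[int(0.8 * len(rets)):]
        trained[seed] = float(tail.mean())
    return PendulumLearning(random_return=baseline, trained_returns=trained)
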