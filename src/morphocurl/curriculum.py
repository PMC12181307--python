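"""Task and morphology scheduling: the double curriculum.

A :class:`Schedule` maps environment-step counts onto (task phase,
morphology stage) via ordered breakpoints with half-open intervals
[start, next_start).  Task phases advance balance -> walking -> running;
the morphology column switches from a child body to the adult mid-training
in the double curricula.

Named schedules (steps in units of 10^6):

==========  ===========================================================
NonCurr     running on the adult from step 0 (no curriculum)
AdultCurr   balance 0-2, walking 2-4, running from 4, adult throughout
OntoCurr    balance 0-2, walking 2-4, running 4-10 on Onto4y, then adult
UniCurr     same with Uni4y
2-4-8       double curriculum with the adult switch advanced to 8
3-6-12      phase increments of 3 instead of 2
4-8-16      phase increments of 4
2-4-8-12    adds the 12-year-old stage on steps 8-12 before the adult
OntoRand    running only, morphology redrawn per episode (ablation)
UniRand     same with uniform scaling
==========  ===========================================================

Per-episode target velocities: balance trains at 0; walking interleaves
{0, 1.2} m/s (balance keeps being rehearsed); running draws uniformly from
{0, 1.2, 1.75, 2.3, 2.85, 3.4} m/s.  Adult-scale targets are Froude-scaled
to the current morphology (v * sqrt(leg-length ratio)), one target per
episode.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from morphocurl.scaling import scale_target_velocity

PHASES = ("balance", "walking", "running")
WALKING_SPEED = 1.2      # m/s, adult scale
MAX_RUNNING_SPEED = 3.4  # m/s, adult scale
RUNNING_SPEEDS = (0.0, 1.2, 1.75, 2.3, 2.85, 3.4)

MILLION = 1_000_000
DEFAULT_TOTAL_STEPS = 60 * MILLION
DEFAULT_EPISODE_HORIZON = 1000

SCHEDULE_NAMES = (
    "NonCurr",
    "AdultCurr",
    "OntoCurr",
    "UniCurr",
    "2-4-8",
    "3-6-12",
    "4-8-16",
    "2-4-8-12",
    "OntoRand",
    "UniRand",
)


@dataclass(frozen=True)
class Breakpoint:
    step: int
    phase: str
    stage: str


@dataclass
class Schedule:
    """Curriculum timeline over environment steps."""

    name: str
    breakpoints: List[Breakpoint]
    total_steps: int

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("schedule needs at least one breakpoint")
        if self.breakpoints[0].step != 0:
            raise ValueError("first breakpoint must start at step 0")
        steps = [b.step for b in self.breakpoints]
        if any(s2 <= s1 for s1, s2 in zip(steps, steps[1:])):
            raise ValueError("breakpoint steps must be strictly increasing")
        for b in self.breakpoints:
            if b.phase not in PHASES:
                raise ValueError(f"unknown phase {b.phase!r}")
        if not self.name.endswith("Rand"):
            order = [PHASES.index(b.phase) for b in self.breakpoints]
            if any(b < a for a, b in zip(order, order[1:])):
                raise ValueError("phases may only advance balance->walking->running")

    @property
    def transition_steps(self) -> List[int]:
        return [b.step for b in self.breakpoints[1:]]


@dataclass(frozen=True)
class TaskSpec:
    """One episode's task: phase plus adult-scale and model-scale targets."""

    phase: str
    v_star_adult: float
    v_star_model: float


def _staged(name: str, incs: Sequence[int], stages: Sequence[str]) -> List[Breakpoint]:
    phases = ["balance", "walking", "running"] + ["running"] * (len(incs) - 2)
    steps = [0] + [i * MILLION for i in incs]
    return [Breakpoint(s, p, st) for s, p, st in zip(steps, phases, stages)]


def make_schedule(
    name: str,
    seed: Optional[int] = None,
    total_steps: int = DEFAULT_TOTAL_STEPS,
    family: str = "onto",
    episode_horizon: int = DEFAULT_EPISODE_HORIZON,
) -> Schedule:
    """Build a named schedule; ablation schedules take the morphology family.

    Random-morphology ablations redraw the stage per episode from a seeded
    generator, so their breakpoints tile the horizon.
    """
    if family not in ("onto", "uni"):
        raise ValueError("family must be 'onto' or 'uni'")
    child, child12 = f"{family}4y", f"{family}12y"
    if name == "NonCurr":
        bps = [Breakpoint(0, "running", "adult")]
    elif name == "AdultCurr":
        bps = _staged(name, [2, 4], ["adult"] * 3)
    elif name in ("OntoCurr", "UniCurr"):
        c = "onto4y" if name == "OntoCurr" else "uni4y"
        bps = _staged(name, [2, 4, 10], [c, c, c, "adult"])
    elif name == "2-4-8":
        bps = _staged(name, [2, 4, 8], [child, child, child, "adult"])
    elif name == "3-6-12":
        bps = _staged(name, [3, 6, 12], [child, child, child, "adult"])
    elif name == "4-8-16":
        bps = _staged(name, [4, 8, 16], [child, child, child, "adult"])
    elif name == "2-4-8-12":
        bps = _staged(name, [2, 4, 8, 12], [child, child, child, child12, "adult"])
    elif name in ("OntoRand", "UniRand"):
        c = "onto4y" if name == "OntoRand" else "uni4y"
        rng = np.random.default_rng(seed)
        stages = rng.choice([c, "adult"], size=max(1, total_steps // episode_horizon))
        bps = []
        prev = None
        for i, st in enumerate(stages):
            if st != prev:
                bps.append(Breakpoint(i * episode_horizon, "running", str(st)))
                prev = st
        if bps[0].step != 0:
            bps.insert(0, Breakpoint(0, "running", str(stages[0])))
    else:
        raise ValueError(f"unknown schedule {name!r}; valid names: {SCHEDULE_NAMES}")
    return Schedule(name=name, breakpoints=bps, total_steps=total_steps)


def phase_at(schedule: Schedule, env_steps: int) -> Tuple[str, str]:
    """(task phase, morphology stage) for the interval containing env_steps."""
    if env_steps < 0:
        raise ValueError("env_steps must be >= 0")
    steps = [b.step for b in schedule.breakpoints]
    i = bisect.bisect_right(steps, env_steps) - 1
    b = schedule.breakpoints[i]
    return b.phase, b.stage


def sample_target_velocity(
    phase: str, leg_ratio: float, rng: np.random.Generator
) -> TaskSpec:
    """Draw one episode's target; adult targets are Froude-scaled to the model."""
    if phase == "balance":
        v = 0.0
    elif phase == "walking":
        v = float(rng.choice([0.0, WALKING_SPEED]))
    elif phase == "running":
        v = float(rng.choice(RUNNING_SPEEDS))
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return TaskSpec(
        phase=phase,
        v_star_adult=v,
        v_star_model=scale_target_velocity(v, leg_ratio),
    )


def morphology_handover(learner, new_env) -> None:
    """Swap the learner's environment, retaining parameters and replay.

    The learner keeps its policy/value parameters and replay contents —
    normalized observations make old transitions approximately valid on the
    new body.  Raises if observation/action dimensionalities differ.
    """
    if learner.obs_dim != new_env.obs_dim or learner.act_dim != new_env.act_dim:
        raise ValueError(
            "observation/action schema mismatch across morphologies: "
            f"({learner.obs_dim}, {learner.act_dim}) vs "
            f"({new_env.obs_dim}, {new_env.act_dim})"
        )
    learner.set_environment(new_env)
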