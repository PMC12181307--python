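"""Experiment orchestration: configs, manifests, artifacts, structured logs.

``run_experiment`` executes one curriculum-training run and leaves a fully
traceable artifact directory::

    out_dir/
      manifest.json     config hash, seed, package version, status
      config.yaml       the exact configuration used
      events.jsonl      scheduler transitions (one JSON object per line)
      curve.csv         per-episode return, phase, morphology stage
      checkpoint.h5     final actor/critic weights

Re-running with an identical config and seed reproduces the metric files.
A directory whose manifest does not match the requested config (or cannot
be parsed) is refused rather than silently overwritten.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

import morphocurl
from morphocurl.curriculum import make_schedule
from morphocurl.envs import locomotion_env_factory, MusclePendulumEnv
from morphocurl.mpo import MPOConfig, train, save_agent


@dataclass
class ExperimentConfig:
    """One training run: schedule, environment, learner, seed."""

    schedule: str = "OntoCurr"
    total_steps: int = 100_000
    seed: int = 0
    environment: str = "biped"       # "biped" | "pendulum"
    learner: Dict = field(default_factory=dict)  # MPOConfig overrides
    out_dir: str = "runs/experiment"

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("out_dir")
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_experiment_config(path) -> ExperimentConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return ExperimentConfig(**doc)


class ManifestError(RuntimeError):
    pass


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the experiment and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
        except json.JSONDecodeError as e:
            raise ManifestError(
                f"{manifest_path} is corrupted; refusing to resume"
            ) from e
        if old.get("config_hash") != config.config_hash():
            raise ManifestError(
                f"{out} holds a different experiment "
                f"({old.get('config_hash')} != {config.config_hash()})"
            )
        if old.get("status") == "complete":
            return out

    with (out / "config.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": morphocurl.__version__,
        "status": "running",
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))

    mpo_cfg = MPOConfig(seed=config.seed, **config.learner)
    schedule = make_schedule(
        config.schedule, seed=config.seed, total_steps=config.total_steps
    )
    if config.environment == "biped":
        factory = locomotion_env_factory()
    elif config.environment == "pendulum":
        factory = lambda stage: MusclePendulumEnv()  # noqa: E731
    else:
        raise ValueError(f"unknown environment {config.environment!r}")

    result = train(
        factory, schedule, mpo_cfg, seed=config.seed, total_steps=config.total_steps
    )

    with (out / "events.jsonl").open("w", encoding="utf-8") as fh:
        for e in result.events:
            fh.write(json.dumps({"env_step": e.env_step, "kind": e.kind, "value": e.value}))
            fh.write("\n")
    pd.DataFrame(
        {
            "episode_return": result.episode_returns,
            "env_step": result.episode_steps,
            "phase": result.episode_phases,
            "stage": result.episode_stages,
        }
    ).to_csv(out / "curve.csv", index=False)
    save_agent(result.agent, out / "checkpoint.h5")

    manifest["status"] = "complete"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out
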