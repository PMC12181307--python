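# morphocurl

Bioinspired **morphology and task curricula** for learning bipedal
locomotion in muscle-actuated systems — a self-contained, desk-scale Python
framework with its own planar musculoskeletal simulator, exploration
analysis, reference RL learner, and robustness evaluation protocols.

## The problem

Learning locomotion with reinforcement learning is notoriously hard in
musculoskeletal bodies: muscles only pull, so every joint needs coordinated
agonist–antagonist control; the system is over-actuated (more muscles than
degrees of freedom); and activation acts as a chemical low-pass filter that
swallows short control twitches.  Inspired by human motor development, the
approach implemented here attacks the *exploration* problem through the
body itself: training starts on a scaled-down child morphology whose
disproportionately light legs make exploratory movement cheap, progresses
through a task curriculum (balance → walking → running), and hands the
policy over to the adult body mid-training.  The package is for researchers
in computational biomechanics and motor-control RL who want a transparent,
CPU-scale testbed for curriculum and morphology effects.

## What's inside

* **Morphologies** — a planar sagittal biped (pelvis, head-torso, 2 ×
  {thigh, shank, foot}; 11 Hill-type muscles per leg; 3 Hunt–Crossley
  contact points per foot, stiffness 11006.4 N/m) as validated YAML, plus
  ontogenetically (Onto4y/Onto12y) and uniformly (Uni4y/Uni12y) scaled
  children generated by the scaling module.
* **Scaling laws** — per-segment or uniform geometric scaling with
  mass-redistribution tables; muscle forces scale with body weight and
  stiffnesses keep their dimensionless values so that Hof-normalized
  mechanics (F/mg, l/l0, v/√(g l0), ω/√(g/l0)) are stage-invariant, and
  target velocities scale at equal Froude number v²/(g l0).
* **Simulator** — generalized-coordinate rigid-body dynamics with muscle
  path actuators, compliant contact, joint stops; semi-implicit Euler with
  a numba-compiled inner loop; 100 Hz control, 1000-step episodes.
* **Rewards/observations** — every component is R = exp(−k((a*−a)/s)²)
  with Hof scales s; balance sums four components, gait scores
  3.5·R_forward + 0.5·R_lateral with k_forward = 10√l/v*; both branches
  peak at 4.0.
* **Curricula** — the named schedules (NonCurr, AdultCurr, OntoCurr,
  UniCurr, 2-4-8, 3-6-12, 4-8-16, 2-4-8-12, OntoRand, UniRand) with
  half-open step intervals and exact-step transitions.
* **Exploration analysis** — the fixed-pelvis/one-leg white-noise toy
  experiment with occupancy-grid workspace coverage, plus a differential
  extrinsic plasticity (DEP) baseline, τĊ = l̇ₜ l̇ₜ₋Δₜᵀ − C.
* **Learner** — a minimal numpy MPO (KL-constrained E-step via convex dual,
  trust-region M-step, TD critic) behind a pluggable
  act/observe/update interface.
* **Evaluation** — velocity errors, a perturbation-force ladder (pushes
  every 4 s lasting 1 s, alternating direction), 100/700/200-step velocity
  ramps, and heel-strike-segmented gait metrics.

## Worked example

Compare how much of its normalized workspace each body explores under pure
white-noise excitation (the conceptual experiment behind the morphological
curriculum):

```bash
morphocurl explore --model onto4y --seed 0 --episodes 5 --steps 1000 --out cov.csv
```

prints (alongside the CSV):

```json
{
  "stage": "onto4y",
  "occupancy_fraction_position": 0.0088,
  "occupancy_fraction_velocity": 0.0876,
  "n_samples": 5000
}
```

against `--model adult` with the same seed, which yields
`occupancy_fraction_position: 0.0024` and
`occupancy_fraction_velocity: 0.0124`: the ontogenetically scaled
4-year-old's swinging foot visits ~3.7× more position cells and ~7× more
velocity cells of the Hof-normalized grid, because its legs are the
lightest relative to its muscle strength.  The mass redistribution behind
that, from the library:

```python
>>> from morphocurl import bundled_morphology, summarize_morphology
>>> summarize_morphology(bundled_morphology("onto4y"), bundled_morphology("adult"))
           mass  mass_fraction  ref_mass_fraction  length  length_ratio
segment
pelvis   2.3925          0.145             0.1420  0.1044          0.58
torso    9.6525          0.585             0.5360  0.3720          0.62
thigh_l  1.3530          0.082             0.1000  0.2293          0.52
...
```

— the child carries 58.5% of its mass in the torso (adult: 53.6%) and only
27% in the legs.  Curriculum training runs through the same interface:

```bash
morphocurl train --schedule OntoCurr --seed 0 --total-steps 100000 --out runs/demo
morphocurl report --run runs/demo
```

which writes a manifest, scheduler event log, per-episode return curve, and
policy checkpoint.

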