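# Methods

`morphocurl` studies how body morphology shapes the learning of bipedal
locomotion in muscle-actuated systems.  It couples a planar musculoskeletal
simulator with a double curriculum — a *morphological* curriculum that
starts training on a biologically scaled-down child body and hands the
policy over to the adult body mid-training, and a *task* curriculum that
progresses balance → walking → running — plus the analysis tooling needed
to quantify exploration, learning, and robustness.  This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## The musculoskeletal model

The body is a planar sagittal biped: a floating-base pelvis, a welded
head-torso segment, and three segments per leg (thigh, shank, foot), nine
mechanical degrees of freedom in total (3 base + 6 revolute joints).  Each
leg carries eleven Hill-type muscle-tendon units spanning hip, knee, and
ankle; two of them (adductor, abductor) are placeholders for the
frontal-plane muscles of a 3-D body, given small sagittal moment arms and
disabled in constrained setups.  Muscles are routed as straight line
segments with optional via points; moment arms follow from the path
geometry.

Adult segment lengths, masses, and radii of gyration follow classic adult
gait-analysis anthropometry (1.80 m, 75 kg, leg length l0 = 0.95 m).  Two
deliberate geometry choices:

* the hip joints sit 5 cm behind the pelvis center, because humans stand
  with the ankle behind the body-COM line; with the hips on the body axis
  the flat-foot center of pressure lies ~9 cm ahead of the COM and every
  standing pose tips backward;
* maximal isometric forces are chosen for **agonist–antagonist torque
  balance** at the reference posture under uniform activation (net hip and
  knee torque ≈ 0, ankle moderately plantar-biased) rather than copied per
  muscle from human strength tables.  With literature per-muscle strengths
  the net torque biases pin the unloaded limb against its joint stops for
  entire rollouts — a degenerate regime in which neither exploration nor
  control is meaningful.  The over-actuated agonist/antagonist structure is
  preserved; only the strength ratios differ from any specific human
  dataset.

Hill curves: Gaussian active force–length (width 0.45, peak at normalized
length 1), hyperbolic force–velocity (zero at maximal shortening, 10
optimal fiber lengths/s; eccentric plateau 1.5 with the eccentric branch
slope-matched to the concentric branch at zero velocity — C1 continuity
keeps the effective small-motion damping finite and the explicit integrator
stable), exponential passive element engaging above optimal length.  The
tendon is rigid: fiber length is path length minus tendon slack, with slack
set so every fiber sits at optimal length in quiet standing.  Activation is
a first-order low-pass of excitation with τ_act = 10 ms and τ_deact = 40 ms
(standard biomechanics values), integrated exactly per control step.
Muscles only pull; total force is clamped at zero.

## Contact, joints, integration

Ground contact acts at three spherical points per foot (one heel, two
forefoot) through a Hunt–Crossley normal force

    N = max(0, k δ^p (1 + c_d δ̇)),   k = 11006.4 N/m, p = 1, c_d = 1,

with a regularized Coulomb friction cone (static 0.9, dynamic 0.8,
viscous 0.6 s/m, tanh regularization velocity 0.01 m/s) capped at
μ_s N + μ_v |v_t| N.  The dissipative multiplier c_d is dimensionless per
unit penetration rate; this reading of the printed "damping 1 N m⁻¹"
(dimensionally a stiffness) is pinned here deliberately.  Revolute joints
carry soft range stops (1000 N·m/rad beyond the physiological range,
physiological passive stops being very stiff) and light in-range viscous
damping (1 N·m·s/rad).

Dynamics are integrated in generalized coordinates (mass matrix from body
Jacobians, centripetal bias terms, gravity, muscle/contact/stop generalized
forces) with semi-implicit Euler at 10 physics substeps per 10 ms control
step; the episode horizon is 1000 steps = 10 s at 100 Hz.  The constrained
toy setups use 20 substeps: the isometric force–velocity slope acts as a
stiff damper under explicit integration and the lighter constrained leg
needs the shorter step.  Rollouts are pure functions of (model, initial
state, excitation sequence).

Falls are declared when the torso COM drops below 0.6 l0 or |torso pitch|
exceeds 60° (strict inequality at the boundary); neither threshold is
prescribed anywhere, both are documented defaults.  Initial states are the
standing posture with seeded joint jitter (σ = 0.5°) and the base preloaded
by the static contact penetration.

A caveat worth stating: passive upright standing of this model is
statically unstable — the rotational contact stiffness k·Σx² almost exactly
cancels the gravitational destabilization m·g·h, and toe lift-off removes
the margin.  That matches human physiology (quiet stance requires active
ankle torque) and is why the static-equilibrium regression test uses a
"standing frame" configuration (base translation/rotation constrained,
height free): it isolates contact statics, which hold body weight exactly.

## Scaling between developmental stages

Child bodies derive from the adult in two modes.  **Uniform** scaling
multiplies every length by one height ratio and keeps the adult's mass
fractions; **ontogenetic** scaling applies per-segment length ratios and an
age-specific mass-fraction table (heavier torso, lighter legs for the
4-year-old).  The bundled anthropometric tables emulate published child
anthropometry; they are editable data files, not a reproduction of any
specific table:

| stage  | height ratio(s)            | mass  | leg length |
|--------|----------------------------|-------|------------|
| uni4y  | 0.572 (all)                | 16.5  | 0.543 m    |
| onto4y | torso 0.62 … legs 0.52     | 16.5  | 0.498 m    |
| uni12y | 0.828 (all)                | 40.0  | 0.787 m    |
| onto12y| torso 0.84 … legs 0.81     | 40.0  | 0.770 m    |

Both 4-year-old variants share one total mass (and likewise at 12), so the
variants differ only in proportions and mass distribution.  Derived
quantities scale so that Hof-normalized mechanics are stage-invariant:

* moments of inertia as I·(m_new/m_old)·(L_new/L_old)²;
* optimal fiber and tendon slack lengths with the reference-posture length
  of the spanned path;
* maximal muscle force with body weight (F̂ = F/mg invariant); a
  configurable extra length exponent is exposed for other mass–length laws;
* translational stiffness preserving k·l0/(m·g) (so k_child =
  k_adult·m_ratio/l_ratio), torsional stiffness preserving k/(m·g·l0);
  a flag switches to constant absolute stiffness instead;
* velocity-bearing coefficients (Hunt–Crossley c_d, viscous friction,
  friction regularization velocity, joint damping) preserving their
  dimensionless forms;
* target velocities by √(leg-length ratio), i.e. equal Froude number
  v²/(g·l0).

The operational check of all this is a drop test: a uniformly scaled body
released from the scaled height, integrated at the Froude-scaled time step,
retraces the adult's normalized COM trajectory to ~1e-4.  Exact similarity
holds for passive mechanics only: activation time constants, the control
rate, and maximal fiber velocity are fixed in absolute units, which is
physiologically right (they are tissue properties, not geometry) and is
precisely why differently sized bodies explore differently.

## Hof normalization, observations, rewards

All learner-facing quantities are rendered dimensionless with Hof's gait
scales: F̂ = F/mg, l̂ = l/l0, v̂ = v/√(g l0), ω̂ = ω/√(g/l0); angles pass
through in radians (already dimensionless).  The observation bundles muscle
length/velocity/force, torso orientation and angular velocity, joint angles
and angular velocities, left/right vertical ground reaction force, and the
normalized target errors (forward/vertical velocity, lateral position); its
dimensionality is identical across all bundled morphologies, which is what
makes the mid-training morphology handover possible.

Every reward component is R = exp(−k((a*−a)/s)²) with s the Hof scale of
the quantity (√(g l0) for velocities, l0 for positions, 1 for orientation).
Balance (v* = 0) sums four unit-weight components (forward velocity,
vertical velocity, lateral position, torso orientation; all targets zero —
vertical-velocity and orientation targets are taken as 0/upright where they
are left implicit); gait scores 3.5·R_forward + 0.5·R_lateral, so both
branches share the maximum 4.0.  Balance sensitivities are 500, the lateral
gait sensitivity 10, and the forward gait sensitivity is recomputed per
morphology as k = 10√l/v* with l the leg-length ratio and v* the
Froude-scaled target — which makes it stage-invariant.  In the planar model
the lateral channel is degenerate (R_lateral ≡ 1, error ≡ 0) and is kept in
the schema for 3-D forward compatibility.

## Curricula

Schedules map environment steps to (task phase, morphology) through
half-open breakpoint intervals.  The main double curricula switch balance →
walking at 2×10⁶ steps, walking → running at 4×10⁶, and child → adult at
10×10⁶; ablations move these to 2-4-8, 3-6-12, 4-8-16, and 2-4-8-12 (the
last inserting the 12-year-old on steps 8–12×10⁶).  Random-morphology
ablations redraw the stage each episode from a seeded generator and train
running only.  Per episode the walking phase interleaves {0, 1.2} m/s
uniformly (balance keeps being rehearsed; the phase description leaves this
open) and the running phase draws uniformly from
{0, 1.2, 1.75, 2.3, 2.85, 3.4} m/s — a discrete grid standing in for
"different speeds up to 3.4" — always one Froude-scaled target per episode.
At a morphology switch the learner keeps its parameters and replay
(normalized observations keep old transitions approximately valid); a flag
can flush the replay instead.

## The reference learner

The learner is a minimal MPO: one-step TD critic with Polyak target
network; an E-step that reweights 20 per-state policy samples by
exp(Q/η*), with the temperature from a bounded scalar minimization of the
convex dual; an M-step fitting the Gaussian policy (two 256-unit ReLU
hidden layers, state-independent diagonal covariance) to the weighted
samples under a KL trust region enforced by backtracking toward the old
policy.  Networks, backprop, and Adam are plain numpy.  Defaults: replay
10⁶, batch 256, 10⁶ initial random steps, 30 batches every 1000 steps,
1-step returns, learning rates 3·10⁻⁴ (actor, critic) and 10⁻² (dual),
ε = 0.1.  Divergences from full MPO, on purpose: a single KL constraint
instead of decoupled mean/covariance constraints, and a single-process
loop with the same data-collection ratio instead of parallel actors.
Actions are muscle excitations on [0, 1]; the policy's samples are clipped
to that box everywhere, including inside the E-step, so the critic is
never queried off-support (unbounded action queries otherwise produce the
classic extrapolation-runaway divergence).  The training loop only needs
``act``/``observe``/``update``/``set_environment``, so any learner with
that surface can replace MPO.

## Synthetic-data generators and what they show

**Workspace-coverage toy experiment.**  Pelvis fixed, one leg immobilized,
frontal placeholders disabled, i.i.d. uniform white-noise excitations per
muscle per 10 ms control step on the nine sagittal muscles of the free leg;
50 episodes of 1000 steps per body.  The noise amplitude (nowhere
prescribed) defaults to 0.3: at amplitude 1.0 every morphology is driven
stop-to-stop, a ceiling regime in which coverage measures joint-range
geometry rather than dynamics.  Coverage is the occupancy fraction of the
Hof-normalized foot-COM position (±1.25 l0) and velocity (±0.25 √(g l0))
on a fixed 50×50 grid, plus convex-hull areas; the bounds are sized to the
operating regime and identical for every stage.  Under these conditions
the ordering Onto4y > Uni4y > adult holds in both position and velocity
occupancy in 5 of 5 seeds.  The mechanism is the one the morphological
curriculum exploits: muscle strength scales with body weight while leg
inertia scales with leg mass × length², so the ontogenetic child's
disproportionately light legs accelerate hardest per normalized unit.
What this does *not* show: 3-D exploration, or coverage under any
particular real toddler's noise statistics.

**One-muscle pendulum.**  The scaled-down learning check uses a rod that
balances at a 0.15 rad lean where gravity (pulling it over) must be matched
by a single pull-only muscle (moment arm 5 cm, F_max 400 N, with the
standard activation low-pass); overpulling past vertical is unrecoverable.
A graded policy holds the target (a hand PD controller scores ~195/200);
uniform random excitation scores ~16.  Under the frozen check conditions
(50k steps, 128-unit networks, 25 batches per 250 steps, Polyak 0.02) MPO
exceeds three times the random return on all three seeds.  This validates
the learner loop end to end at desk scale; it says nothing about gait
quality on the full biped, which at the reference scale (6×10⁷ steps) is
outside this package's compute envelope by design.

**Gait metrics.**  Cycle segmentation triggers on the vertical GRF rising
through 5% body weight (heel strike); cycles are resampled to 101 points
and pooled over both legs in a trailing 10 s window.  The synthetic gait
used in tests is sinusoidal and antiphased — it validates the bookkeeping,
not any physiological GRF shape.

## Evaluation protocols

Robustness pushes act at the torso COM: onsets at t = k·4 s (k ≥ 1), each
lasting 1 s, direction alternating after a seeded initial sign.  The
maximum withstood force is found by a ladder search in 5 N increments
(monotone, matching "maximum withstood" semantics) rather than bisection.
In the planar model only the sagittal (x) axis exists; requesting z raises.
Velocity ramps are 1000-step target traces: up = 100 steps at 0, linear
1.2 → 3.4 over 700, 200 at 3.4; down = 100 at 3.4, linear down to 1.2 over
700, then an abrupt drop to 0 for 200 — deliberately not mirror images.
Balance velocity error is mean |v_x| divided by the achieved
episode-length fraction (early falls are penalized); gait error is mean
|v_x − v*|/v*.

## Numerical choices and limitations

* Explicit (semi-implicit Euler) integration bounds the stable step through
  the muscle force–velocity slope and contact stiffness; 1 ms substeps for
  the full biped, 0.5 ms for the constrained toy.
* The physics inner loop is compiled with numba around precomputed
  per-body origin Jacobians over active-DOF lists (~10 µs per substep).
* The E-step dual is minimized over log η ∈ [−10, 10] to a 1e-8 bracket.
* Equal-Q E-steps give exactly uniform weights; weights are normalized per
  state and always a proper distribution.
* Limitations: planar dynamics only (no frontal-plane balance, no z-axis
  perturbations), no wrapping surfaces or toe joint, rigid tendon by
  default, no energy/symmetry/pain reward terms, no terrain generation,
  and no attempt to reproduce reference-scale reward magnitudes or
  perturbation forces, which require orders of magnitude more training
  compute than the desk-scale checks bundled here.

## Reproduction script

`scripts/acceptance.py --seed S --out results.json` recomputes every
headline quantity from scratch and reports it with the problem size used.
The deterministic checks run at full precision; the stochastic studies run
at reproduction scale chosen to keep the script within a few CPU-minutes:
the coverage ordering uses 3 seeds × 25 episodes × 1000 steps per
morphology (the test suite runs the full 5 × 50 protocol), and the
pendulum learning check trains one seed for the full 50k steps against the
500-episode random baseline.  All randomness derives from `--seed`.
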