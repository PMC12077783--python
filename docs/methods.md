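# Methods

## Model

`cohesim` simulates a one-dimensional cluster of N identical spherical cells
(radius r = 1, mass m = 1) on the axis of an external chemical gradient. All
quantities are in computational units: lengths in cell radii, time in
timesteps (dt = 1), speeds reported in mr/τ = 10⁻³ radii per timestep. The
cells start at rest on a just-touching lattice, x_i = 2r·(i−1), with cell 1
trailing and cell N leading.

### Bonds

Nearest neighbors interact through a viscoelastic bond whose strain variable
is the surface-to-surface gap g = x_{i+1} − x_i − 2r; g = 0 (just touching)
is the zero-stress rest state. Two standard rheologies are implemented:

* **Kelvin–Voigt (KV)**: σ = K·g + η_i·ġ (spring and dashpot in parallel; no
  creep).
* **Standard Linear Solid (SLS)**: the Maxwell form
  σ + τ·σ̇ = K₁·g + τ·(K₁+K₂)·ġ, integrated as a third-order equation for
  the bond displacement whose acceleration memory carries the stress
  (σ = −g̈_bond). A sudden strain step Δg produces the unrelaxed stress
  response (K₁+K₂)·Δg, which then relaxes toward the K₁·g plateau with time
  constant τ = η/K₂. As τ → 0 at fixed η the SLS bond reduces exactly to the
  KV bond with the same moduli (a property-tested invariant).

The elastic modulus switches with the sign of the strain: the tensile
(cohesive) stiffness Kₐ acts only under separation, the compressive
stiffness K_r only under overlap; at any instant exactly one is active. A
bond whose gap exceeds the detection distance `zone_max` is detached and
exerts no force (its SLS stress memory decays freely). Each bond applies its
full stress, with opposite signs, to its two member cells, so internal
forces conserve momentum exactly.

The **cohesion gradient** enters through the tensile stiffnesses of the N−1
bonds, linearly spaced from K_min (trailing) to
K_max = gradient_strength · K_min (leading). A per-agent assignment (bond
stiffness = leading member's value) is available as a configuration
alternative; the bond-midpoint assignment is the default because it makes
the action–reaction pairing unambiguous.

### Time stepping

Each timestep advances the coupled system with one classical RK4 step
(no sub-stepping), then applies environmental damping: every velocity — and,
for SLS, every bond acceleration memory — is multiplied by the retention
factor η_env. η_env = 0 is the overdamped Stokes limit used for KV runs;
SLS runs retain 75% (η_env = 0.75), since part of their dissipation is
internal creep. Strong damping is what makes dt = 1 stable at the default
stiffnesses; a stability check aborts with the offending timestep if any
position or velocity becomes non-finite.

### Protrusions

Every T-th step ("protrusion period") the selected cells attempt an
instantaneous displacement before that step's relaxation:

* **Stochastic modes** draw a signed length from N(0, σ²)
  (σ = "protrusion amplitude"). `ends_only` lets only cells 1 and N
  protrude; `all_cells` lets every cell protrude at full σ; `hybrid` keeps
  the ends at σ and scales interior cells by `interior_scale` (default 0.25,
  i.e. interior wandering suppressed by 75%).
* **Deterministic modes** displace the two end cells by a fixed length:
  `outward_step` (both away from the center each event),
  `inphase_oscillation` (both in the same direction, alternating), and
  `antiphase_oscillation` (alternately both outward / both inward).

A proposal that would bring a cell within one diameter of a neighbor is
**rejected** — the cell does not move at all. The same rule applies to the
deterministic modes. Simultaneous proposals are drawn for all protruders and
validated trailing-to-leading against already-updated positions. A tie
(landing exactly just-touching) is accepted.

A protrusion event kinematically repositions the overdamped cluster: all
velocities are reset at the event. Combined with momentum-conserving
internal forces this gives the model a clean bookkeeping property: **the
center of mass moves only through accepted protrusion displacements** —
relaxation redistributes the cells but provably never moves their mean. The
deterministic controls are consequently stationary to machine precision, and
directed migration can only arise from asymmetric acceptance of stochastic
steps. For SLS, a jump also adds the unrelaxed stress increment (K₁+K₂)·Δg
to the affected bonds (a bond crossing the detachment distance instead
resets its memory).

## Default parameters and how they were set

| parameter | default | meaning |
|---|---|---|
| N | 5 | cluster size |
| gradient_strength | 10 | K_max / K_min |
| K_min | 0.0022 | trailing tensile stiffness |
| K_r | 1.0 | compressive stiffness (uniform) |
| zone_max | 4.0 | detachment gap, radii |
| η_i | 0.1 | bond viscosity (KV) |
| K₂, τ | 0.01, 10 | SLS series spring and relaxation time (η = K₂τ = 0.1) |
| η_env | 0 (KV) / 0.75 (SLS) | velocity retention per step |
| σ, T | 0.5, 15 | protrusion amplitude and period (sweep baseline) |
| n_steps | 2000 | run length |

The damping convention encodes "velocities reduced by 100% (KV) / 25% (SLS)
per step" as a retention factor, with 0 the purely viscous limit.

The stiffness scale is not derivable from first principles, and the
reference study the model reproduces does not state its values, so it was
calibrated **once** against the single published reference speed
(2.0 ± 0.1 mr/τ for gradient 10, N = 5, σ = 1, T = 5) and frozen. The
calibration has a physical reading: the reference speed selects a regime in
which the *leading* bond relaxes over a few tens of timesteps (several
protrusion periods) while the *trailing* bond is so weak (relaxation ≳ 10³
steps) that the trailing cell wanders almost independently of the cluster —
visible in reference trajectories as a nearly free random walk of the last
cell. A stiffer scale that also reproduces the reference speed exists
(K_min ≈ 0.25, with relaxation complete within each period), but in that
regime all parameter-sweep speeds collapse below the ensemble noise floor
and the trailing cell stays locked to the cluster. With the compliant
default, both rheologies reproduce the reference speed (KV 1.94 ± 0.20, SLS
2.06 ± 0.19 at 100 replicates), consistent with the observation that the
choice of rheology does not change the phenomenon. The shared dashpot
η = 0.1 couples the two models' parameterizations (τ = η/K₂).

## Analysis procedures

* **Cluster speed**: per replicate, the ordinary least-squares slope of the
  center-of-mass series against time over the full run (a configurable
  burn-in is available but defaults to zero); reported as the mean ± standard
  error over replicates, in mr/τ.
* **Ensemble MSD**: MSD(t) = mean over replicates of (com(t) − com(0))².
  This from-origin estimator carries ≈ √(2/R) correlated relative noise at
  every lag for R replicates (≈ 14% at R = 100). Through-origin fits a·t
  (diffusive) or a·t + b·t² (directed) exclude lag 0; R² is computed against
  the uncentered total sum of squares (a centered R² of the same curve is
  also reported). The headline fits restrict to the **initial 10% of lags**
  (`fit_msd(..., max_lag=...)`), the customary MSD practice, because
  large-lag from-origin estimates are statistically unreliable: at 100
  replicates the null (no-gradient) linear fit reaches R² ≈ 0.994–0.996 on
  the initial window versus ≈ 0.98 over the full range, while the directed
  ensemble's quadratic fit exceeds 0.99 with either window.
* **Chemotactic index**: net displacement along the axis divided by total
  path length, in [−1, 1].

## Experiments

`experiments` packages the study designs: the reference migration run
(gradient 10 vs 1; σ = 1, T = 5), the MSD regime comparison (T = 15), four
one-parameter sweeps (gradient strength, N, σ, T; 100 replicates per value;
per-replicate speed distributions retained for violin-style summaries), the
protruder-selection scenarios (ends-only / all-cells / hybrid at matched
parameters, SLS), and the deterministic controls. Replicate i of any
ensemble uses an independent PCG64 generator seeded base_seed + i; ensembles
are integrated as one vectorized system, and a single run is bit-identical
to the corresponding ensemble row.

Observed behaviors at the defaults, all asserted by the test suite:

* speed rises from ≈ 0 at gradient 1 toward an asymptote at large gradient;
* mean speed follows c/N across N = 3…10 (both rheologies, R² ≈ 0.98);
* speed grows monotonically with σ and falls monotonically with T;
* ends-only > hybrid > all-cells at matched parameters — interior wandering
  interferes with migration, and suppressing it by 75% rescues most of the
  ends-only speed (the ends-only/hybrid separation is a ~4% effect,
  resolvable at ≈ 2000 replicates);
* the all-cells mode does not migrate: its speed is consistent with zero at
  100 replicates and is at most a few percent of the ends-only speed
  (slightly negative) at high replication.

### Deterministic controls and their regime

The deterministic protocols are controls built on the premise that the
cluster returns to its just-touching rest state within every forcing period.
`run_deterministic_baseline` therefore uses the stiffer control scale
(K_min = 0.1 by default), under which every inward leg is rejected
identically at both ends once transients decay and the center of mass is
exactly stationary — the asymptotic drift, measured at matched forcing phase
over whole cycles, is zero to floating-point precision for every submode,
gradient and rheology. Outside that premise the control is *not* inert: in
the compliant migration regime, incomplete relaxation lets the
overlap-rejection rule rectify even the inphase periodic forcing into a
small drift (~2 × 10⁻³ radii/step at gradient 10) by the same acceptance
asymmetry that drives stochastic migration. This is a genuine model behavior
worth knowing about, not a numerical artifact.

## Numerical choices and degenerate inputs

* RK4 once per dt on the full coupled system; positions recorded every step.
* Blow-up (non-finite state) raises immediately with the offending timestep;
  sweep errors are annotated with the parameter value, replicate and seed.
* Non-overlap: accepted protrusions can never create overlap (rejection
  rule, tie-to-accept at exact contact). KV trajectories additionally never
  overlap dynamically at the defaults. SLS velocity retention can overshoot
  relaxation into transient compressions of up to a few hundredths of a
  radius, which the repulsive modulus resolves within a few steps; tests
  bound these transients at 0.1 r.
* A protrusion period ≥ n_steps produces a warning and a protrusion-free
  (pure relaxation) run. N = 2 has a single bond and hence no gradient; it
  migrates randomly. The truncated-mean closed form uses its series limit
  Δ/2 for Δ/σ < 10⁻⁸ to avoid 0/0.
* Gradient strengths far above the defaults (K_max ≳ 3 for KV at dt = 1, or
  with damping disabled) are outside the stable envelope; the stability
  check reports rather than silently corrupts such runs.

## What the generator emulates — and what it does not

The simulator generates all study inputs itself; there is no external data.
It emulates: differential cadherin-mediated cohesion as a static linear
stiffness gradient; protrusion formation as instantaneous, unpolarized
Gaussian repositioning with steric rejection; and a very viscous
environment. It does **not** emulate: 2D/3D geometry (motion is strictly
along the gradient axis), chemoattractant field dynamics (the gradient never
evolves or depletes), biochemical signalling or polarization feedback,
cell division, substrate adhesion heterogeneity, or gradation of the SLS
series spring along the cluster (only the parallel tensile spring is
graded). Passing tests therefore demonstrate the internal consistency of the
mechanism — rectified noise plus cohesion asymmetry produces directed
motion with the predicted parameter dependences — not quantitative agreement
with any particular cell type.

## Known limitations

* The stiffness scale is calibrated to one published speed; absolute speeds
  at other parameter combinations are predictions of the calibrated model,
  not independently validated quantities.
* The closed-form speed is an upper envelope with no finite-cohesion
  correction; simulated speeds approach it only in the strong-gradient,
  free-trailing limit.
* The speed-vs-amplitude trend at very short periods (T ≈ 5) flattens, as
  collisions between protrusion and incomplete relaxation become frequent;
  sweeps therefore default to T = 15.
* Deterministic forcing is only guaranteed inert in the full-relaxation
  regime (see above).
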