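# Methods

## The model

The package represents a C2-C6 cervical spine specimen as five rigid
vertebral bodies coupled by four six-degree-of-freedom viscoelastic bushing
elements (Kelvin-Voigt: a linear spring and damper in parallel per
component).  Each joint frame sits at the centre of the intervertebral
mid-plane; its y-axis is normal to the superior surface of the caudal
vertebra (superior-inferior), x points anteriorly and z completes a
right-handed triad.  The bushing wrench on the cranial body is

    F_i = -k_i d_i - b_i d'_i,   i in {x, y, z, rx, ry, rz},

evaluated in the joint frame, with the equal-and-opposite reaction applied
to the caudal body at the joint origin.  Because bushings are force
elements, the equations of motion decouple per body: each free body obeys
the Newton-Euler equations under gravity, the constant preload, the two
adjacent bushing wrenches and the applied drive force.

The experimental mounting is reproduced by constraints: C6 is fixed, C2
rides an axial slider (one translational DoF), C3-C5 are free.  The 152 N
preload is the sum of two constant-force springs (102 N) and the
impact-plate weight (50 N); the 5.10 kg plate mass additionally rides with
C2's translation.  Gravity on the vertebral masses is included by default
and switchable (`SpecimenModel.include_gravity`); over a 5 ms window its
effect is negligible but its cost is zero.

Simplifications, stated as such:

* Rotations are parameterised as body-fixed X-Y-Z Euler-angle deviations
  from each body's rest orientation.  The gyroscopic term and the
  Euler-rate/angular-velocity distinction are dropped - second-order in
  the sub-degree rotations occurring within the simulated windows.
* Segment inertia uses a solid-cylinder approximation (default radius
  15 mm, per-vertebra height from the geometry); only order of magnitude
  matters because rotational dynamics are dominated by the bushing lever
  arms.
* Specimen mass is split equally across vertebrae by default
  (configurable weights); only the total is reported for real specimens.

## Numerics

* **Integrator**: fixed-step classical RK4 at 1 microsecond (5000 steps per
  5 ms window), compiled with numba.  The stiffest identified mode
  (k ~ 3e7 N/m on ~0.08 kg) has omega*h ~ 0.02, far inside the stability
  region; a step-halving test bounds the discretisation error of final
  marker positions below 1e-8 m.  States that leave a guard box (1 m,
  1 rad) or go non-finite mark the run as diverged.
* **Initial condition**: static equilibrium under preload, found by a
  Newton-type root solve (`scipy.optimize.root`, hybr) on the free
  coordinates with the same force evaluation the integrator uses.
* **Divergence handling in search**: inside the identification loop a
  diverging simulation returns a finite penalty (1e6 mm) instead of
  raising, because uniform sampling of the search box does visit unstable
  corners (very large damping against tiny rotational inertia).
* **Filtering**: "zero-lag fourth-order Butterworth" is read as net fourth
  order - a second-order design applied forward and backward
  (`net_order=False` recovers the per-pass reading).  Edges use reflective
  padding of at least three filter lengths.
* **Onset**: first sample strictly exceeding 200 N above the pre-impact
  baseline, where the baseline is the median of the leading 10 ms
  truncated at the first raw threshold crossing.  Referencing the
  threshold to the baseline keeps the 152 N preload from interacting with
  the 200 N criterion.
* **Windowing**: force windows are half-open `[onset, onset + 5 ms)` at
  the force rate; marker windows keep every frame whose timestamp falls in
  the closed window (21 frames at 4 kHz when the onset lands on a frame).

## Parameter identification

Sixteen parameters - axial and shear stiffness and damping per joint -
minimise the RMS Euclidean distance between measured and simulated marker
positions pooled over the 15 markers and all window frames, reported in
mm.  Genes are log10-encoded; default bounds (axial k 1e5-1e8 N/m, shear k
1e3-1e6 N/m, dampings 10-1e5 Ns/m) bracket the literature initialisation
and all identified values.

The search has two parts:

1. **Genetic stage** - tournament selection (size 3), blend crossover
   (alpha 0.5, rate 0.9), per-gene Gaussian mutation (sigma 0.1 log units,
   rate 0.2), elitism 1.  The literature-initialised individual is seeded
   into generation 0, which guarantees the identified optimum is never
   worse than the initialisation.  Study-scale budget: population 100 over
   15 generations.
2. **Refinement stage** - a covariance-adapting evolution strategy
   (CMA-ES, package-authored) run in two seeded phases under one
   evaluation budget (`refine_evals`, default 13000): a broad full-space
   basin search (sigma 0.5 log units, population 32, 40 % of the budget)
   followed by a deep polish (sigma 0.12, population 16, the rest).  The
   objective's landscape has long curved valleys in which stiffness and
   damping errors compensate across joints; fixed-operator genetic search
   stalls on their floors (tracking errors of 0.1-0.5 mm), whereas
   covariance adaptation follows them to the optimum.  Refinement stops
   early below a target tracking error (default 1e-5 mm, the level at
   which every parameter is pinned well inside the recovery tolerances on
   noise-free data).

All stages draw from seeds derived from the single configured seed;
identical configuration and inputs give bit-identical results.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed and acceptance surface.  It
emulates: specimen mass/height drawn from the reference cohort's
descriptive statistics (Normal(0.390, 0.033) kg, Normal(0.204, 0.006) m,
truncated positive); a stacked parametric geometry whose mid-plane sagittal
tilts increase caudally (2, 4, 6, 10 degrees) so the caudal-most joint sees
the axial load at the largest shear angle - the geometric mechanism behind
the low identified C5-C6 axial stiffness; ground-truth parameters drawn
log-uniform within the span of the identified reference values per degree
of freedom; a haversine drive pulse (default peak 3.5 kN, rise 2.5 ms,
within the measured 3.0-4.8 kN range) atop the 152 N baseline at 1 MHz;
15 tracking markers (4 per cluster on C3/C4/C5 on 25 mm posterior lever
arms, 3 cranial-pot markers) at 4 kHz with isotropic Gaussian noise
(default SD 0.3 mm, the order of the motion-capture calibration error).

It does not emulate: soft-tissue artifact or cluster-lever-arm resonance,
marker gaps or relabelling, non-linear or poroelastic disc behaviour,
facet contact, or specimen-to-specimen biological covariance beyond
independent draws.  Passing recovery tests therefore demonstrate that the
pipeline inverts its own forward model under realistic rates, noise and
geometry - not that a linear Kelvin-Voigt bushing is an adequate disc
model; that adequacy rests on the tracking errors being of the order of
the measurement noise.

Trials are generated through the same preprocessing path identification
uses (filter, onset, window, simulate from preloaded equilibrium), so on a
noise-free bundle the objective at the generating parameters sits at the
integrator-determinism floor (~1e-15 mm) rather than being biased by
pre-onset transients.

## Validation and sensitivity

* **Median aggregation** is componentwise; for even counts the arithmetic
  midpoint of the two central values (each cross-validation fold medians
  exactly four specimens).
* **Five-fold cross-validation** transfers all 16 median parameters
  jointly to the held-out specimen and re-runs forward dynamics only.
* **Monte Carlo**: each sample draws one uniform coefficient in
  [-0.5, 0.5] per functional set (axial k, axial b, shear k, shear b) and
  scales the whole set, `p_i = p (1 + r_set)`; `dRMSE = RMSE_per -
  RMSE_opt`.  A per-parameter switch (16 independent coefficients) is
  available.  Third-degree polynomial surfaces (full ten-term bivariate
  cubic, ordinary least squares) are fitted to the six set pairs.
* **Joint-frame sweeps** shift all four joint origins together along
  their anteroposterior axes within +/-0.02 m; the shift moves both
  attachment points identically, so the rest configuration stays
  undeflected and only the load path changes.

## Scenario comparison

A muscle-free head + C2-C6 chain (head mass 4.5 kg lumped into the
cranial-most segment, no preload, free vertebrae on a fixed base) is driven
by a haversine head load (default 2 kN peak, 7.5 ms rise - the regime in
which axial sporting impacts reach 2 kN within 5-10 ms).  Variants:
`constrained` (translations locked; loads transmit statically, reported
displacements are identically zero), `impact_specific` (the midpoint of
the C3-C4 and C4-C5 medians per DoF applied at every joint - the two
levels whose segments carried no experimental constraints), and
`quasi_static` (the literature initialisation values).  Reported peaks are
maxima of compressive bushing force and absolute axial/shear displacement;
a 0.84 mm near-failure compression is attached as annotation only.  The
muscled population model this mirrors is not reproduced: muscles carried
no activation in the comparison and their passive contribution over
~20 ms is neglected - orderings between variants, not absolute peaks, are
the supported claims.

## Problem sizes used in the shipped checks

Desk-scale budgets keep the full suite and the acceptance script within
ordinary workstation runtimes: recovery uses a reduced search (population
40, 25 generations, ~19k total simulations of 5 ms each), Monte Carlo
properties use n = 200 samples, and the noisy-trial tracking error uses a
reduced refinement budget.  Study-scale settings (population 100, 15
generations, n = 1000 Monte Carlo) remain the configuration defaults.

## Known limitations

* Linear bushings approximate one operating region of a strongly
  non-linear, rate-dependent disc response; identified values are specific
  to this loading regime.
* The Euler-angle small-rotation treatment is invalid for large head
  excursions; the integrator guard (1 rad) aborts such runs rather than
  misreporting them.
* Identifiability of damping is intrinsically weaker than stiffness over
  a 5 ms window: the flattest objective direction changes the tracking
  error by only ~3e-4 mm while moving dampings by 25 %.  Noise of 0.3 mm
  therefore leaves dampings loosely constrained on real-scale data; the
  noise-free recovery checks quantify the search, not the experiment.
* The damping subspace is moreover multimodal: marker motion sampled at
  4 kHz over 5 ms admits compensating damping patterns across joints,
  producing spurious local optima with correct stiffnesses but dampings
  tens of percent off at tracking errors of ~1e-3 mm.  At the reduced
  search budget, refinement escapes these traps for most ground-truth
  draws but not all of them; a dedicated global search over the damping
  subspace was evaluated and does not reliably help at this budget.
  Raising `refine_evals` is the supported remedy when a specific trial
  resists.
* The C2-C3 shear damping median in the bundled dataset is stored as the
  value recomputable from the per-specimen entries (0.6e3 Ns/m); the
  source table's summary row rounds this cell differently.
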