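# Methods

## Model structure

The pathway is a deterministic reaction network over a fixed 15-species
state vector (free Keap1, free cytoplasmic Nrf2, p62, latch-bound
Keap1·Nrf2, stress-modified hinge-only Keap1·Nrf2, Keap1·p62, autophagosomal
Keap1, nuclear Nrf2, KEAP1/NFE2L2/SQSTM1/SRXN1 mRNAs, Srxn1 protein, total
glutathione, intracellular electrophile). All reactions are mass action
except transcription of the Nrf2 target genes and glutathione synthesis,
which follow Hill laws `Vmax · n^h / (K^h + n^h)` in nuclear Nrf2 on top of
a basal rate. NFE2L2 mRNA is produced constitutively, so its trajectory is
dose-independent by construction — a structural prediction the tests check
to solver precision.

Shared backbone: basal synthesis of Nrf2, Keap1 (plus mKEAP1-dependent
translation) and p62 (plus mSQSTM1-dependent translation); one lumped
association step Keap1 + Nrf2 → latch complex (the two-site hinge/latch
binding is not resolved kinetically); proteasomal Nrf2 degradation out of
the latch complex with Keap1 recycling; the p62 route
p62 + Keap1 → Keap1·p62 → autophagosomal Keap1 → clearance; reversible
nuclear shuttling of Nrf2; translation of Srxn1 from its mRNA; glutathione
conjugation of the electrophile; first-order decay of every pool.

The two mechanistic variants differ exactly in the stress-modification
block:

* **hinge_latch** — `latch + Stress → modified complex` (persistent, Nrf2
  protected from degradation), and modification of *free* Keap1 lumped with
  its immediate hinge-only capture of free Nrf2
  (`Keap1 + Nrf2 + Stress → modified complex`). The fixed state vector
  carries no separate "modified free Keap1" pool; since the only kinetic
  consequence of that pool is that it binds Nrf2 without closing the latch,
  the lumped termolecular step is its exact reduction under a fast-capture
  assumption.
* **dissociation** — `latch + Stress → Keap1 + Nrf2`. Modified free Keap1
  is kinetically indistinguishable from free Keap1 here, so no separate
  free-modification step exists and the modified-complex pool stays empty.

The network is held as a data-driven reaction table (species, stoichiometry,
rate-law kind, parameter names); the right-hand side and its Jacobian are
generated symbolically (sympy) and compiled once per variant. A smooth clamp
`(y + sqrt(y² + 1e-24))/2` guards the Hill activator against the tiny
negative excursions a stiff solver may take, keeping non-integer powers and
the Jacobian finite.

## Inputs

Treatment is a Gauss-shaped electrophile influx whose peak equals the
nominal dose in μM; defaults centre the bolus 0.5 h after onset with a
0.25 h width (the data constrain mainly the injected amount, so the exact
shape parameters are conventions, both configurable). A constant
low-amplitude background influx (`stress_background`, an estimable
parameter) represents the modest DMSO response; it is switched on at
treatment onset together with the bolus. siRNA knock-downs multiply the
targeted protein's production rates (basal and translation) by an efficiency
factor in (0, 1] from t = 0; treatment follows after 72 h. Integration is
piecewise over [0, onset], the bolus window (step-capped at width/5 so LSODA
cannot step over the pulse) and the tail.

## Steady state and parameter reduction

The system is assumed to be at its unstimulated equilibrium at t = 0.
`solve_steady_state` uses damped root finding (hybr, analytic Jacobian) from
a heuristic production/degradation-balance start, falling back to a 10⁴-hour
pre-simulation plus polish; an independent pure pre-simulation endpoint
serves as a cross-check in the tests (agreement within 10⁻⁶ relative, with
pools below 10⁻⁶ a.u. treated as numerical zeros). `constrain_parameters`
solves the anchored production rates jointly with the non-anchored species
from the full equilibrium system, so anchored species hit prescribed steady
values exactly; the shipped convention anchors free Keap1 at 1 (fixing the
concentration gauge in place of a formal symmetry analysis) and the other
basally produced pools at their unit values. An anchor demanding a negative
production rate is rejected with the offending species named.

## Observation and likelihood

`y = log(s·x + b) + ε`, `ε ~ N(0, σ²)`: per observable a scale s (unknown
measurement units), an offset b (free for the three GFP readouts as
background fluorescence, fixed to 0 for ratio-type qPCR and GSH
measurements) and a constant σ on the log scale. The objective is
`Σ (res/σ)² + Σ log σ²`; per-target σ is concentrated out analytically
(σ̂² = mean squared log-residual, floored at 10⁻³ to avoid degeneracy on
noise-free synthetic data), or held fixed when a quadratic test oracle needs
it. For trust-region least squares the `Σ log σ²` part is carried as
per-record entries `sqrt(log σ² + 30)`; the constant 30 keeps the root real
down to σ ≈ 3·10⁻⁷ and cancels exactly when the objective is reported.

Observable map: nuclear Nrf2-GFP → nuclear Nrf2 (mean nuclear intensity
quantification, so the cytoplasmic pool is excluded); Srxn1-GFP → Srxn1;
Keap1-GFP foci → autophagosomal Keap1; mRNAs and total GSH → their species.

## Replicate alignment

The scaling model `S_{i,k,n} = y_{i,n}/s_k` with log-normal noise is linear
in log space, so time-course parameters and scalings are an exact
least-squares solve (gauge: s of the first experiment ≡ 1, applied per
observable). Two experiment series are merged with the mixed model
`S = y/s + b` — the offset breaks log-linearity, so (s, b) come from a
2-parameter nonlinear least squares on the natural scale over bridging
conditions, with b of the reference series ≡ 0. Note the aligned course
inherits the first experiment's scale; downstream fits therefore estimate
the per-observable observation scales rather than pinning them at 1.

## Calibration and identifiability

Free parameters live on log10 scale with multiplicative bounds (default
10⁻⁵–10⁵ of nominal; recovery studies use tighter, documented boxes).
Multi-start fitting draws Latin-hypercube starts (deterministic per seed)
and runs trust-region reflective least squares on the residual vector. The
finite-difference step is fixed at 10⁻⁴ on log10 parameters — well above
the ODE-solver noise floor at the fitting tolerances (rtol 10⁻⁶), which is
essential for convergence. Exploration runs are iteration-capped and the
best few candidates are polished; simulations are cached on the kinetic
parameter vector, so derivative columns for observation-only parameters are
nearly free.

Profiles step one parameter multiplicatively in both directions, re-optimise
all others warm-started from the neighbouring optimum, adapt the step to the
local objective change, and stop at Δ(−2 log L) = 5 or at a bound. The 95%
CI interpolates the 3.84 crossings; a profile flat to within 0.01 across its
whole range is classified structurally non-identifiable, a missing crossing
on either side as practically non-identifiable. Variant comparison reports
both objectives plus each variant's complex-trajectory signature (baseline
versus post-bolus minimum within 2 h) and states explicitly that
equal-quality fits do not exclude either hypothesis. Per-compound extensions
(DCF: association/clearance; OMZ: additionally Srxn1 degradation and SRXN1
transcription capacity) are nested refits initialised at the base optimum,
reported as Δ(−2 log L).

## Synthetic data

The generator simulates the full study design (DEM 0/10/100/316/561 μM,
DCF 100/316/500/1000 μM, OMZ 4.7–282 μM; hourly imaging 0–48 h; qPCR at
3/8/24 h; GSH at 0.5–48 h; knock-down arms with 72 h pre-incubation; ≥3
replicates), divides by per-experiment scalings drawn log-uniform from
[0.5, 2] and multiplies log-normal noise with σ = 0.1 per target (the noise
family is the study's; its magnitude and the scaling spread are conventions,
overridable in the design). Identical seeds reproduce datasets bitwise.

The reference parameter set is hand-tuned and then anchored through the
steady-state constraint; a simulate-and-check harness asserts its response
features: nuclear Nrf2 peaks 3–5 h after DEM 316 with slow relaxation,
target mRNAs peak near 8 h, NFE2L2 mRNA stays flat, total GSH rises
dose-dependently but by no more than ~30% at 561 μM, autophagosomal Keap1
dips 5–10% in the first 3 h (Keap1 sequestration into the modified complex)
before recovering, and Srxn1 is still rising at 48 h at the top dose
(sustained SRXN1 mRNA elevation via the slowly recovering Keap1 pool). The
generator emulates replicate scalings and log-normal noise but not
single-cell heterogeneity, image segmentation error, or day effects beyond a
single scalar per experiment — passing recovery tests therefore demonstrates
the estimator under the model's own error structure, not robustness to
misspecification.

## Problem sizes and numerical choices

Simulations integrate with LSODA and analytic Jacobians (rtol 10⁻⁸ for
reference trajectories, 10⁻⁶ inside fits); solver-refinement agreement is
tested at 10⁻⁴. Negative concentrations beyond −10⁻⁸ (relative) abort with
a diagnostic; smaller excursions are clamped to zero for observation. The
shipped recovery study frees two kinetic parameters (electrophile clearance,
SRXN1 transcription capacity) plus all per-observable scales, uses 50
Latin-hypercube starts with capped local iterations and polishes the top
three; profile-interval coverage is measured over 100 repeated noisy
datasets of a single-condition design, where the profiled observation scale
has an unambiguous generating value. Kinetic parameters are the coverage
targets in the joint fit; aligned data carry an arbitrary per-observable
gauge factor (the first experiment's scaling), so observation-scale "truth"
is only defined up to alignment sampling error and is not used for coverage
claims.

## Known limitations

* The network is a canonical reconstruction of the mechanisms named for this
  pathway; competitive ETGE binders (WTX, p21, PALB2, DPP3), β-TrCP/PKC
  branches and stochastic/spatial effects are out of scope.
* The hinge-only intermediate of unmodified Keap1 is not resolved; two-site
  binding is lumped into a single association step, which is adequate for
  the observables modelled here but cannot describe hinge-latch cycling
  kinetics at sub-minute resolution.
* Whether stress modification acts on free Keap1, complexed Keap1, or both
  is not established; both routes are implemented (with separate rates) in
  the hinge-latch variant, and the free route is structurally absent in the
  dissociation variant.
* Per-target noise sd during alignment is estimated per observable; a single
  global sd is not enforced.
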