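# nrf2dyn

Dynamic ODE modelling of Nrf2 pathway activation in liver cells after
electrophile exposure: deterministic simulation of the Keap1–Nrf2–p62
network, replicate alignment, maximum-likelihood calibration with a
log-normal error model, and profile-likelihood identifiability analysis.

## The problem

The transcription factor Nrf2 (NFE2L2) orchestrates the cellular antioxidant
response. Under basal conditions its negative regulator Keap1 binds Nrf2 at
two motifs — the high-affinity ETGE ("hinge") and the low-affinity DLG
("latch") — and routes it to proteasomal degradation. The autophagy adaptor
p62 (SQSTM1) competes for Keap1 and carries it into autophagosomal foci.
Electrophilic stress (e.g. diethyl maleate, DEM, or the DILI-associated drugs
diclofenac and omeprazole) modifies Keap1 cysteines, Nrf2 degradation stops,
nuclear Nrf2 accumulates and induces target genes (SRXN1, KEAP1, SQSTM1) and
glutathione synthesis.

Two mechanistic hypotheses compete for the stress-modification step:

* **hinge–latch** — the modified complex persists with only the hinge bound;
  Nrf2 inside it is protected from degradation, and only newly synthesised
  Nrf2 reaches the nucleus;
* **dissociation** — stress releases Nrf2 from Keap1 entirely.

Both variants are implemented over the same 15-species state vector; they
differ only in the stress-modification step. Fitted to time-course data they
are near-indistinguishable in quality, but they make opposite predictions for
the internal Keap1–Nrf2 complex: an immediate post-bolus dip (dissociation)
versus a monotone increase (hinge–latch).

## The model

A reaction network of mass-action kinetics plus Hill-type transcription,

* `d/dt x = S · v(x, θ, u(t))` over species
  (Keap1, Nrf2, p62, the latch-bound and stress-modified Keap1·Nrf2
  complexes, Keap1·p62, autophagosomal Keap1, nuclear Nrf2, four mRNAs,
  Srxn1 protein, total glutathione, and the intracellular electrophile),
* treatment input `u(t)`: a Gauss-shaped bolus whose height equals the
  nominal dose (μM), plus a small constant DMSO background,
* siRNA knock-downs as multiplicative switches on protein production rates,
  simulated for 72 h before treatment,
* the system is in equilibrium at t = 0; the steady-state constraint is used
  to eliminate production rates (anchor convention: free Keap1 = 1 a.u.).

Measurements enter on the log scale through `y = log(s·x + b) + ε`,
`ε ~ N(0, σ²)` with constant per-target σ, and parameters are estimated by
minimising

```
-2 log L(θ) = Σ_i [ (y(t_i, θ) − y_i^D)² / σ_i² + log σ_i² ]
```

with trust-region least squares on log-parameters from Latin-hypercube
multi-starts. Identifiability and 95% confidence intervals come from profile
likelihoods (threshold Δ(−2 log L) = 3.84). Biological replicates are first
condensed by a scaling model `S_{i,k,n} = y_{i,n}/s_k` (exact least squares
in log space); independent experiment series are merged with a mixed
scaling–offset model `S = y/s + b`.

Because the study's microscopy/qPCR/GSH tables are not publicly deposited,
the package ships a synthetic-data generator (`nrf2dyn.synthetic`) that
emulates the study design — DEM/DCF/OMZ dose ranges, hourly imaging over
48 h, qPCR at 3/8/24 h, GSH at 0.5–48 h, knock-down arms, ≥3 replicates with
per-experiment scalings and log-normal noise — around a hand-tuned reference
parameter set whose dynamics reproduce the reported response features.

## Worked example

```python
import numpy as np
from nrf2dyn import (Condition, StimulusSpec, SyntheticDesign, Dataset,
                     FitProblem, align_replicates, complex_total,
                     default_observation_map, fit_multistart,
                     generate_dataset, make_conditions, reference_parameters,
                     simulate_condition, solve_steady_state)

theta = reference_parameters()
ss = solve_steady_state("hinge_latch", theta)
times = tuple(np.arange(0.0, 48.5, 0.5))
cond = Condition(stimulus=StimulusSpec(compound="DEM", dose=316.0),
                 horizon=48.0, observation_times=times)
traj = simulate_condition("hinge_latch", theta, cond, x0=ss.state0)
n = traj["nNrf2"]
print(f"nuclear Nrf2 peak: {n.max() / n[0]:.1f}-fold at t = "
      f"{traj.times[np.argmax(n)]:.1f} h")

design = SyntheticDesign(seed=1, imaging_times=tuple(np.arange(0., 49., 2.)),
                         doses={"DEM": (0.0, 316.0, 561.0)})
replicates, truth = generate_dataset(design, theta)
aligned = align_replicates(replicates)
print("estimated replicate scalings:",
      np.round(aligned.scalings.groupby(level="experiment").mean().to_numpy(), 3))

problem = FitProblem(variant="hinge_latch", values=theta.as_dict(),
                     free=("k_clear_stress", "vmax_msrxn1"),
                     dataset=Dataset(aligned.aligned),
                     conditions=make_conditions(design, theta),
                     obs_map=default_observation_map(), bounds_factor=100.0)
best = fit_multistart(problem, n_starts=8, seed=1, max_nfev=60)[0]
for name in problem.free:
    print(f"{name}: estimate {best.values[name]:.3f} (truth {theta[name]})")
```

prints

```
nuclear Nrf2 peak: 5.3-fold at t = 4.5 h
estimated replicate scalings: [1.    1.842 0.603]
k_clear_stress: estimate 1.016 (truth 1.0)
vmax_msrxn1: estimate 0.793 (truth 0.8)
```

Nuclear Nrf2 rises fast (peaking 3–5 h after the bolus) and relaxes slowly;
the alignment recovers the simulated per-experiment scalings (gauge: first
experiment ≡ 1); the multi-start fit recovers the generating electrophile
clearance rate and SRXN1 transcription capacity to a few percent.

A full run — generate → align → fit → profile → compare variants → report
with diagnostic plots — is one command:

```bash
nrf2dyn run config.yaml        # see nrf2dyn --help for the stages
```

Real measurements can replace the generator: the pipeline ingests the same
long-format table (condition, experiment, observable, time, value), and fit
problems round-trip through PEtab-style TSV/YAML files
(`nrf2dyn.petab_io`).

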