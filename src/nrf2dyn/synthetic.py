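"""Synthetic ground truth and replicate data with the study's statistical structure.

The generator emulates the design of the underlying experiments: dose-response
time courses for DEM/DCF/OMZ plus DMSO control (hourly imaging over 48 h,
qPCR at 3/8/24 h, total-GSH at 0.5-48 h), siRNA knock-down arms (72 h
pre-incubation, then DMSO or DEM 316), at least three biological replicates
per condition, multiplicative per-experiment scalings, and multiplicative
log-normal measurement noise with constant per-target standard deviation.

``reference_parameters`` ships a hand-tuned ground-truth rate set whose
simulated dynamics reproduce the qualitative response features the pathway
shows in HepG2 reporter cells: a fast nuclear-Nrf2 rise peaking 3-5 h after
a DEM bolus followed by slow relaxation, target-gene mRNA peaks near 8 h,
flat NFE2L2 mRNA, a 5-10% initial dip in autophagosomal Keap1 foci before
recovery, a modest (<= ~30%) glutathione rise at the top DEM dose, and
Srxn1 protein still accumulating at 48 h at the highest dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (Condition, KnockdownSpec, ParameterSet, StimulusSpec,
                    Trajectories, resolve_compound, simulate_condition)
from .observation import (Dataset, ObservationMap, default_observation_map,
                          observe_trajectories)
from .steady_state import constrain_parameters, solve_steady_state

__all__ = ["DOSES", "IMAGING_TIMES", "QPCR_TIMES", "GSH_TIMES",
           "REFERENCE_ANCHORS", "SyntheticDesign", "GroundTruth",
           "reference_parameters", "make_conditions", "generate_dataset",
           "knockdown_scenario"]

# treatment designs: compound -> doses in micromolar
DOSES: dict[str, tuple[float, ...]] = {
    "DEM": (0.0, 10.0, 100.0, 316.0, 561.0),
    "DCF": (100.0, 316.0, 500.0, 1000.0),
    "OMZ": (4.7, 23.5, 47.0, 94.0, 188.0, 282.0),
}

IMAGING_TIMES = tuple(float(t) for t in range(0, 49))       # hourly, 48 h
QPCR_TIMES = (3.0, 8.0, 24.0)
GSH_TIMES = (0.5, 1.0, 2.0, 5.0, 10.0, 24.0, 48.0)

IMAGING_OBSERVABLES = ("Keap1_foci", "Nrf2_nuc", "Srxn1_cyt")
QPCR_OBSERVABLES = ("mKEAP1", "mNFE2L2", "mSQSTM1", "mSRXN1")

# steady-state anchor convention of the reference set (free Keap1 = 1 a.u.)
REFERENCE_ANCHORS: dict[str, float] = {
    "Keap1_free": 1.0, "Nrf2_free": 0.02, "p62": 1.0, "mKEAP1": 1.0,
    "mNFE2L2": 1.0, "mSQSTM1": 1.0, "mSRXN1": 1.0, "GSH": 1.0,
}

# hand-tuned ground truth (production rates below are re-solved from the
# anchors by the steady-state constraint; the listed values are start guesses)
_REFERENCE_BASE: dict[str, float] = dict(
    k_prod_nrf2=0.5,
    k_prod_keap1=0.1,
    k_prod_p62=0.1,
    k_transl_keap1=0.1,
    k_transl_p62=0.08,
    k_transl_srxn1=0.05,
    k_bind_k1n2=50.0,
    k_unbind_k1n2=1.0,
    k_deg_nrf2_complex=8.0,
    k_bind_k1p62=0.5,
    k_unbind_k1p62=0.2,
    k_auto_flux=0.15,
    k_clear_auto=0.12,
    k_import_nrf2=1.0,
    k_export_nrf2=0.2,
    k_basal_mkeap1=0.25,
    k_basal_mnfe2l2=0.25,
    k_basal_msqstm1=0.25,
    k_basal_msrxn1=0.25,
    k_basal_gsh=0.1,
    vmax_mkeap1=0.7, K_mkeap1=0.4, h_mkeap1=2.0,
    vmax_msqstm1=2.0, K_msqstm1=0.4, h_msqstm1=2.0,
    vmax_msrxn1=0.8, K_msrxn1=0.1, h_msrxn1=2.0,
    vmax_gsh=0.09, K_gsh=0.15, h_gsh=2.0,
    k_mod_complex=0.3,
    k_mod_free=0.3,
    k_conj_gsh=2e-4,
    k_clear_stress=1.0,
    k_deg_keap1=0.02,
    k_deg_nrf2=0.1,
    k_deg_p62=0.1,
    k_deg_k1n2=0.05,
    k_deg_k1n2mod=0.04,
    k_deg_k1p62=0.05,
    k_deg_nnrf2=0.3,
    k_deg_mkeap1=0.25,
    k_deg_mnfe2l2=0.25,
    k_deg_msqstm1=0.25,
    k_deg_msrxn1=0.25,
    k_deg_srxn1=0.005,
    k_deg_gsh=0.1,
    stress_background=0.2,
    # DCF: slower electrophile generation and clearance than DEM
    k_mod_complex_dcf=0.1, k_mod_free_dcf=0.1, k_clear_stress_dcf=0.7,
    # OMZ: distinct stress kinetics plus altered Srxn1 regulation
    k_mod_complex_omz=0.6, k_mod_free_omz=0.6, k_clear_stress_omz=2.0,
    k_deg_srxn1_omz=0.02, vmax_msrxn1_omz=0.4,
    # siRNA knock-down efficiencies (residual production fraction)
    f_keap1=0.2, f_nfe2l2=0.2, f_sqstm1=0.2,
)

_REFERENCE_CACHE: dict[str, ParameterSet] = {}


def reference_parameters() -> ParameterSet:
    """Ground-truth rate set, steady-state constrained at the anchors."""
    if "theta" not in _REFERENCE_CACHE:
        base = ParameterSet(_REFERENCE_BASE)
        _REFERENCE_CACHE["theta"] = constrain_parameters(
            base, REFERENCE_ANCHORS, variant="hinge_latch")
    return _REFERENCE_CACHE["theta"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Experimental design of a synthetic study."""

    compounds: tuple[str, ...] = ("DEM",)
    doses: dict[str, tuple[float, ...]] | None = None
    imaging_times: tuple[float, ...] = IMAGING_TIMES
    qpcr_times: tuple[float, ...] = QPCR_TIMES
    gsh_times: tuple[float, ...] = GSH_TIMES
    include_qpcr: bool = True
    include_gsh: bool = True
    knockdowns: tuple[str, ...] = ()     # e.g. ("KEAP1", "NFE2L2", "SQSTM1")
    kd_doses: tuple[float, ...] = (0.0, 316.0)
    n_replicates: int = 3
    sigma: float = 0.1                   # log-scale noise sd, constant/target
    scaling_low: float = 0.5             # per-experiment scalings drawn
    scaling_high: float = 2.0            # log-uniform in [low, high]
    seed: int = 0

    def dose_list(self, compound: str) -> tuple[float, ...]:
        if self.doses and compound in self.doses:
            return self.doses[compound]
        return DOSES[compound]


@dataclass
class GroundTruth:
    """Noise-free truth underlying a generated dataset."""

    params: ParameterSet
    variant: str
    trajectories: dict[str, Trajectories]
    observables: pd.DataFrame   # condition, observable, time, value (natural)
    scalings: pd.Series         # experiment id -> s_k
    obs_map: ObservationMap


def _condition_id(compound: str, dose: float, kd: str = "control") -> str:
    tag = f"{compound}_{dose:g}"
    return tag if kd == "control" else f"si{kd}_{tag}"


def make_conditions(design: SyntheticDesign,
                    params: ParameterSet) -> dict[str, tuple[Condition, str]]:
    """All (condition id) -> (Condition, compound) pairs of a design."""
    times = sorted(set(design.imaging_times)
                   | (set(design.qpcr_times) if design.include_qpcr else set())
                   | (set(design.gsh_times) if design.include_gsh else set()))
    horizon = max(times) if times else 48.0
    conditions: dict[str, tuple[Condition, str]] = {}
    for compound in design.compounds:
        for dose in design.dose_list(compound):
            comp = compound if dose > 0 else "DMSO"
            cond = Condition(
                stimulus=StimulusSpec(compound=comp, dose=dose),
                horizon=horizon, observation_times=tuple(times))
            conditions[_condition_id(compound, dose)] = (cond, comp)
    kd_factor = {"KEAP1": params["f_keap1"], "NFE2L2": params["f_nfe2l2"],
                 "SQSTM1": params["f_sqstm1"]}
    for target in design.knockdowns:
        for dose in design.kd_doses:
            comp = "DEM" if dose > 0 else "DMSO"
            kd = (KnockdownSpec() if target == "control"
                  else KnockdownSpec(target=target, factor=kd_factor[target]))
            cond = Condition(
                stimulus=StimulusSpec(compound=comp, dose=dose),
                knockdown=kd, horizon=horizon, observation_times=tuple(times))
            conditions[_condition_id(comp, dose, target)] = (cond, comp)
    return conditions


def _observable_times(design: SyntheticDesign, observable: str) -> set[float]:
    if observable in QPCR_OBSERVABLES:
        return set(design.qpcr_times) if design.include_qpcr else set()
    if observable == "GSH_total":
        return set(design.gsh_times) if design.include_gsh else set()
    return set(design.imaging_times)


def generate_dataset(design: SyntheticDesign, params: ParameterSet | None = None,
                     variant: str = "hinge_latch",
                     obs_map: ObservationMap | None = None,
                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a design and emit noisy replicate tables plus the truth.

    Returns a long-format replicate table (condition, experiment, observable,
    time, value) ready for ``align_replicates`` and the ``GroundTruth``
    (noise-free trajectories, observables and the scalings used).  Replicate
    k of every condition is treated as one independent experiment with its
    own scaling s_k; values are  truth / s_k * exp(N(0, sigma^2)).
    """
    params = params or reference_parameters()
    obs_map = obs_map or default_observation_map(sigma=design.sigma)
    rng = np.random.default_rng(design.seed)
    ss = solve_steady_state(variant, params)
    if not ss.converged:
        raise RuntimeError("ground-truth parameters have no steady state")

    conditions = make_conditions(design, params)
    truth_rows, rep_rows = [], []
    trajectories = {}
    n_rep = design.n_replicates
    scalings = np.exp(rng.uniform(np.log(design.scaling_low),
                                  np.log(design.scaling_high), size=n_rep))
    for cid, (cond, compound) in conditions.items():
        p_comp = resolve_compound(params, compound)
        traj = simulate_condition(variant, p_comp, cond, x0=ss.state0)
        trajectories[cid] = traj
        obs = observe_trajectories(traj, obs_map)
        for name in obs.columns:
            keep = _observable_times(design, name)
            for t, logval in obs[name].items():
                if t not in keep:
                    continue
                truth_val = float(np.exp(logval))
                truth_rows.append((cid, name, t, truth_val))
                # the map's sigma floor protects estimation; a zero-noise
                # design must reproduce the truth exactly
                sd = obs_map[name].sigma if design.sigma > 0 else 0.0
                for k in range(n_rep):
                    noise = np.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0
                    rep_rows.append((cid, f"exp{k + 1}", name, t,
                                     truth_val / scalings[k] * noise))

    truth = pd.DataFrame(truth_rows,
                         columns=["condition", "observable", "time", "value"])
    reps = pd.DataFrame(rep_rows, columns=["condition", "experiment",
                                           "observable", "time", "value"])
    gt = GroundTruth(params=params, variant=variant, trajectories=trajectories,
                     observables=truth,
                     scalings=pd.Series(scalings,
                                        index=[f"exp{k + 1}" for k in range(n_rep)],
                                        name="s"),
                     obs_map=obs_map)
    return reps, gt


def knockdown_scenario(design: SyntheticDesign | None = None,
                       params: ParameterSet | None = None,
                       factors: dict[str, float] | None = None,
                       variant: str = "hinge_latch") -> dict[str, Trajectories]:
    """Simulate the siRNA arms: 72 h knock-down, then DMSO or DEM 316.

    Returns trajectories keyed by arm id (siCtrl_DMSO_0, siKEAP1_DEM_316, ...).
    """
    params = params or reference_parameters()
    if factors:
        for t, f in factors.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"knock-down factor for {t} must be in (0,1]")
        params = params.replace(**{f"f_{t.lower()}": f for t in factors})
    design = design or SyntheticDesign(knockdowns=("KEAP1", "NFE2L2", "SQSTM1"))
    ss = solve_steady_state(variant, params)
    times = tuple(np.arange(0.0, 24.5, 1.0))
    out = {}
    kd_factor = {"control": 1.0, "KEAP1": params["f_keap1"],
                 "NFE2L2": params["f_nfe2l2"], "SQSTM1": params["f_sqstm1"]}
    arms = ("control",) + tuple(design.knockdowns)
    for target in arms:
        for dose in design.kd_doses:
            comp = "DEM" if dose > 0 else "DMSO"
            kd = (KnockdownSpec() if target == "control"
                  else KnockdownSpec(target=target, factor=kd_factor[target]))
            cond = Condition(stimulus=StimulusSpec(compound=comp, dose=dose),
                             knockdown=kd, horizon=24.0,
                             observation_times=times)
            label = "siCtrl" if target == "control" else f"si{target}"
            p_comp = resolve_compound(params, comp)
            out[f"{label}_{comp}_{dose:g}"] = simulate_condition(
                variant, p_comp, cond, x0=ss.state0)
    return out
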