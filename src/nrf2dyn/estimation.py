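"""Maximum-likelihood calibration and profile-likelihood identifiability.

Free parameters (rate constants, observation scales/offsets) are estimated on
log10 scale by trust-region least squares on the weighted-residual form of
the log-normal likelihood, from Latin-hypercube multi-starts.  Per-target
noise sigmas are concentrated out analytically (sigma^2 = mean squared log
residual per target, floored) so the optimiser only sees kinetic and
observation parameters.  Identifiability is assessed by profile likelihood:
one parameter is stepped away from the optimum while all others are
re-optimised; 95% confidence intervals are read off at a -2 log L increase
of 3.84 (chi-square, 1 df) and flat profiles flag non-identifiability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import (COMPOUND_OVERRIDES, PARAMETERS, Condition, ParameterSet,
                    SimulationError, StimulusSpec, complex_total,
                    resolve_compound, simulate_condition)
from .observation import (PENALTY_SHIFT, Dataset, ObservationMap,
                          concentrated_sigmas, neg2_log_likelihood,
                          observe_trajectories, residual_vector)
from .steady_state import constrain_parameters, solve_steady_state

__all__ = ["FitProblem", "FitResult", "ProfileResult", "fit_multistart",
           "profile_likelihood", "compare_variants", "fit_compound_extension",
           "ExtensionResult", "PROFILE_THRESHOLD"]

PROFILE_THRESHOLD = 3.84   # 95% CI, chi-square with 1 df
_FAIL_RESIDUAL = 1e4       # residual filler for failed simulations

# extra parameters that may be freed per compound on top of the shared set
ALLOWED_COMPOUND_PARAMS: dict[str, tuple[str, ...]] = {
    "DCF": ("k_mod_complex_dcf", "k_mod_free_dcf", "k_clear_stress_dcf"),
    "OMZ": ("k_mod_complex_omz", "k_mod_free_omz", "k_clear_stress_omz",
            "k_deg_srxn1_omz", "vmax_msrxn1_omz"),
}


@dataclass
class FitProblem:
    """Calibration problem: model variant, data, designs and free parameters.

    ``values`` holds every model parameter plus observation-map entries named
    ``obs_s_<observable>`` / ``obs_b_<observable>``; ``free`` names the subset
    being estimated, each with positive natural-scale ``bounds``.
    """

    variant: str
    values: dict[str, float]
    free: tuple[str, ...]
    dataset: Dataset
    conditions: dict[str, tuple[Condition, str]]   # id -> (Condition, compound)
    obs_map: ObservationMap
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    anchors: dict[str, float] | None = None
    bounds_factor: float = 1e5
    rtol: float = 1e-6
    atol: float = 1e-8
    sigma_mode: str = "concentrated"   # or "fixed": use the map's sigmas

    def __post_init__(self):
        self.free = tuple(self.free)
        unknown = [n for n in self.free if n not in self.values]
        if unknown:
            raise ValueError(f"free parameters not in values: {unknown}")
        for name in self.free:
            if name not in self.bounds:
                v = self.values[name]
                self.bounds[name] = (v / self.bounds_factor,
                                     v * self.bounds_factor)
            lo, hi = self.bounds[name]
            if not (0 < lo < hi):
                raise ValueError(f"invalid bounds for {name}: {self.bounds[name]}")
        self._row_index = self._build_row_index()

    def _build_row_index(self):
        """For each dataset row: (condition id, observable, time position)."""
        pos_cache: dict[str, dict[float, int]] = {}
        for cid, (cond, _) in self.conditions.items():
            pos_cache[cid] = {t: i for i, t in enumerate(cond.observation_times)}
        idx = []
        for _, row in self.dataset.records.iterrows():
            cid = row["condition"]
            if cid not in self.conditions:
                raise ValueError(f"dataset condition {cid!r} has no design")
            tpos = pos_cache[cid].get(float(row["time"]))
            if tpos is None:
                raise ValueError(f"time {row['time']} of condition {cid!r} "
                                 f"not among its observation times")
            idx.append((cid, row["observable"], tpos))
        return idx

    # -- parameter-space helpers (log10 internally) --------------------------
    def pack(self, values: dict[str, float]) -> np.ndarray:
        return np.log10([values[n] for n in self.free])

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        out = dict(self.values)
        out.update({n: 10.0 ** xi for n, xi in zip(self.free, x)})
        return out

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.log10([self.bounds[n][0] for n in self.free])
        hi = np.log10([self.bounds[n][1] for n in self.free])
        return lo, hi

    # -- forward simulation ---------------------------------------------------
    def model_params(self, values: dict[str, float]) -> ParameterSet:
        params = ParameterSet({n: values[n] for n in PARAMETERS})
        if self.anchors:
            params = constrain_parameters(params, self.anchors, self.variant)
        return params

    def observation_map(self, values: dict[str, float]) -> ObservationMap:
        updates = {k: v for k, v in values.items()
                   if k.startswith(("obs_s_", "obs_b_", "obs_sigma_"))}
        return self.obs_map.with_values(updates)

    def _trajectories(self, params: ParameterSet,
                      needed: dict[str, set]) -> dict:
        """Condition trajectories, cached on the model-parameter vector."""
        key = tuple(params.values[n] for n in PARAMETERS)
        cache = getattr(self, "_traj_cache", None)
        if cache is None:
            cache = self._traj_cache = {}
        if key in cache:
            return cache[key]
        ss = solve_steady_state(self.variant, params)
        if not ss.converged:
            raise SimulationError("steady state did not converge", params)
        trajs = {}
        for cid, (cond, compound) in self.conditions.items():
            if cid not in needed:
                continue
            p = resolve_compound(params, compound)
            trajs[cid] = simulate_condition(self.variant, p, cond,
                                            x0=ss.state0, rtol=self.rtol,
                                            atol=self.atol)
        if len(cache) >= 16:
            cache.pop(next(iter(cache)))
        cache[key] = trajs
        return trajs

    def simulate(self, values: dict[str, float]) -> np.ndarray:
        """Log-scale model observations aligned with the dataset rows."""
        params = self.model_params(values)
        omap = self.observation_map(values)
        needed: dict[str, set] = {}
        for cid, obs, _ in self._row_index:
            needed.setdefault(cid, set()).add(obs)
        trajs = self._trajectories(params, needed)
        sims = {cid: observe_trajectories(traj, omap,
                                          tuple(sorted(needed[cid])))
                for cid, traj in trajs.items()}
        out = np.empty(len(self.dataset))
        for i, (cid, obs, tpos) in enumerate(self._row_index):
            out[i] = sims[cid][obs].iloc[tpos]
        return out

    # -- objective ------------------------------------------------------------
    def _effective_map(self, values, simulated):
        omap = self.observation_map(values)
        if self.sigma_mode == "fixed":
            return omap
        sig = concentrated_sigmas(self.dataset, simulated)
        return omap.with_values({f"obs_sigma_{k}": v for k, v in sig.items()})

    def objective(self, values: dict[str, float]) -> float:
        sim = self.simulate(values)
        return neg2_log_likelihood(self.dataset, sim, self._effective_map(values, sim))

    def residuals(self, x: np.ndarray) -> np.ndarray:
        try:
            values = self.unpack(x)
            sim = self.simulate(values)
            return residual_vector(self.dataset, sim,
                                   self._effective_map(values, sim))
        except (SimulationError, ValueError, OverflowError):
            return np.full(2 * len(self.dataset), _FAIL_RESIDUAL)


@dataclass
class FitResult:
    values: dict[str, float]         # full parameter values at the optimum
    objective: float                 # -2 log L (sigmas concentrated)
    sigmas: dict[str, float]
    converged: bool
    start_index: int
    nfev: int
    variant: str
    start_objectives: list[float] = field(default_factory=list)

    def theta(self, free: tuple[str, ...]) -> dict[str, float]:
        return {n: self.values[n] for n in free}


def _local_fit(problem: FitProblem, x0: np.ndarray, max_nfev: int | None,
               xtol: float = 1e-10) -> tuple[np.ndarray, float, bool, int]:
    lo, hi = problem.log_bounds()
    x0 = np.clip(x0, lo, hi)
    # finite-difference step must sit above the ODE-solver noise floor
    res = least_squares(problem.residuals, x0, bounds=(lo, hi), method="trf",
                        x_scale="jac", xtol=xtol, ftol=1e-10, gtol=1e-10,
                        diff_step=1e-4, max_nfev=max_nfev)
    r = problem.residuals(res.x)
    failed = bool(np.all(r == _FAIL_RESIDUAL))
    obj = float(r @ r - len(problem.dataset) * PENALTY_SHIFT)
    # a capped run (status 0, max_nfev reached) still yields a usable point;
    # only infeasible input or a simulation-failure plateau counts as failed
    return res.x, obj, (res.status != -1 and not failed), res.nfev


def fit_multistart(problem: FitProblem, n_starts: int = 20, seed: int = 0,
                   max_nfev: int | None = None,
                   include_nominal: bool = False) -> list[FitResult]:
    """Latin-hypercube multi-start local optimisation, best fit first.

    Deterministic for a given seed.  Failed starts are recorded with
    ``converged=False`` rather than raised.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo, hi = problem.log_bounds()
    sampler = qmc.LatinHypercube(d=len(problem.free), seed=seed)
    starts = lo + sampler.random(n=n_starts) * (hi - lo)
    if include_nominal:
        starts = np.vstack([problem.pack(problem.values), starts])

    results = []
    for i, x0 in enumerate(starts):
        try:
            x, obj, ok, nfev = _local_fit(problem, x0, max_nfev)
        except Exception:
            results.append(FitResult({}, math.inf, {}, False, i, 0,
                                     problem.variant))
            continue
        values = problem.unpack(x)
        try:
            sim = problem.simulate(values)
            sigmas = concentrated_sigmas(problem.dataset, sim)
        except (SimulationError, ValueError):
            sigmas, ok = {}, False
        results.append(FitResult(values, obj, sigmas, ok, i, nfev,
                                 problem.variant))
    if all(not r.converged for r in results):
        raise RuntimeError("all optimisation starts failed")
    results.sort(key=lambda r: (not r.converged, r.objective))
    results[0].start_objectives = [r.objective for r in results]
    return results


@dataclass
class ProfileResult:
    parameter: str
    values: np.ndarray        # natural-scale grid (sorted ascending)
    delta: np.ndarray         # -2 log L increase over the fit optimum
    ci: tuple[float, float]   # 95% interval; +-inf where no crossing
    identifiability: str      # identifiable | practically non-identifiable |
                              # structurally non-identifiable
    estimate: float
    threshold: float = PROFILE_THRESHOLD


def profile_likelihood(problem: FitProblem, fit: FitResult, parameter: str,
                       init_step: float = 0.08, max_steps: int = 25,
                       delta_max: float = 5.0,
                       threshold: float = PROFILE_THRESHOLD,
                       max_nfev: int | None = 60,
                       flat_tol: float = 0.01) -> ProfileResult:
    """Profile one free parameter in both directions from the optimum.

    Adaptive multiplicative stepping on log10 scale; all other free
    parameters are re-optimised at every point (started from the neighbouring
    optimum).  A point whose re-optimisation fails is flagged (delta = NaN)
    and the profile continues.
    """
    if parameter not in problem.free:
        raise ValueError(f"{parameter!r} is not a free parameter")
    if not fit.converged:
        raise ValueError("profile requires a converged fit")

    reduced_free = tuple(n for n in problem.free if n != parameter)
    lo, hi = problem.bounds[parameter]
    theta_hat = fit.values[parameter]
    obj_hat = fit.objective

    def make_reduced(fixed_value, base_values):
        vals = dict(base_values)
        vals[parameter] = fixed_value
        return FitProblem(variant=problem.variant, values=vals,
                          free=reduced_free, dataset=problem.dataset,
                          conditions=problem.conditions, obs_map=problem.obs_map,
                          bounds={n: problem.bounds[n] for n in reduced_free},
                          anchors=problem.anchors, rtol=problem.rtol,
                          atol=problem.atol, sigma_mode=problem.sigma_mode)

    pts = [(theta_hat, 0.0)]
    for direction in (+1, -1):
        step = init_step
        log_v = math.log10(theta_hat)
        base_values = dict(fit.values)
        prev_delta = 0.0
        for _ in range(max_steps):
            log_v += direction * step
            log_v = min(max(log_v, math.log10(lo)), math.log10(hi))
            v = 10.0 ** log_v
            sub = make_reduced(v, base_values)
            if reduced_free:
                try:
                    x, obj, ok, _ = _local_fit(sub, sub.pack(base_values),
                                               max_nfev)
                    base_values = sub.unpack(x)
                except Exception:
                    ok = False
            else:
                try:
                    obj = sub.objective(sub.values)
                    ok = True
                except (SimulationError, ValueError):
                    ok = False
            if not ok:
                pts.append((v, math.nan))
            else:
                delta = obj - obj_hat
                pts.append((v, delta))
                jump = abs(delta - prev_delta)
                if jump > 1.5:
                    step = max(step * 0.5, 0.01)
                elif jump < 0.05:
                    step = min(step * 1.8, 0.5)
                prev_delta = delta
                if delta >= delta_max:
                    break
            if log_v <= math.log10(lo) or log_v >= math.log10(hi):
                break

    pts.sort(key=lambda p: p[0])
    values = np.array([p[0] for p in pts])
    delta = np.array([p[1] for p in pts])

    ci = [-math.inf, math.inf]
    finite = ~np.isnan(delta)
    vf, df = values[finite], delta[finite]
    i_hat = int(np.argmin(np.abs(vf - theta_hat)))
    # lower crossing
    for i in range(i_hat, 0, -1):
        if df[i - 1] >= threshold > df[i]:
            w = (threshold - df[i]) / (df[i - 1] - df[i])
            ci[0] = float(vf[i] + w * (vf[i - 1] - vf[i]))
            break
    # upper crossing
    for i in range(i_hat, len(df) - 1):
        if df[i + 1] >= threshold > df[i]:
            w = (threshold - df[i]) / (df[i + 1] - df[i])
            ci[1] = float(vf[i] + w * (vf[i + 1] - vf[i]))
            break

    if np.nanmax(delta) < flat_tol:
        ident = "structurally non-identifiable"
    elif math.isfinite(ci[0]) and math.isfinite(ci[1]):
        ident = "identifiable"
    else:
        ident = "practically non-identifiable"
    return ProfileResult(parameter=parameter, values=values, delta=delta,
                         ci=(ci[0], ci[1]), identifiability=ident,
                         estimate=theta_hat, threshold=threshold)


def _complex_signature(variant: str, values: dict[str, float],
                       window: float = 2.0, onset: float = 72.0) -> dict:
    """Baseline vs post-bolus minimum of the total Keap1-Nrf2 complex."""
    params = ParameterSet({n: values[n] for n in PARAMETERS})
    ss = solve_steady_state(variant, params)
    times = tuple(np.arange(0.0, 24.05, 0.05))
    cond = Condition(stimulus=StimulusSpec(compound="DEM", dose=316.0,
                                           onset=onset),
                     horizon=24.0, observation_times=times)
    traj = simulate_condition(variant, params, cond, x0=ss.state0)
    total = complex_total(traj)
    baseline = float(total[0])
    in_window = np.asarray(times) <= window
    tmin = float(np.min(total[in_window]))
    return {"baseline": baseline,
            "min_within_2h": tmin,
            "dip_fraction": (baseline - tmin) / baseline if baseline > 0 else 0.0,
            "dips_below_baseline": bool(tmin < baseline * (1 - 1e-9))}


def compare_variants(problem: FitProblem, fit_hl: FitResult,
                     fit_diss: FitResult) -> dict:
    """Contrast the two mechanistic hypotheses fitted to the same data.

    Reports both objectives and each variant's total-complex response
    signature after a DEM 316 bolus at 72 h.  Equal-quality fits do not
    exclude either hypothesis; the discriminating feature is the predicted
    complex time course (immediate dip under dissociation, monotone increase
    under hinge-latch).
    """
    if fit_hl.variant == fit_diss.variant and fit_hl.variant not in (
            "hinge_latch", "dissociation"):
        raise ValueError("unknown variants in comparison")
    sig_hl = _complex_signature(fit_hl.variant, fit_hl.values)
    sig_diss = _complex_signature(fit_diss.variant, fit_diss.values)
    return {
        "objective_hinge_latch": fit_hl.objective,
        "objective_dissociation": fit_diss.objective,
        "objective_difference": fit_hl.objective - fit_diss.objective,
        "signature_hinge_latch": sig_hl,
        "signature_dissociation": sig_diss,
        "note": ("Comparable fit quality does not exclude either hypothesis; "
                 "the internal Keap1-Nrf2 complex trajectory is the "
                 "discriminating prediction."),
    }


@dataclass
class ExtensionResult:
    fit: FitResult
    base_objective: float
    delta_objective: float     # base - extended (>0 means improvement)
    extra_free: tuple[str, ...]


def fit_compound_extension(problem: FitProblem, base_fit: FitResult,
                           compound: str,
                           extra_free: tuple[str, ...] = (),
                           max_nfev: int | None = None) -> ExtensionResult:
    """Refit with additional per-compound parameters freed.

    ``extra_free`` must come from the compound's allowed set (association /
    clearance rates; for OMZ additionally the Srxn1 degradation rate and the
    Nrf2-dependent SRXN1 transcription capacity).  Shared parameters start at
    the base fit's optimum, making the comparison nested: the reported
    delta(-2 log L) is the improvement over re-optimising the base
    parameterisation on the same data.
    """
    if compound not in ALLOWED_COMPOUND_PARAMS and extra_free:
        raise ValueError(f"no per-compound parameters defined for {compound!r}")
    allowed = ALLOWED_COMPOUND_PARAMS.get(compound, ())
    bad = [n for n in extra_free if n not in allowed]
    if bad:
        raise ValueError(f"parameters {bad} not in the allowed per-compound "
                         f"set for {compound}: {allowed}")

    values = dict(problem.values)
    values.update(base_fit.values)
    ext = FitProblem(variant=problem.variant, values=values,
                     free=tuple(problem.free) + tuple(extra_free),
                     dataset=problem.dataset, conditions=problem.conditions,
                     obs_map=problem.obs_map,
                     bounds=dict(problem.bounds), anchors=problem.anchors,
                     rtol=problem.rtol, atol=problem.atol,
                     sigma_mode=problem.sigma_mode)
    x, obj, ok, nfev = _local_fit(ext, ext.pack(values), max_nfev)
    fit_values = ext.unpack(x)
    sim = ext.simulate(fit_values)
    sigmas = concentrated_sigmas(ext.dataset, sim)
    fit = FitResult(fit_values, obj, sigmas, ok, 0, nfev, problem.variant)
    # nested baseline: re-optimise the base free set from the same init
    base_refit_x, base_obj, _, _ = _local_fit(problem, problem.pack(values),
                                              max_nfev)
    return ExtensionResult(fit=fit, base_objective=base_obj,
                           delta_objective=base_obj - obj,
                           extra_free=tuple(extra_free))
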