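"""Basal equilibrium of the pathway and the steady-state parameter constraint.

The model is assumed to sit at its unstimulated steady state at t = 0.  The
equilibrium conditions couple rate constants and initial concentrations; the
full system is polynomial and is solved numerically (damped root finding with
a long pre-simulation fallback).  ``constrain_parameters`` uses the same
conditions in the opposite direction: production rates that enter the
right-hand side linearly are solved for analytically so that chosen species
hit prescribed steady-state values (the anchor convention: free Keap1 = 1 in
arbitrary units), which removes those rates from the free-parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import (MODEL_PARAMETERS, SPECIES, SPECIES_INDEX, ParameterSet,
                    build_model)

__all__ = ["SteadyStateResult", "solve_steady_state", "constrain_parameters",
           "ANCHORABLE_PRODUCTION"]

# species -> production-rate parameter entering its RHS row linearly (slope 1)
ANCHORABLE_PRODUCTION: dict[str, str] = {
    "Keap1_free": "k_prod_keap1",
    "Nrf2_free": "k_prod_nrf2",
    "p62": "k_prod_p62",
    "mKEAP1": "k_basal_mkeap1",
    "mNFE2L2": "k_basal_mnfe2l2",
    "mSQSTM1": "k_basal_msqstm1",
    "mSRXN1": "k_basal_msrxn1",
    "GSH": "k_basal_gsh",
}

_STRESS = SPECIES_INDEX["Stress"]


@dataclass
class SteadyStateResult:
    state0: np.ndarray
    residual_norm: float
    method: str  # "rootfind" | "presimulation"
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SPECIES, self.state0))


def _heuristic_start(params: ParameterSet) -> np.ndarray:
    """Decoupled production/degradation balance as a rough starting point."""
    x = np.full(len(SPECIES), 0.1)
    p = params.values
    x[SPECIES_INDEX["mKEAP1"]] = p["k_basal_mkeap1"] / p["k_deg_mkeap1"]
    x[SPECIES_INDEX["mNFE2L2"]] = p["k_basal_mnfe2l2"] / p["k_deg_mnfe2l2"]
    x[SPECIES_INDEX["mSQSTM1"]] = p["k_basal_msqstm1"] / p["k_deg_msqstm1"]
    x[SPECIES_INDEX["mSRXN1"]] = p["k_basal_msrxn1"] / p["k_deg_msrxn1"]
    x[SPECIES_INDEX["GSH"]] = p["k_basal_gsh"] / p["k_deg_gsh"]
    x[SPECIES_INDEX["Srxn1"]] = (p["k_transl_srxn1"] * x[SPECIES_INDEX["mSRXN1"]]
                                 / p["k_deg_srxn1"])
    x[SPECIES_INDEX["Keap1_free"]] = 1.0
    x[_STRESS] = 0.0
    return x


def solve_steady_state(variant: str, params: ParameterSet,
                       tol: float = 1e-8) -> SteadyStateResult:
    """Unstimulated equilibrium of the network (Stress input = 0).

    A moderate pre-simulation from the heuristic start commits to the
    dynamically reached attractor (some rate combinations make the p62
    feedback loop bistable, where pure root finding can land in the wrong
    basin); the endpoint is then polished by damped root finding, with a
    1e4-hour pre-simulation as fallback.
    """
    net = build_model(variant)
    pvec = params.vector()

    def f(x):
        return np.asarray(net._rhs(x, pvec, 0.0), dtype=float)

    def jac(x):
        return np.asarray(net._jac(x, pvec, 0.0), dtype=float)

    def try_root(x_start):
        with np.errstate(all="ignore"):
            sol = root(f, x_start, jac=jac, method="hybr", tol=1e-12)
        x = sol.x
        res = float(np.max(np.abs(f(x))))
        ok = res < tol and np.all(x >= -1e-12) and np.all(np.isfinite(x))
        return x, res, ok

    def relax(horizon, rtol, atol):
        with np.errstate(all="ignore"):
            sol = solve_ivp(lambda t, yv: f(yv), (0.0, horizon),
                            _heuristic_start(params), method="LSODA",
                            jac=lambda t, yv: jac(yv), rtol=rtol, atol=atol)
        if not sol.success:
            return None
        return np.clip(sol.y[:, -1], 0.0, None)

    x_end = relax(2000.0, 1e-8, 1e-10)
    if x_end is not None:
        x, res, ok = try_root(x_end)
        if ok:
            return SteadyStateResult(np.clip(x, 0.0, None), res,
                                     "rootfind", True)

    # fallback: long pre-simulation, then polish
    x_end = relax(1e4, 1e-10, 1e-12)
    if x_end is not None:
        x, res, ok = try_root(x_end)
        if ok:
            return SteadyStateResult(np.clip(x, 0.0, None), res,
                                     "presimulation", True)
        res_end = float(np.max(np.abs(f(x_end))))
        return SteadyStateResult(x_end, res_end, "presimulation",
                                 res_end < tol)
    return SteadyStateResult(np.full(len(SPECIES), np.nan), np.inf,
                             "presimulation", False)


def presimulate_steady_state(variant: str, params: ParameterSet,
                             horizon: float = 1e4) -> SteadyStateResult:
    """Pure pre-simulation endpoint (independent cross-check of the root)."""
    net = build_model(variant)
    pvec = params.vector()
    sol = solve_ivp(lambda t, yv: net._rhs(yv, pvec, 0.0), (0.0, horizon),
                    _heuristic_start(params), method="LSODA",
                    jac=lambda t, yv: net._jac(yv, pvec, 0.0),
                    rtol=1e-12, atol=1e-14)
    x = np.clip(sol.y[:, -1], 0.0, None)
    res = float(np.max(np.abs(net._rhs(x, pvec, 0.0))))
    return SteadyStateResult(x, res, "presimulation", bool(sol.success))


def constrain_parameters(params: ParameterSet, anchors: dict[str, float] | None,
                         variant: str = "hinge_latch",
                         tol: float = 1e-8) -> ParameterSet:
    """Solve production rates so anchored species hit target steady values.

    Each anchored species must map to a production rate that enters its RHS
    row linearly (``ANCHORABLE_PRODUCTION``).  The non-anchored species and
    the anchored production rates are solved jointly from the full
    equilibrium system.  Raises ``ValueError`` naming the violated anchor
    when the required rate is non-positive.
    """
    if not anchors:
        return params
    unknown = set(anchors) - set(ANCHORABLE_PRODUCTION)
    if unknown:
        raise ValueError(f"species not anchorable via a linear production rate: "
                         f"{sorted(unknown)}")
    for s_name, v in anchors.items():
        if v <= 0:
            raise ValueError(f"anchor for {s_name} must be positive, got {v}")

    net = build_model(variant)
    anchor_species = list(anchors)
    free_species = [s for s in SPECIES if s not in anchors]
    free_idx = np.array([SPECIES_INDEX[s] for s in free_species])
    anch_idx = np.array([SPECIES_INDEX[s] for s in anchor_species])
    rate_names = [ANCHORABLE_PRODUCTION[s] for s in anchor_species]
    rate_pidx = np.array([MODEL_PARAMETERS.index(n) for n in rate_names])

    pvec0 = params.vector()
    x_full = np.empty(len(SPECIES))
    x_full[anch_idx] = [anchors[s] for s in anchor_species]

    # joint unknowns: non-anchored species and the anchored production rates
    def f(z):
        x_full[free_idx] = z[:len(free_idx)]
        pv = pvec0.copy()
        pv[rate_pidx] = z[len(free_idx):]
        return np.asarray(net._rhs(x_full, pv, 0.0), dtype=float)

    z0 = np.concatenate([_heuristic_start(params)[free_idx],
                         pvec0[rate_pidx]])
    with np.errstate(all="ignore"):
        sol = root(f, z0, method="hybr", tol=1e-13)
    res = float(np.max(np.abs(f(sol.x))))
    if res > max(tol, 1e-8):
        raise ValueError(f"steady-state constraint solve did not converge "
                         f"(residual {res:.3e})")
    rates = dict(zip(rate_names, sol.x[len(free_idx):]))
    for s_name, rname in zip(anchor_species, rate_names):
        if rates[rname] <= 0:
            raise ValueError(
                f"anchor {s_name}={anchors[s_name]} inconsistent: required "
                f"production rate {rates[rname]:.3e} is not positive")
    if np.any(sol.x[:len(free_idx)] < -1e-10):
        raise ValueError("anchored equilibrium has negative species")
    return params.replace(**rates)
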