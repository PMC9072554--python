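"""Reaction network and deterministic simulation of the Nrf2-Keap1-p62 pathway.

The model tracks 15 species: the core proteins (free Keap1, free cytoplasmic
Nrf2, p62), the Keap1-Nrf2 complexes (latch-bound at both ETGE and DLG motifs,
and the stress-modified hinge-only complex), the Keap1-p62 complex and the
autophagosomal Keap1 pool (the foci observable), nuclear Nrf2, four mRNAs
(KEAP1, NFE2L2, SQSTM1, SRXN1), the Srxn1 protein, the total glutathione pool
and the intracellular active electrophile ("Stress").

Two mechanistic variants of the stress-modification step are supported:

``hinge_latch``
    Electrophile attack on Keap1 blocks DLG (latch) binding: the latch complex
    is converted to a persistent hinge-only complex (``K1N2_mod``) in which
    Nrf2 is protected from proteasomal degradation.  Stress-modified free
    Keap1 can still hinge-bind Nrf2 but cannot close the latch; this route is
    represented as direct capture of free Nrf2 into ``K1N2_mod``.

``dissociation``
    Electrophile attack releases Nrf2 from the complex; modified Keap1 is
    kinetically indistinguishable from free Keap1 and ``K1N2_mod`` stays
    empty.

Kinetics are mass action except for nuclear-Nrf2-driven production of the
target-gene mRNAs and of glutathione, which follow Hill kinetics, and the
treatment input, a Gauss-shaped electrophile bolus whose height equals the
nominal dose.  Concentrations are in arbitrary units with the basal steady
state of free Keap1 conventionally normalised to 1; time is in hours, doses
in micromolar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "MODEL_PARAMETERS",
    "PARAMETERS",
    "COMPOUNDS",
    "KNOCKDOWN_TARGETS",
    "ParameterSet",
    "StimulusSpec",
    "KnockdownSpec",
    "Condition",
    "Reaction",
    "ReactionNetwork",
    "build_model",
    "stimulus_value",
    "apply_knockdown",
    "resolve_compound",
    "ode_rhs",
    "simulate_condition",
    "Trajectories",
    "complex_total",
    "SimulationError",
]

# Fixed species ordering of the state vector.
SPECIES: tuple[str, ...] = (
    "Keap1_free",
    "Nrf2_free",
    "p62",
    "K1N2_latch",
    "K1N2_mod",
    "K1p62",
    "Keap1_auto",
    "nNrf2",
    "mKEAP1",
    "mNFE2L2",
    "mSQSTM1",
    "mSRXN1",
    "Srxn1",
    "GSH",
    "Stress",
)

SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

VARIANTS = ("hinge_latch", "dissociation")

COMPOUNDS = ("DMSO", "DEM", "DCF", "OMZ")

KNOCKDOWN_TARGETS = ("control", "KEAP1", "NFE2L2", "SQSTM1")

# Parameters entering the compiled right-hand side, in canonical order.
MODEL_PARAMETERS: tuple[str, ...] = (
    "k_prod_nrf2",
    "k_prod_keap1",
    "k_prod_p62",
    "k_transl_keap1",
    "k_transl_p62",
    "k_transl_srxn1",
    "k_bind_k1n2",
    "k_unbind_k1n2",
    "k_deg_nrf2_complex",
    "k_bind_k1p62",
    "k_unbind_k1p62",
    "k_auto_flux",
    "k_clear_auto",
    "k_import_nrf2",
    "k_export_nrf2",
    "k_basal_mkeap1",
    "k_basal_mnfe2l2",
    "k_basal_msqstm1",
    "k_basal_msrxn1",
    "k_basal_gsh",
    "vmax_mkeap1",
    "K_mkeap1",
    "h_mkeap1",
    "vmax_msqstm1",
    "K_msqstm1",
    "h_msqstm1",
    "vmax_msrxn1",
    "K_msrxn1",
    "h_msrxn1",
    "vmax_gsh",
    "K_gsh",
    "h_gsh",
    "k_mod_complex",
    "k_mod_free",
    "k_conj_gsh",
    "k_clear_stress",
    "k_deg_keap1",
    "k_deg_nrf2",
    "k_deg_p62",
    "k_deg_k1n2",
    "k_deg_k1n2mod",
    "k_deg_k1p62",
    "k_deg_nnrf2",
    "k_deg_mkeap1",
    "k_deg_mnfe2l2",
    "k_deg_msqstm1",
    "k_deg_msrxn1",
    "k_deg_srxn1",
    "k_deg_gsh",
    "stress_background",
)

# Compound-specific overrides and knock-down efficiency factors live alongside
# the kinetic parameters but are applied by substitution before compilation
# order matters (resolve_compound / apply_knockdown).
EXTRA_PARAMETERS: tuple[str, ...] = (
    "k_mod_complex_dcf",
    "k_mod_free_dcf",
    "k_clear_stress_dcf",
    "k_mod_complex_omz",
    "k_mod_free_omz",
    "k_clear_stress_omz",
    "k_deg_srxn1_omz",
    "vmax_msrxn1_omz",
    "f_keap1",
    "f_nfe2l2",
    "f_sqstm1",
)

PARAMETERS: tuple[str, ...] = MODEL_PARAMETERS + EXTRA_PARAMETERS

# Base-parameter -> compound-specific-parameter substitution maps.
COMPOUND_OVERRIDES: dict[str, dict[str, str]] = {
    "DMSO": {},
    "DEM": {},
    "DCF": {
        "k_mod_complex": "k_mod_complex_dcf",
        "k_mod_free": "k_mod_free_dcf",
        "k_clear_stress": "k_clear_stress_dcf",
    },
    "OMZ": {
        "k_mod_complex": "k_mod_complex_omz",
        "k_mod_free": "k_mod_free_omz",
        "k_clear_stress": "k_clear_stress_omz",
        "k_deg_srxn1": "k_deg_srxn1_omz",
        "vmax_msrxn1": "vmax_msrxn1_omz",
    },
}

# Production-rate parameters scaled by each siRNA switch.
KNOCKDOWN_RATES: dict[str, tuple[str, ...]] = {
    "KEAP1": ("k_prod_keap1", "k_transl_keap1"),
    "NFE2L2": ("k_prod_nrf2",),
    "SQSTM1": ("k_prod_p62", "k_transl_p62"),
}

_HILL_COEFFS = ("h_mkeap1", "h_msqstm1", "h_msrxn1", "h_gsh")
_KD_FACTORS = ("f_keap1", "f_nfe2l2", "f_sqstm1")
_MAY_BE_ZERO = ("stress_background",)


class SimulationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the parameter set."""

    def __init__(self, message: str, params: "ParameterSet | None" = None):
        if params is not None:
            message = f"{message}\nparameters: {dict(params.values)}"
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class ParameterSet:
    """Immutable named parameter collection for the pathway model.

    All rates must be strictly positive, Hill coefficients >= 1 and knock-down
    efficiency factors in (0, 1]; the DMSO background amplitude may be zero.
    """

    values: Mapping[str, float]

    def __post_init__(self):
        vals = dict(self.values)
        missing = [n for n in PARAMETERS if n not in vals]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        for name in PARAMETERS:
            v = float(vals[name])
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v}")
            if name in _KD_FACTORS:
                if not (0.0 < v <= 1.0):
                    raise ValueError(f"knock-down factor {name} must be in (0,1]: {v}")
            elif name in _HILL_COEFFS:
                if v < 1.0:
                    raise ValueError(f"Hill coefficient {name} must be >= 1: {v}")
            elif name in _MAY_BE_ZERO:
                if v < 0.0:
                    raise ValueError(f"parameter {name} must be >= 0: {v}")
            elif v <= 0.0:
                raise ValueError(f"rate parameter {name} must be > 0: {v}")
            vals[name] = v
        object.__setattr__(self, "values", vals)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def replace(self, **updates: float) -> "ParameterSet":
        unknown = set(updates) - set(PARAMETERS)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return ParameterSet({**self.values, **updates})

    def vector(self, names: Iterable[str] = MODEL_PARAMETERS) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


@dataclass(frozen=True)
class StimulusSpec:
    """Gauss-shaped electrophile bolus; height equals the nominal dose."""

    compound: str = "DEM"
    dose: float = 0.0
    onset: float = 0.0
    center_offset: float = 0.5
    width: float = 0.25
    dmso_background: bool = True

    def __post_init__(self):
        if self.compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


@dataclass(frozen=True)
class KnockdownSpec:
    """siRNA knock-down: a multiplicative switch on protein production rates."""

    target: str = "control"
    factor: float = 1.0
    duration_before_treatment: float = 72.0

    def __post_init__(self):
        if self.target not in KNOCKDOWN_TARGETS:
            raise ValueError(f"unknown knock-down target {self.target!r}")
        if not (0.0 < self.factor <= 1.0):
            raise ValueError("knock-down factor must be in (0, 1]")
        if self.target == "control" and self.factor != 1.0:
            raise ValueError("control knock-down must have factor 1")


@dataclass(frozen=True)
class Condition:
    """Treatment + knock-down + observation design of one experiment."""

    stimulus: StimulusSpec
    knockdown: KnockdownSpec = KnockdownSpec()
    horizon: float = 48.0
    observation_times: tuple[float, ...] = ()

    def __post_init__(self):
        times = tuple(float(t) for t in self.observation_times)
        if any(t < 0 for t in times):
            raise ValueError("observation times must be >= 0")
        if list(times) != sorted(times):
            raise ValueError("observation times must be sorted")
        if times and self.horizon < max(times):
            raise ValueError("horizon must cover all observation times")
        object.__setattr__(self, "observation_times", times)


@dataclass(frozen=True)
class Reaction:
    name: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    kind: str  # mass_action | hill | input
    parameters: tuple[str, ...]
    modifier: str | None = None

    def __post_init__(self):
        if self.kind not in ("mass_action", "hill", "input"):
            raise ValueError(f"unknown rate-law kind {self.kind!r}")
        for sp_name in list(self.reactants) + list(self.products):
            if sp_name not in SPECIES_INDEX:
                raise ValueError(f"unknown species {sp_name!r} in {self.name}")


def _r(name, reactants, products, kind, parameters, modifier=None) -> Reaction:
    return Reaction(name, dict(reactants), dict(products), kind, tuple(parameters), modifier)


def _shared_reactions() -> list[Reaction]:
    rx = [
        _r("prod_nrf2", {}, {"Nrf2_free": 1}, "mass_action", ["k_prod_nrf2"]),
        _r("prod_keap1", {}, {"Keap1_free": 1}, "mass_action", ["k_prod_keap1"]),
        _r("transl_keap1", {"mKEAP1": 1}, {"mKEAP1": 1, "Keap1_free": 1},
           "mass_action", ["k_transl_keap1"]),
        _r("prod_p62", {}, {"p62": 1}, "mass_action", ["k_prod_p62"]),
        _r("transl_p62", {"mSQSTM1": 1}, {"mSQSTM1": 1, "p62": 1},
           "mass_action", ["k_transl_p62"]),
        # Keap1-Nrf2 binding: two-site hinge/latch binding lumped into one step
        _r("bind_k1n2", {"Keap1_free": 1, "Nrf2_free": 1}, {"K1N2_latch": 1},
           "mass_action", ["k_bind_k1n2"]),
        _r("unbind_k1n2", {"K1N2_latch": 1}, {"Keap1_free": 1, "Nrf2_free": 1},
           "mass_action", ["k_unbind_k1n2"]),
        # proteasomal Nrf2 degradation out of the latch complex; Keap1 recycled
        _r("deg_nrf2_proteasome", {"K1N2_latch": 1}, {"Keap1_free": 1},
           "mass_action", ["k_deg_nrf2_complex"]),
        # p62 route: Keap1 sequestration and autophagosomal clearance
        _r("bind_k1p62", {"Keap1_free": 1, "p62": 1}, {"K1p62": 1},
           "mass_action", ["k_bind_k1p62"]),
        _r("unbind_k1p62", {"K1p62": 1}, {"Keap1_free": 1, "p62": 1},
           "mass_action", ["k_unbind_k1p62"]),
        _r("auto_flux", {"K1p62": 1}, {"Keap1_auto": 1}, "mass_action", ["k_auto_flux"]),
        _r("clear_auto", {"Keap1_auto": 1}, {}, "mass_action", ["k_clear_auto"]),
        # nucleocytoplasmic shuttling of Nrf2
        _r("import_nrf2", {"Nrf2_free": 1}, {"nNrf2": 1}, "mass_action", ["k_import_nrf2"]),
        _r("export_nrf2", {"nNrf2": 1}, {"Nrf2_free": 1}, "mass_action", ["k_export_nrf2"]),
        # transcription: basal plus nuclear-Nrf2-driven Hill production
        _r("prod_mkeap1_basal", {}, {"mKEAP1": 1}, "mass_action", ["k_basal_mkeap1"]),
        _r("prod_mkeap1_hill", {}, {"mKEAP1": 1}, "hill",
           ["vmax_mkeap1", "K_mkeap1", "h_mkeap1"], modifier="nNrf2"),
        _r("prod_mnfe2l2", {}, {"mNFE2L2": 1}, "mass_action", ["k_basal_mnfe2l2"]),
        _r("prod_msqstm1_basal", {}, {"mSQSTM1": 1}, "mass_action", ["k_basal_msqstm1"]),
        _r("prod_msqstm1_hill", {}, {"mSQSTM1": 1}, "hill",
           ["vmax_msqstm1", "K_msqstm1", "h_msqstm1"], modifier="nNrf2"),
        _r("prod_msrxn1_basal", {}, {"mSRXN1": 1}, "mass_action", ["k_basal_msrxn1"]),
        _r("prod_msrxn1_hill", {}, {"mSRXN1": 1}, "hill",
           ["vmax_msrxn1", "K_msrxn1", "h_msrxn1"], modifier="nNrf2"),
        _r("transl_srxn1", {"mSRXN1": 1}, {"mSRXN1": 1, "Srxn1": 1},
           "mass_action", ["k_transl_srxn1"]),
        # glutathione: basal + Nrf2-driven synthesis, electrophile conjugation
        _r("prod_gsh_basal", {}, {"GSH": 1}, "mass_action", ["k_basal_gsh"]),
        _r("prod_gsh_hill", {}, {"GSH": 1}, "hill",
           ["vmax_gsh", "K_gsh", "h_gsh"], modifier="nNrf2"),
        _r("conj_gsh", {"GSH": 1, "Stress": 1}, {}, "mass_action", ["k_conj_gsh"]),
        # electrophile input and clearance
        _r("stimulus", {}, {"Stress": 1}, "input", []),
        _r("clear_stress", {"Stress": 1}, {}, "mass_action", ["k_clear_stress"]),
    ]
    # basal first-order decay of every species pool
    decays = [
        ("Keap1_free", "k_deg_keap1"),
        ("Nrf2_free", "k_deg_nrf2"),
        ("p62", "k_deg_p62"),
        ("K1N2_latch", "k_deg_k1n2"),
        ("K1N2_mod", "k_deg_k1n2mod"),
        ("K1p62", "k_deg_k1p62"),
        ("nNrf2", "k_deg_nnrf2"),
        ("mKEAP1", "k_deg_mkeap1"),
        ("mNFE2L2", "k_deg_mnfe2l2"),
        ("mSQSTM1", "k_deg_msqstm1"),
        ("mSRXN1", "k_deg_msrxn1"),
        ("Srxn1", "k_deg_srxn1"),
        ("GSH", "k_deg_gsh"),
    ]
    rx += [_r(f"deg_{s}", {s: 1}, {}, "mass_action", [k]) for s, k in decays]
    return rx


def _variant_reactions(variant: str) -> list[Reaction]:
    if variant == "hinge_latch":
        return [
            # electrophile modification of complexed Keap1: latch opens, the
            # hinge-only complex persists and protects Nrf2 from degradation
            _r("mod_complex", {"K1N2_latch": 1, "Stress": 1}, {"K1N2_mod": 1},
               "mass_action", ["k_mod_complex"]),
            # modification of free Keap1, lumped with its hinge-only capture
            # of free Nrf2 (modified Keap1 cannot close the latch)
            _r("mod_free", {"Keap1_free": 1, "Nrf2_free": 1, "Stress": 1},
               {"K1N2_mod": 1}, "mass_action", ["k_mod_free"]),
        ]
    if variant == "dissociation":
        return [
            # electrophile attack releases Nrf2; modified Keap1 is lumped with
            # the free pool, no persistent hinge-only complex
            _r("mod_complex", {"K1N2_latch": 1, "Stress": 1},
               {"Keap1_free": 1, "Nrf2_free": 1}, "mass_action", ["k_mod_complex"]),
        ]
    raise ValueError(f"unknown model variant {variant!r}")


@dataclass
class ReactionNetwork:
    """Reaction system with a generated, compiled right-hand side."""

    variant: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    stoichiometry: np.ndarray = field(repr=False)  # (n_species, n_reactions)
    _rhs: Callable = field(repr=False, default=None)
    _jac: Callable = field(repr=False, default=None)

    def rhs(self, state: np.ndarray, t: float, pvec: np.ndarray, u: float) -> np.ndarray:
        """Time derivative of the state; ``u`` is the stimulus input value."""
        return np.asarray(self._rhs(state, pvec, u), dtype=float)

    def jacobian(self, state: np.ndarray, pvec: np.ndarray, u: float) -> np.ndarray:
        return np.asarray(self._jac(state, pvec, u), dtype=float)

    def species_index(self, name: str) -> int:
        return SPECIES_INDEX[name]

    def to_table(self) -> pd.DataFrame:
        """Serialise the reaction list as a delimited-text-ready table."""
        rows = []
        for rx in self.reactions:
            rows.append({
                "reaction": rx.name,
                "reactants": "+".join(f"{v}*{k}" if v > 1 else k
                                      for k, v in rx.reactants.items()) or "0",
                "products": "+".join(f"{v}*{k}" if v > 1 else k
                                     for k, v in rx.products.items()) or "0",
                "rate_law": rx.kind,
                "parameters": ";".join(rx.parameters),
                "modifier": rx.modifier or "",
            })
        return pd.DataFrame(rows)


def _compile(reactions: tuple[Reaction, ...]):
    y = sp.symbols(f"y0:{len(SPECIES)}", real=True)
    p = sp.symbols([f"p{i}" for i in range(len(MODEL_PARAMETERS))], real=True)
    u = sp.Symbol("u", real=True)
    pidx = {name: i for i, name in enumerate(MODEL_PARAMETERS)}
    sidx = SPECIES_INDEX

    rates = []
    for rx in reactions:
        if rx.kind == "mass_action":
            rate = p[pidx[rx.parameters[0]]]
            for s_name, count in rx.reactants.items():
                rate *= y[sidx[s_name]] ** count
        elif rx.kind == "hill":
            vmax, K, h = (p[pidx[n]] for n in rx.parameters)
            ym = y[sidx[rx.modifier]]
            # smooth clamp to (0, inf): keeps y**h and the Jacobian finite for
            # the tiny negative excursions a stiff solver may take
            n_act = (ym + sp.sqrt(ym**2 + sp.Float(1e-24))) / 2
            rate = vmax * n_act ** h / (K ** h + n_act ** h)
        else:  # input
            rate = u
        rates.append(rate)

    n_sp, n_rx = len(SPECIES), len(reactions)
    stoich = np.zeros((n_sp, n_rx), dtype=int)
    for j, rx in enumerate(reactions):
        for s_name, c in rx.reactants.items():
            stoich[sidx[s_name], j] -= c
        for s_name, c in rx.products.items():
            stoich[sidx[s_name], j] += c

    rhs_exprs = [sp.Add(*(int(stoich[i, j]) * rates[j]
                          for j in range(n_rx) if stoich[i, j] != 0))
                 for i in range(n_sp)]
    jac_mat = sp.Matrix(rhs_exprs).jacobian(sp.Matrix(y))

    rhs_fn = sp.lambdify((y, p, u), rhs_exprs, modules="math", cse=True)
    jac_fn = sp.lambdify((y, p, u), jac_mat.tolist(), modules="math", cse=True)
    return stoich, rhs_fn, jac_fn


@lru_cache(maxsize=4)
def _build_cached(variant: str) -> ReactionNetwork:
    reactions = tuple(_shared_reactions() + _variant_reactions(variant))
    stoich, rhs_fn, jac_fn = _compile(reactions)
    return ReactionNetwork(variant=variant, species=SPECIES, reactions=reactions,
                           stoichiometry=stoich, _rhs=rhs_fn, _jac=jac_fn)


def build_model(variant: str) -> ReactionNetwork:
    """Construct the canonical pathway network for a mechanistic variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    return _build_cached(variant)


def stimulus_value(t: float, spec: StimulusSpec, background: float = 0.0) -> float:
    """Electrophile input at time ``t`` (hours).

    Zero before onset; afterwards a Gaussian whose peak, at
    ``onset + center_offset``, equals the nominal dose, plus a constant
    DMSO background amplitude when the spec's flag is set.
    """
    if not math.isfinite(t):
        raise ValueError("time must be finite")
    if spec.dose < 0:
        raise ValueError("dose must be >= 0")
    if t < spec.onset:
        return 0.0
    z = (t - spec.onset - spec.center_offset) / spec.width
    val = spec.dose * math.exp(-0.5 * z * z)
    if spec.dmso_background:
        val += background
    return val


def apply_knockdown(params: ParameterSet, kd: KnockdownSpec) -> ParameterSet:
    """Multiply the targeted protein's production rates by the efficiency factor."""
    if kd.target == "control":
        return params
    rates = KNOCKDOWN_RATES[kd.target]
    return params.replace(**{r: params[r] * kd.factor for r in rates})


def resolve_compound(params: ParameterSet, compound: str) -> ParameterSet:
    """Substitute compound-specific rates into the base-named slots."""
    if compound not in COMPOUND_OVERRIDES:
        raise ValueError(f"unknown compound {compound!r}")
    overrides = COMPOUND_OVERRIDES[compound]
    return params.replace(**{base: params[specific] for base, specific in overrides.items()})


def ode_rhs(state: np.ndarray, t: float, params: ParameterSet,
            stimulus: StimulusSpec | None, variant: str) -> np.ndarray:
    """Derivative of the full state vector at time ``t``.

    ``stimulus=None`` means no electrophile input (pre-treatment phase).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(SPECIES),):
        raise ValueError(f"state must have length {len(SPECIES)}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite entries")
    net = build_model(variant)
    pvec = params.vector()
    u = 0.0 if stimulus is None else stimulus_value(t, stimulus, params["stress_background"])
    out = net.rhs(state, t, pvec, u)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite derivative (check parameters/state)")
    return out


@dataclass
class Trajectories:
    """Simulated concentration time courses sampled at observation times.

    ``times`` are hours relative to treatment onset.
    """

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    species: tuple[str, ...] = SPECIES

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=pd.Index(self.times, name="time"),
                            columns=list(self.species))


def _integrate(net: ReactionNetwork, x0, t0, t1, pvec, ufun, rtol, atol,
               t_eval=None, max_step=np.inf, params=None):
    if t1 <= t0:
        return np.asarray([t0]), np.asarray([x0])

    def f(t, yv):
        return net._rhs(yv, pvec, ufun(t))

    def jac(t, yv):
        return net._jac(yv, pvec, ufun(t))

    sol = solve_ivp(f, (t0, t1), x0, method="LSODA", jac=jac, rtol=rtol,
                    atol=atol, t_eval=t_eval, max_step=max_step, dense_output=False)
    if not sol.success:
        raise SimulationError(f"integration failed on [{t0}, {t1}]: {sol.message}", params)
    return sol.t, sol.y.T


def simulate_condition(variant: str, params: ParameterSet, condition: Condition,
                       x0: np.ndarray | None = None, rtol: float = 1e-8,
                       atol: float = 1e-10, full_output: bool = False) -> Trajectories:
    """Integrate one experimental condition from the pre-equilibrated state.

    The knock-down switch acts at t = 0; the stimulus (plus DMSO background)
    starts at onset, which is the knock-down duration for knock-down designs
    and the stimulus spec's own onset otherwise.  Sampling times are relative
    to treatment onset.  With ``full_output`` a dense hourly grid spanning the
    whole simulation (including the pre-treatment phase, at negative relative
    times) is returned instead of ``condition.observation_times``.
    """
    from .steady_state import solve_steady_state  # deferred: avoid cycle

    net = build_model(variant)
    kd = condition.knockdown
    stim = condition.stimulus
    if kd.target != "control":
        onset = kd.duration_before_treatment
    else:
        onset = stim.onset
    stim = replace(stim, onset=onset)

    if x0 is None:
        ss = solve_steady_state(variant, params)
        if not ss.converged:
            raise SimulationError("no pre-equilibrated steady state", params)
        x0 = ss.state0
    x0 = np.asarray(x0, dtype=float)

    params_kd = apply_knockdown(params, kd)
    pvec = params_kd.vector()
    background = params_kd["stress_background"]

    def ufun(t):
        return stimulus_value(t, stim, background)

    if full_output:
        pre = np.arange(0.0, onset, 1.0) if onset > 0 else np.array([])
        obs_abs = np.unique(np.concatenate([
            pre, onset + np.arange(0.0, condition.horizon + 0.5, 0.5)]))
    else:
        obs_abs = onset + np.asarray(condition.observation_times, dtype=float)

    t_end = onset + condition.horizon
    # integrate piecewise: pre-treatment, bolus window (step-capped), tail
    bolus_end = min(onset + stim.center_offset + 8.0 * stim.width, t_end)
    breaks = sorted({0.0, onset, bolus_end, t_end})
    breaks = [b for b in breaks if 0.0 <= b <= t_end]

    collected_t, collected_x = [np.array([0.0])], [x0[None, :]]
    x = x0.copy()
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_eval = obs_abs[(obs_abs > a) & (obs_abs <= b)]
        t_eval = np.unique(np.concatenate([seg_eval, [b]]))
        ms = stim.width / 5.0 if (a >= onset and a < bolus_end) else np.inf
        tt, xx = _integrate(net, x, a, b, pvec, ufun, rtol, atol,
                            t_eval=t_eval, max_step=ms, params=params_kd)
        x = xx[-1]
        collected_t.append(tt)
        collected_x.append(xx)

    all_t = np.concatenate(collected_t)
    all_x = np.concatenate(collected_x)
    # pick the requested sample times
    idx = np.searchsorted(all_t, obs_abs)
    idx = np.clip(idx, 0, len(all_t) - 1)
    # snap to nearest stored time (guards float round-off at segment joins)
    for j, ta in enumerate(obs_abs):
        lo = max(idx[j] - 1, 0)
        if abs(all_t[lo] - ta) < abs(all_t[idx[j]] - ta):
            idx[j] = lo
    states = all_x[idx]

    floor = states.min()
    if floor < -1e-8 * max(1.0, np.abs(states).max()):
        raise SimulationError(f"negative concentration {floor:.3e} beyond tolerance",
                              params_kd)
    states = np.clip(states, 0.0, None)
    return Trajectories(times=obs_abs - onset, states=states)


def complex_total(traj: Trajectories | pd.DataFrame) -> np.ndarray:
    """Total Keap1-Nrf2 complex: latch-bound plus (when present) modified pool."""
    if isinstance(traj, pd.DataFrame):
        if "K1N2_latch" not in traj.columns:
            raise KeyError("trajectories lack species column 'K1N2_latch'")
        total = traj["K1N2_latch"].to_numpy(dtype=float)
        if "K1N2_mod" in traj.columns:
            total = total + traj["K1N2_mod"].to_numpy(dtype=float)
        return total
    return traj["K1N2_latch"] + traj["K1N2_mod"]
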