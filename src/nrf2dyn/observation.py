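"""Observation model and log-normal likelihood.

A measurement of species (or species-sum) x is modelled on the log scale as

    y = log(s * x + b) + eps,     eps ~ N(0, sigma^2)

with an unknown concentration scale s, an optional background offset b
(free for fluorescence readouts, fixed to 0 for ratio-type qPCR and GSH
measurements) and constant per-target noise sigma.  The corresponding
maximum-likelihood objective is

    -2 log L = sum_i [ ((y_i - y_i^D) / sigma_i)^2 + log(sigma_i^2) ]

where y_i^D is a log-scale data point and sigma_i the standard deviation of
its target.  With everything else fixed, minimising over a target's sigma has
the closed form sigma^2 = mean squared residual of that target; sigma is
floored at SIGMA_MIN to avoid degeneracy on noise-free data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .model import SPECIES, Trajectories

__all__ = ["SIGMA_MIN", "ObservableDef", "ObservationMap", "Dataset",
           "observe", "observe_trajectories", "neg2_log_likelihood",
           "residual_vector", "PENALTY_SHIFT", "default_observation_map",
           "OBSERVABLE_SPECIES"]

SIGMA_MIN = 1e-3  # log units; lower bound on the error-model sigma

# constant added under the sqrt in the penalty entries of residual_vector so
# they stay real down to sigma ~ 3e-7; ||r||^2 - N*PENALTY_SHIFT == -2 log L
PENALTY_SHIFT = 30.0

# observable -> species whose (scaled, offset) value is measured
OBSERVABLE_SPECIES: dict[str, tuple[str, ...]] = {
    "Keap1_foci": ("Keap1_auto",),
    "Nrf2_nuc": ("nNrf2",),
    "Srxn1_cyt": ("Srxn1",),
    "mKEAP1": ("mKEAP1",),
    "mNFE2L2": ("mNFE2L2",),
    "mSQSTM1": ("mSQSTM1",),
    "mSRXN1": ("mSRXN1",),
    "GSH_total": ("GSH",),
    "complex_total": ("K1N2_latch", "K1N2_mod"),
}

_GFP_OBSERVABLES = ("Keap1_foci", "Nrf2_nuc", "Srxn1_cyt")


@dataclass(frozen=True)
class ObservableDef:
    """One observable: target species sum, scale, offset and noise sigma."""

    name: str
    species: tuple[str, ...]
    scale: float = 1.0
    offset: float = 0.0
    sigma: float = 0.1
    offset_free: bool = False  # background fluorescence estimable?

    def __post_init__(self):
        for s in self.species:
            if s not in SPECIES:
                raise ValueError(f"observable {self.name!r} maps to unknown "
                                 f"species {s!r}")
        if self.scale <= 0:
            raise ValueError(f"scale of {self.name!r} must be > 0")
        if self.offset < 0:
            raise ValueError(f"offset of {self.name!r} must be >= 0")
        if self.sigma < SIGMA_MIN:
            object.__setattr__(self, "sigma", SIGMA_MIN)


@dataclass
class ObservationMap:
    observables: dict[str, ObservableDef]

    def __getitem__(self, name: str) -> ObservableDef:
        return self.observables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.observables

    def names(self) -> tuple[str, ...]:
        return tuple(self.observables)

    def with_values(self, updates: Mapping[str, float]) -> "ObservationMap":
        """Return a copy with ``obs_s_<name>`` / ``obs_b_<name>`` /
        ``obs_sigma_<name>`` entries applied."""
        new = dict(self.observables)
        for key, val in updates.items():
            for prefix, fieldname in (("obs_s_", "scale"), ("obs_b_", "offset"),
                                      ("obs_sigma_", "sigma")):
                if key.startswith(prefix):
                    name = key[len(prefix):]
                    if name not in new:
                        raise KeyError(f"unknown observable {name!r} in {key!r}")
                    new[name] = replace(new[name], **{fieldname: float(val)})
        return ObservationMap(new)

    def to_table(self) -> pd.DataFrame:
        rows = [{
            "observable": o.name,
            "formula": "+".join(o.species),
            "scale": o.scale,
            "offset": o.offset,
            "sigma": o.sigma,
            "offset_free": o.offset_free,
        } for o in self.observables.values()]
        return pd.DataFrame(rows)


def default_observation_map(sigma: float = 0.1) -> ObservationMap:
    """Canonical map: GFP readouts with free offsets, qPCR/GSH with b = 0."""
    obs = {}
    for name, species in OBSERVABLE_SPECIES.items():
        if name == "complex_total":
            continue  # model-internal diagnostic, not a measured target
        obs[name] = ObservableDef(name=name, species=species, scale=1.0,
                                  offset=0.0, sigma=sigma,
                                  offset_free=name in _GFP_OBSERVABLES)
    return ObservationMap(obs)


@dataclass
class Dataset:
    """Long-format measurements: condition, observable, time, value.

    ``value`` is on the natural scale (positive); the log-scale datum used in
    the likelihood is ``log(value)``.
    """

    records: pd.DataFrame

    REQUIRED = ("condition", "observable", "time", "value")

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if not np.all(np.isfinite(df["value"])) or (df["value"] <= 0).any():
            raise ValueError("dataset values must be finite and positive")
        if (df["time"] < 0).any():
            raise ValueError("dataset times must be >= 0")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def log_values(self) -> np.ndarray:
        return np.log(self.records["value"].to_numpy(dtype=float))

    def conditions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.records["condition"]))


def observe(x: float | np.ndarray, entry: ObservableDef) -> float | np.ndarray:
    """Deterministic part of the observation: log(s*x + b)."""
    arg = entry.scale * np.asarray(x, dtype=float) + entry.offset
    if np.any(arg <= 0):
        raise ValueError(f"non-positive argument of log for observable "
                         f"{entry.name!r} (s*x+b = {np.min(arg):.3e})")
    out = np.log(arg)
    return float(out) if np.isscalar(x) else out


def observe_trajectories(traj: Trajectories, obs_map: ObservationMap,
                         names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Log-scale observables over time for one simulated condition."""
    names = names or obs_map.names()
    out = {}
    for name in names:
        entry = obs_map[name]
        x = sum(traj[s] for s in entry.species)
        out[name] = observe(x, entry)
    return pd.DataFrame(out, index=pd.Index(traj.times, name="time"))


def _sigmas_for(dataset: Dataset, obs_map: ObservationMap) -> np.ndarray:
    return dataset.records["observable"].map(
        {n: obs_map[n].sigma for n in obs_map.names()}).to_numpy(dtype=float)


def neg2_log_likelihood(dataset: Dataset, simulated_log: np.ndarray,
                        obs_map: ObservationMap) -> float:
    """-2 log L of the dataset given log-scale model observations.

    ``simulated_log`` must be aligned row-by-row with ``dataset.records``.
    """
    simulated_log = np.asarray(simulated_log, dtype=float)
    if simulated_log.shape != (len(dataset),):
        raise ValueError("simulated values must align with dataset records")
    sig = _sigmas_for(dataset, obs_map)
    if np.any(~np.isfinite(sig)):
        bad = dataset.records.loc[~np.isfinite(sig), "observable"].unique()
        raise ValueError(f"observables without sigma in map: {list(bad)}")
    res = (simulated_log - dataset.log_values) / sig
    val = float(np.sum(res**2) + np.sum(np.log(sig**2)))
    if not math.isfinite(val):
        raise ValueError("non-finite likelihood")
    return val


def residual_vector(dataset: Dataset, simulated_log: np.ndarray,
                    obs_map: ObservationMap) -> np.ndarray:
    """Weighted residuals plus per-record sigma penalty entries.

    Returns a vector r of length 2N with ||r||^2 - N*PENALTY_SHIFT equal to
    ``neg2_log_likelihood`` exactly, suitable for trust-region least squares.
    """
    simulated_log = np.asarray(simulated_log, dtype=float)
    if simulated_log.shape != (len(dataset),):
        raise ValueError("simulated values must align with dataset records")
    sig = _sigmas_for(dataset, obs_map)
    res = (simulated_log - dataset.log_values) / sig
    penalty = np.sqrt(np.log(sig**2) + PENALTY_SHIFT)
    return np.concatenate([res, penalty])


def concentrated_sigmas(dataset: Dataset, simulated_log: np.ndarray) -> dict[str, float]:
    """Per-target ML noise estimate: sqrt(mean squared log residual), floored."""
    simulated_log = np.asarray(simulated_log, dtype=float)
    df = dataset.records.assign(res=simulated_log - dataset.log_values)
    out = {}
    for name, grp in df.groupby("observable", sort=False):
        out[name] = max(float(np.sqrt(np.mean(grp["res"]**2))), SIGMA_MIN)
    return out
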