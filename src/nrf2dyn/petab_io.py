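"""PEtab-style problem exchange (TSV tables + YAML index).

A calibration problem round-trips through five plain-text files following the
PEtab v1 layout: condition, observable, measurement and parameter tables plus
a YAML index.  Condition-specific design (compound, dose, knock-down) and the
model variant are carried in extra columns / keys, so an exported problem can
be re-imported into an equivalent ``FitProblem`` with bit-identical
measurement values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import FitProblem, FitResult
from .model import Condition, KnockdownSpec, StimulusSpec
from .observation import Dataset, ObservableDef, ObservationMap

__all__ = ["export_petab", "import_petab"]

_FILES = {
    "conditions": "conditions.tsv",
    "observables": "observables.tsv",
    "measurements": "measurements.tsv",
    "parameters": "parameters.tsv",
}


def _write_tsv(df: pd.DataFrame, path: Path):
    """TSV with shortest-roundtrip float formatting (bit-exact re-parse)."""
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(repr)
    df.to_csv(path, sep="\t", index=False)


def export_petab(problem: FitProblem, out_dir: str | Path,
                 fit: FitResult | None = None) -> dict[str, Path]:
    """Write the problem (and optionally fitted values) as PEtab-style files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in _FILES.items()}

    cond_rows = []
    for cid, (cond, compound) in problem.conditions.items():
        cond_rows.append({
            "conditionId": cid,
            "compound": compound,
            "dose": cond.stimulus.dose,
            "bolusCenterOffset": cond.stimulus.center_offset,
            "bolusWidth": cond.stimulus.width,
            "dmsoBackground": int(cond.stimulus.dmso_background),
            "stimulusOnset": cond.stimulus.onset,
            "knockdownTarget": cond.knockdown.target,
            "knockdownFactor": cond.knockdown.factor,
            "knockdownDuration": cond.knockdown.duration_before_treatment,
            "horizon": cond.horizon,
            "observationTimes": ";".join(repr(t) for t in
                                         cond.observation_times),
        })
    _write_tsv(pd.DataFrame(cond_rows), paths["conditions"])

    obs_rows = []
    for name in problem.obs_map.names():
        o = problem.obs_map[name]
        obs_rows.append({
            "observableId": name,
            "observableFormula": "+".join(o.species),
            "observableTransformation": "log",
            "scale": o.scale,
            "offset": o.offset,
            "noiseFormula": o.sigma,
            "offsetFree": int(o.offset_free),
        })
    _write_tsv(pd.DataFrame(obs_rows), paths["observables"])

    meas = problem.dataset.records.rename(columns={
        "observable": "observableId", "condition": "simulationConditionId",
        "value": "measurement"})
    meas = meas[["observableId", "simulationConditionId", "time", "measurement"]]
    _write_tsv(meas, paths["measurements"])

    values = dict(problem.values)
    if fit is not None:
        values.update(fit.values)
    par_rows = []
    for name, val in values.items():
        lo, hi = problem.bounds.get(
            name, (val / problem.bounds_factor, val * problem.bounds_factor))
        par_rows.append({
            "parameterId": name,
            "parameterScale": "log10",
            "lowerBound": lo,
            "upperBound": hi,
            "nominalValue": val,
            "estimate": int(name in problem.free),
        })
    _write_tsv(pd.DataFrame(par_rows), paths["parameters"])

    yaml_path = out / "problem.yaml"
    with open(yaml_path, "w") as fh:
        yaml.safe_dump({
            "format_version": 1,
            "parameter_file": _FILES["parameters"],
            "problems": [{
                "condition_files": [_FILES["conditions"]],
                "measurement_files": [_FILES["measurements"]],
                "observable_files": [_FILES["observables"]],
            }],
            "extensions": {
                "model_variant": problem.variant,
                "steady_state_anchors": problem.anchors or {},
            },
        }, fh, sort_keys=False)
    paths["yaml"] = yaml_path
    return paths


def _fail(fname: str, row: int, msg: str):
    raise ValueError(f"{fname}, row {row}: {msg}")


def import_petab(yaml_path: str | Path) -> FitProblem:
    """Reconstruct a ``FitProblem`` from exported PEtab-style files."""
    yaml_path = Path(yaml_path)
    with open(yaml_path) as fh:
        index = yaml.safe_load(fh)
    base = yaml_path.parent
    prob = index["problems"][0]
    ext = index.get("extensions", {})

    def _read(path):
        return pd.read_csv(path, sep="\t", float_precision="round_trip")

    cond_df = _read(base / prob["condition_files"][0])
    obs_df = _read(base / prob["observable_files"][0])
    meas_df = _read(base / prob["measurement_files"][0])
    par_df = _read(base / index["parameter_file"])

    from .model import SPECIES
    observables = {}
    for i, row in obs_df.iterrows():
        species = tuple(str(row["observableFormula"]).split("+"))
        for s in species:
            if s not in SPECIES:
                _fail("observables.tsv", i, f"unknown species {s!r} in "
                      f"observable {row['observableId']!r}")
        observables[row["observableId"]] = ObservableDef(
            name=row["observableId"], species=species,
            scale=float(row["scale"]), offset=float(row["offset"]),
            sigma=float(row["noiseFormula"]),
            offset_free=bool(row["offsetFree"]))
    obs_map = ObservationMap(observables)

    # fall back to measurement times when the grid column is absent
    times_by_cond = {
        cid: tuple(sorted(set(grp["time"].astype(float))))
        for cid, grp in meas_df.groupby("simulationConditionId")
    }
    conditions = {}
    for i, row in cond_df.iterrows():
        cid = row["conditionId"]
        if "observationTimes" in cond_df.columns and pd.notna(row["observationTimes"]):
            times_by_cond[cid] = tuple(
                float(t) for t in str(row["observationTimes"]).split(";"))
        kd = KnockdownSpec(target=row["knockdownTarget"],
                           factor=float(row["knockdownFactor"]),
                           duration_before_treatment=float(row["knockdownDuration"]))
        stim = StimulusSpec(compound=row["compound"], dose=float(row["dose"]),
                            onset=float(row["stimulusOnset"]),
                            center_offset=float(row["bolusCenterOffset"]),
                            width=float(row["bolusWidth"]),
                            dmso_background=bool(row["dmsoBackground"]))
        conditions[cid] = (Condition(stimulus=stim, knockdown=kd,
                                     horizon=float(row["horizon"]),
                                     observation_times=times_by_cond.get(cid, ())),
                           row["compound"])

    for i, row in meas_df.iterrows():
        if row["observableId"] not in obs_map:
            _fail("measurements.tsv", i,
                  f"unknown observable {row['observableId']!r}")
        if row["simulationConditionId"] not in conditions:
            _fail("measurements.tsv", i,
                  f"unknown condition {row['simulationConditionId']!r}")

    dataset = Dataset(meas_df.rename(columns={
        "observableId": "observable", "simulationConditionId": "condition",
        "measurement": "value"}))

    values, free, bounds = {}, [], {}
    for i, row in par_df.iterrows():
        name = row["parameterId"]
        values[name] = float(row["nominalValue"])
        bounds[name] = (float(row["lowerBound"]), float(row["upperBound"]))
        if int(row["estimate"]):
            free.append(name)

    anchors = ext.get("steady_state_anchors") or None
    return FitProblem(variant=ext.get("model_variant", "hinge_latch"),
                      values=values, free=tuple(free), dataset=dataset,
                      conditions=conditions, obs_map=obs_map, bounds=bounds,
                      anchors=anchors)
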