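"""End-to-end orchestration: generate/ingest -> align -> fit -> profile ->
compare variants -> report.

The pipeline is driven by a validated configuration (YAML-friendly); every
stage writes its outputs under the configured directory and appends to a
structured run log, and the whole run is reproducible from config + seed
(the config hash is embedded in the report).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .alignment import align_replicates
from .estimation import (FitProblem, compare_variants, fit_multistart,
                         profile_likelihood)
from .model import PARAMETERS
from .observation import Dataset, default_observation_map
from .synthetic import (SyntheticDesign, generate_dataset, make_conditions,
                        reference_parameters)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    compounds: list[str] = ["DEM"]
    doses: dict[str, list[float]] | None = None
    n_replicates: int = 3
    sigma: float = 0.1
    imaging_step: float = 2.0       # hours between imaging samples
    knockdowns: list[str] = []


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    output_dir: str
    seed: int = 1
    variant: Literal["hinge_latch", "dissociation"] = "hinge_latch"
    synthetic: SyntheticConfig | None = None
    dataset_path: str | None = None          # replicate table (TSV) to ingest
    free_parameters: list[str] = ["k_mod_complex", "k_clear_stress",
                                  "vmax_msrxn1"]
    bounds_factor: float = 100.0
    n_starts: int = 8
    max_nfev: int | None = 80
    profile_parameters: list[str] = []
    compare_variants: bool = False
    make_plots: bool = True

    @model_validator(mode="after")
    def _check_inputs(self):
        if self.synthetic is None and self.dataset_path is None:
            raise ValueError("config needs either a synthetic design or a "
                             "dataset_path")
        bad = [p for p in self.free_parameters
               if p not in PARAMETERS and not p.startswith(("obs_s_", "obs_b_"))]
        if bad:
            raise ValueError(f"unknown free parameters: {bad}")
        return self

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(**(yaml.safe_load(fh) or {}))


def _design_from_config(cfg: PipelineConfig) -> SyntheticDesign:
    s = cfg.synthetic
    imaging = tuple(np.arange(0.0, 48.0 + 1e-9, s.imaging_step))
    return SyntheticDesign(
        compounds=tuple(s.compounds),
        doses={k: tuple(v) for k, v in s.doses.items()} if s.doses else None,
        imaging_times=imaging, n_replicates=s.n_replicates, sigma=s.sigma,
        knockdowns=tuple(s.knockdowns), seed=cfg.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the report dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    report: dict = {"config_hash": config.digest(),
                    "config": config.model_dump()}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                log.append({"stage": name, "status": "failed",
                            "error": f"{type(exc).__name__}: {exc}"})
                _write_log(out, log)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            log.append({"stage": name, "status": "ok",
                        "seconds": round(time.perf_counter() - t0, 3)})
            return result
        return deco

    params = reference_parameters()

    # --- data stage ---------------------------------------------------------
    if config.synthetic is not None:
        design = _design_from_config(config)

        @stage("generate")
        def replicates():
            reps, truth = generate_dataset(design, params, config.variant)
            reps.to_csv(out / "replicates.tsv", sep="\t", index=False)
            truth.observables.to_csv(out / "truth_observables.tsv", sep="\t",
                                     index=False)
            return reps
    else:
        design = SyntheticDesign()

        @stage("ingest")
        def replicates():
            return pd.read_csv(config.dataset_path, sep="\t")

    # --- alignment ----------------------------------------------------------
    @stage("align")
    def aligned():
        res = align_replicates(replicates)
        res.aligned.to_csv(out / "aligned.tsv", sep="\t", index=False)
        res.scalings.rename("s").to_csv(out / "scalings.tsv", sep="\t")
        report["alignment"] = {"sigma": res.sigma, "objective": res.objective}
        return res

    # --- fit ----------------------------------------------------------------
    conditions = make_conditions(design, params)

    @stage("fit")
    def fits():
        dataset = Dataset(aligned.aligned)
        problem = FitProblem(
            variant=config.variant,
            values={**params.as_dict()},
            free=tuple(config.free_parameters),
            dataset=dataset, conditions=conditions,
            obs_map=default_observation_map(),
            bounds_factor=config.bounds_factor)
        results = fit_multistart(problem, n_starts=config.n_starts,
                                 seed=config.seed, max_nfev=config.max_nfev)
        best = results[0]
        tab = pd.DataFrame([{"parameter": n, "estimate": best.values[n],
                             "truth": params[n] if n in PARAMETERS else None}
                            for n in problem.free])
        tab.to_csv(out / "fit_parameters.tsv", sep="\t", index=False)
        report["fit"] = {
            "objective": best.objective,
            "converged_starts": sum(r.converged for r in results),
            "n_starts": len(results),
            "estimates": best.theta(problem.free),
            "sigmas": best.sigmas,
        }
        return problem, results

    problem, results = fits
    best = results[0]

    # --- profiles -----------------------------------------------------------
    if config.profile_parameters:
        @stage("profile")
        def profiles():
            rows, out_profiles = [], {}
            for name in config.profile_parameters:
                pr = profile_likelihood(problem, best, name)
                truth_val = params[name] if name in PARAMETERS else None
                rows.append({
                    "parameter": name, "estimate": pr.estimate,
                    "ci_low": pr.ci[0], "ci_high": pr.ci[1],
                    "identifiability": pr.identifiability,
                    "truth": truth_val,
                    "covers_truth": (truth_val is not None and
                                     pr.ci[0] <= truth_val <= pr.ci[1]),
                })
                out_profiles[name] = pr
            pd.DataFrame(rows).to_csv(out / "profiles.tsv", sep="\t",
                                      index=False)
            report["profiles"] = rows
            return out_profiles
        _ = profiles

    # --- variant comparison -------------------------------------------------
    if config.compare_variants:
        @stage("compare")
        def comparison():
            other_variant = ("dissociation" if config.variant == "hinge_latch"
                             else "hinge_latch")
            other = FitProblem(
                variant=other_variant, values=dict(problem.values),
                free=problem.free, dataset=problem.dataset,
                conditions=problem.conditions, obs_map=problem.obs_map,
                bounds=dict(problem.bounds))
            other_results = fit_multistart(other, n_starts=config.n_starts,
                                           seed=config.seed,
                                           max_nfev=config.max_nfev)
            if config.variant == "hinge_latch":
                cmp = compare_variants(problem, best, other_results[0])
            else:
                cmp = compare_variants(problem, other_results[0], best)
            with open(out / "variant_comparison.json", "w") as fh:
                json.dump(cmp, fh, indent=2)
            report["variant_comparison"] = cmp
            return cmp
        _ = comparison

    # --- report -------------------------------------------------------------
    @stage("report")
    def final():
        if config.make_plots:
            from .plotting import plot_fit_overlay
            sim = problem.simulate(best.values)
            plot_fit_overlay(problem.dataset.records, sim, best.sigmas,
                             out / "fit_overlay.png",
                             title=f"variant={config.variant}")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        return report

    _write_log(out, log)
    return final


def _write_log(out: Path, log: list[dict]):
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
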