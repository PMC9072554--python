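"""Multi-start fitting, profile likelihood and nested model comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from nrf2dyn.estimation import (FitProblem, compare_variants,
                                fit_compound_extension, fit_multistart,
                                profile_likelihood)
from nrf2dyn.model import SPECIES_INDEX
from nrf2dyn.observation import (SIGMA_MIN, Dataset, default_observation_map,
                                 observe_trajectories)
from nrf2dyn.synthetic import (SyntheticDesign, generate_dataset,
                               make_conditions)

COARSE_TIMES = (0.0, 2.0, 4.0, 8.0, 16.0, 24.0, 36.0, 48.0)


@pytest.fixture(scope="module")
def small_design():
    return SyntheticDesign(seed=3, imaging_times=COARSE_TIMES,
                           doses={"DEM": (0.0, 316.0)}, include_qpcr=False,
                           include_gsh=False, n_replicates=1,
                           scaling_low=1.0, scaling_high=1.0)


def noise_free_dataset(theta, design, variant="hinge_latch"):
    design0 = SyntheticDesign(**{**design.__dict__, "sigma": 0.0})
    reps, gt = generate_dataset(design0, theta, variant)
    return Dataset(gt.observables), gt


@pytest.fixture(scope="module")
def small_problem(theta, small_design):
    ds, _ = noise_free_dataset(theta, small_design)
    return FitProblem(variant="hinge_latch", values=theta.as_dict(),
                      free=("k_clear_stress", "vmax_msrxn1"), dataset=ds,
                      conditions=make_conditions(small_design, theta),
                      obs_map=default_observation_map(), bounds_factor=100.0)


class TestFit:
    def test_noise_free_start_at_truth_reaches_floor(self, theta,
                                                     small_problem):
        """With perfect data the optimum is at truth with sigma at its floor."""
        fits = fit_multistart(small_problem, n_starts=1, seed=0,
                              include_nominal=True, max_nfev=5)
        best = fits[0]
        floor = len(small_problem.dataset) * math.log(SIGMA_MIN**2)
        assert best.objective == pytest.approx(floor, rel=1e-6)
        for name in small_problem.free:
            assert best.values[name] == pytest.approx(theta[name], rel=1e-6)

    def test_same_seed_is_bitwise_deterministic(self, small_problem):
        a = fit_multistart(small_problem, n_starts=3, seed=11, max_nfev=4)
        b = fit_multistart(small_problem, n_starts=3, seed=11, max_nfev=4)
        assert [r.objective for r in a] == [r.objective for r in b]
        assert all(ra.values == rb.values for ra, rb in zip(a, b))

    def test_recovery_from_lhs_starts(self, theta, small_design):
        """Multi-start on noisy data lands within a few percent of truth."""
        reps, gt = generate_dataset(small_design, theta)
        ds = Dataset(reps.drop(columns=["experiment"]))
        prob = FitProblem(variant="hinge_latch", values=theta.as_dict(),
                          free=("k_clear_stress", "vmax_msrxn1"), dataset=ds,
                          conditions=make_conditions(small_design, theta),
                          obs_map=default_observation_map(),
                          bounds_factor=30.0)
        best = fit_multistart(prob, n_starts=6, seed=2, max_nfev=120)[0]
        assert best.converged
        assert best.objective <= prob.objective(theta.as_dict()) + 1e-6
        for name in prob.free:
            assert best.values[name] == pytest.approx(theta[name], rel=0.25)

    def test_all_starts_failing_raises(self, small_problem):
        bad = FitProblem(variant="hinge_latch",
                         values={**small_problem.values,
                                 "k_clear_stress": 1.0},
                         free=("k_clear_stress",),
                         dataset=small_problem.dataset,
                         conditions=small_problem.conditions,
                         obs_map=small_problem.obs_map,
                         bounds={"k_clear_stress": (1e30, 1e32)})
        with pytest.raises(RuntimeError, match="starts failed"):
            fit_multistart(bad, n_starts=2, seed=0, max_nfev=3)


class TestProfile:
    def test_quadratic_objective_gives_closed_form_ci(self, theta,
                                                      small_design):
        """Profiling an observation scale on noise-free data: the objective is
        exactly quadratic in log s, so the 95% CI is analytic."""
        ds, _ = noise_free_dataset(theta, small_design)
        sigma = 0.25
        records = ds.records[ds.records["observable"] == "Nrf2_nuc"]
        ds_n = Dataset(records.reset_index(drop=True))
        omap = default_observation_map(sigma=sigma)
        prob = FitProblem(variant="hinge_latch",
                          values={**theta.as_dict(), "obs_s_Nrf2_nuc": 1.0},
                          free=("obs_s_Nrf2_nuc",), dataset=ds_n,
                          conditions=make_conditions(small_design, theta),
                          obs_map=omap, bounds_factor=100.0,
                          sigma_mode="fixed")
        fit = fit_multistart(prob, n_starts=1, seed=0, include_nominal=True,
                             max_nfev=5)[0]
        pr = profile_likelihood(prob, fit, "obs_s_Nrf2_nuc", init_step=0.01)
        n = len(ds_n)
        half_width = sigma * math.sqrt(3.84 / n)   # on the log scale
        assert pr.identifiability == "identifiable"
        assert math.log(pr.ci[1]) == pytest.approx(half_width, rel=0.05)
        assert math.log(pr.ci[0]) == pytest.approx(-half_width, rel=0.05)
        assert pr.ci[0] < fit.values["obs_s_Nrf2_nuc"] < pr.ci[1]

    def test_constructed_symmetry_is_flat(self, theta):
        """Srxn1 output depends on obs scale and translation rate only through
        their product, so freeing both leaves a flat profile."""
        design = SyntheticDesign(seed=5, imaging_times=(0.0, 8.0, 24.0, 48.0),
                                 doses={"DEM": (316.0,)}, include_qpcr=False,
                                 include_gsh=False, n_replicates=1,
                                 scaling_low=1.0, scaling_high=1.0)
        ds, _ = noise_free_dataset(theta, design)
        records = ds.records[ds.records["observable"] == "Srxn1_cyt"]
        prob = FitProblem(variant="hinge_latch",
                          values={**theta.as_dict(), "obs_s_Srxn1_cyt": 1.0,
                                  "obs_b_Srxn1_cyt": 0.0},
                          free=("obs_s_Srxn1_cyt", "k_transl_srxn1"),
                          dataset=Dataset(records.reset_index(drop=True)),
                          conditions=make_conditions(design, theta),
                          obs_map=default_observation_map(),
                          bounds_factor=10.0)
        fit = fit_multistart(prob, n_starts=1, seed=0, include_nominal=True,
                             max_nfev=5)[0]
        pr = profile_likelihood(prob, fit, "obs_s_Srxn1_cyt", init_step=0.15,
                                max_steps=6)
        assert pr.identifiability == "structurally non-identifiable"
        assert np.nanmax(pr.delta) < 0.01

    def test_profile_floor_is_fit_optimum(self, theta, small_problem):
        fit = fit_multistart(small_problem, n_starts=1, seed=0,
                             include_nominal=True, max_nfev=5)[0]
        pr = profile_likelihood(small_problem, fit, "vmax_msrxn1",
                                init_step=0.05, max_steps=8)
        assert np.nanmin(pr.delta) >= -1e-6
        assert pr.ci[0] <= fit.values["vmax_msrxn1"] <= pr.ci[1]

    def test_unconverged_fit_rejected(self, small_problem):
        from nrf2dyn.estimation import FitResult
        bad = FitResult({}, math.inf, {}, False, 0, 0, "hinge_latch")
        with pytest.raises(ValueError, match="converged"):
            profile_likelihood(small_problem, bad, "vmax_msrxn1")


class TestVariantComparison:
    def test_identical_fit_twice_gives_zero_difference(self, theta,
                                                       small_problem):
        fit = fit_multistart(small_problem, n_starts=1, seed=0,
                             include_nominal=True, max_nfev=5)[0]
        report = compare_variants(small_problem, fit, fit)
        assert report["objective_difference"] == 0.0
        assert (report["signature_hinge_latch"]
                == report["signature_dissociation"])

    def test_dip_contrast_between_variants(self, theta, small_problem):
        import json
        fit_hl = fit_multistart(small_problem, n_starts=1, seed=0,
                                include_nominal=True, max_nfev=5)[0]
        fit_ds = type(fit_hl)(dict(fit_hl.values), fit_hl.objective,
                              dict(fit_hl.sigmas), True, 0, 0, "dissociation")
        report = compare_variants(small_problem, fit_hl, fit_ds)
        assert not report["signature_hinge_latch"]["dips_below_baseline"]
        assert report["signature_dissociation"]["dips_below_baseline"]
        json.dumps(report)   # machine-readable summary

    def test_report_carries_both_objectives(self, small_problem):
        fit = fit_multistart(small_problem, n_starts=1, seed=0,
                             include_nominal=True, max_nfev=5)[0]
        report = compare_variants(small_problem, fit, fit)
        assert "objective_hinge_latch" in report
        assert "objective_dissociation" in report


@pytest.fixture(scope="module")
def omz_problem(theta):
    """OMZ data generated with a genuinely different Srxn1 degradation."""
    design = SyntheticDesign(
        seed=9, compounds=("OMZ",), doses={"OMZ": (47.0, 282.0)},
        imaging_times=COARSE_TIMES, include_qpcr=False, include_gsh=False,
        n_replicates=2, sigma=0.05, scaling_low=1.0, scaling_high=1.0)
    reps, _ = generate_dataset(design, theta)
    ds = Dataset(reps.drop(columns=["experiment"]))
    # baseline model: OMZ shares the DEM Srxn1 kinetics
    values = theta.as_dict()
    values["k_deg_srxn1_omz"] = values["k_deg_srxn1"]
    values["vmax_msrxn1_omz"] = values["vmax_msrxn1"]
    return FitProblem(variant="hinge_latch", values=values,
                      free=("k_clear_stress_omz",), dataset=ds,
                      conditions=make_conditions(design, theta),
                      obs_map=default_observation_map(),
                      bounds_factor=50.0)


class TestCompoundExtension:
    def test_zero_extra_parameters_is_a_plain_refit(self, omz_problem):
        base = fit_multistart(omz_problem, n_starts=1, seed=0,
                              include_nominal=True, max_nfev=60)[0]
        ext = fit_compound_extension(omz_problem, base, "OMZ", (),
                                     max_nfev=60)
        assert ext.fit.objective == pytest.approx(ext.base_objective,
                                                  abs=1e-6)

    def test_freeing_true_difference_improves_significantly(self, theta,
                                                            omz_problem):
        base = fit_multistart(omz_problem, n_starts=1, seed=0,
                              include_nominal=True, max_nfev=60)[0]
        ext = fit_compound_extension(
            omz_problem, base, "OMZ",
            ("k_deg_srxn1_omz", "vmax_msrxn1_omz"), max_nfev=120)
        assert ext.delta_objective > 3.84
        # freed rates head toward the generating values
        assert ext.fit.values["k_deg_srxn1_omz"] == pytest.approx(
            theta["k_deg_srxn1_omz"], rel=0.5)

    def test_disallowed_parameter_rejected(self, omz_problem):
        base = fit_multistart(omz_problem, n_starts=1, seed=0,
                              include_nominal=True, max_nfev=10)[0]
        with pytest.raises(ValueError, match="allowed"):
            fit_compound_extension(omz_problem, base, "OMZ",
                                   ("k_prod_nrf2",))
        with pytest.raises(ValueError, match="allowed"):
            fit_compound_extension(omz_problem, base, "DCF",
                                   ("k_deg_srxn1_omz",))
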