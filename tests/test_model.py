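"""Reaction network construction, inputs and deterministic simulation."""

import math

import numpy as np
import pytest

from nrf2dyn.model import (MODEL_PARAMETERS, SPECIES, SPECIES_INDEX, Condition,
                           KnockdownSpec, StimulusSpec, apply_knockdown,
                           build_model, complex_total, ode_rhs,
                           resolve_compound, simulate_condition,
                           stimulus_value)

KEAP1_POOLS = ("Keap1_free", "K1N2_latch", "K1N2_mod", "K1p62", "Keap1_auto")
NRF2_POOLS = ("Nrf2_free", "K1N2_latch", "K1N2_mod", "nNrf2")


class TestBuildModel:
    def test_hinge_latch_has_persistent_modified_complex(self):
        net = build_model("hinge_latch")
        mod = {r.name: r for r in net.reactions}["mod_complex"]
        assert mod.products == {"K1N2_mod": 1}
        # no reaction releases Nrf2_free from the stress-modified complex
        for r in net.reactions:
            if "K1N2_mod" in r.reactants:
                assert "Nrf2_free" not in r.products

    def test_dissociation_releases_nrf2(self):
        net = build_model("dissociation")
        mod = {r.name: r for r in net.reactions}["mod_complex"]
        assert mod.products == {"Keap1_free": 1, "Nrf2_free": 1}

    def test_variants_share_all_but_stress_modification(self):
        hl = {r.name: r for r in build_model("hinge_latch").reactions}
        ds = {r.name: r for r in build_model("dissociation").reactions}
        stress_steps = {"mod_complex", "mod_free"}
        shared_hl = {k: v for k, v in hl.items() if k not in stress_steps}
        shared_ds = {k: v for k, v in ds.items() if k not in stress_steps}
        assert shared_hl == shared_ds
        assert build_model("hinge_latch").species == build_model(
            "dissociation").species

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_model("induced_fit")

    @pytest.mark.parametrize("variant", ["hinge_latch", "dissociation"])
    def test_mass_bookkeeping_is_exact(self, variant):
        """Binding/transport steps conserve Keap1 and Nrf2 mass exactly."""
        net = build_model(variant)
        keap1 = np.array([s in KEAP1_POOLS for s in SPECIES], dtype=int)
        nrf2 = np.array([s in NRF2_POOLS for s in SPECIES], dtype=int)
        sources_sinks = {"prod", "deg", "clear", "transl", "stimulus"}
        for j, rx in enumerate(net.reactions):
            col = net.stoichiometry[:, j]
            if any(rx.name.startswith(p) for p in sources_sinks):
                continue
            assert keap1 @ col == 0, f"{rx.name} violates Keap1 mass"
            assert nrf2 @ col == 0, f"{rx.name} violates Nrf2 mass"


class TestStimulus:
    def test_peak_equals_dose(self):
        spec = StimulusSpec(dose=316.0, onset=10.0, center_offset=0.5,
                            width=0.25, dmso_background=False)
        assert stimulus_value(10.5, spec) == pytest.approx(316.0)

    def test_zero_before_onset_and_zero_dose(self):
        spec = StimulusSpec(dose=316.0, onset=5.0, dmso_background=False)
        assert stimulus_value(4.999, spec) == 0.0
        zero = StimulusSpec(dose=0.0, dmso_background=False)
        assert stimulus_value(7.3, zero) == 0.0

    def test_six_widths_out_is_negligible(self):
        spec = StimulusSpec(dose=316.0, onset=0.0, center_offset=0.5,
                            width=0.25, dmso_background=False)
        assert stimulus_value(0.5 + 1.5, spec) < 1e-6 * 316.0

    def test_background_only_after_onset(self):
        spec = StimulusSpec(compound="DMSO", dose=0.0, onset=2.0,
                            dmso_background=True)
        assert stimulus_value(1.0, spec, background=0.2) == 0.0
        assert stimulus_value(50.0, spec, background=0.2) == pytest.approx(0.2)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(dose=-1.0)
        with pytest.raises(ValueError):
            StimulusSpec(width=0.0)


class TestKnockdown:
    def test_control_is_identity(self, theta):
        assert apply_knockdown(theta, KnockdownSpec()).values == theta.values

    def test_sqstm1_switch_scales_only_p62_production(self, theta):
        kd = KnockdownSpec(target="SQSTM1", factor=0.2)
        out = apply_knockdown(theta, kd)
        for name in MODEL_PARAMETERS:
            if name in ("k_prod_p62", "k_transl_p62"):
                assert out[name] == pytest.approx(0.2 * theta[name])
            else:
                assert out[name] == theta[name]

    def test_vanishing_factor_kills_synthesis_flux(self, theta):
        kd = KnockdownSpec(target="KEAP1", factor=1e-9)
        out = apply_knockdown(theta, kd)
        assert out["k_prod_keap1"] < 1e-8
        assert out["k_transl_keap1"] < 1e-8

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            KnockdownSpec(target="TP53", factor=0.5)


class TestRhs:
    def test_zero_state_derivative_is_pure_production(self, theta):
        x0 = np.zeros(len(SPECIES))
        rhs = ode_rhs(x0, 0.0, theta, None, "hinge_latch")
        produced = {"Nrf2_free": "k_prod_nrf2", "Keap1_free": "k_prod_keap1",
                    "p62": "k_prod_p62", "mKEAP1": "k_basal_mkeap1",
                    "mNFE2L2": "k_basal_mnfe2l2", "mSQSTM1": "k_basal_msqstm1",
                    "mSRXN1": "k_basal_msrxn1", "GSH": "k_basal_gsh"}
        for i, s in enumerate(SPECIES):
            if s in produced:
                assert rhs[i] == pytest.approx(theta[produced[s]], rel=1e-12)
            else:
                assert rhs[i] == pytest.approx(0.0, abs=1e-15)

    def test_vanishes_at_steady_state(self, theta, steady_hl):
        rhs = ode_rhs(steady_hl.state0, 0.0, theta, None, "hinge_latch")
        assert np.max(np.abs(rhs)) < 1e-8

    def test_nonfinite_state_rejected(self, theta):
        bad = np.full(len(SPECIES), np.nan)
        with pytest.raises(ValueError):
            ode_rhs(bad, 0.0, theta, None, "hinge_latch")

    def test_network_rhs_matches_handwritten_subnetwork(self, theta):
        """Generated RHS equals closed-form rate laws for the Nrf2/Srxn1 rows."""
        rng = np.random.default_rng(42)
        p = theta.values
        for _ in range(100):
            x = rng.uniform(0.0, 3.0, size=len(SPECIES))
            rhs = ode_rhs(x, 0.0, theta, None, "hinge_latch")
            K, N = x[SPECIES_INDEX["Keap1_free"]], x[SPECIES_INDEX["Nrf2_free"]]
            latch = x[SPECIES_INDEX["K1N2_latch"]]
            nN = x[SPECIES_INDEX["nNrf2"]]
            m = x[SPECIES_INDEX["mSRXN1"]]
            srxn1 = x[SPECIES_INDEX["Srxn1"]]
            stress = x[SPECIES_INDEX["Stress"]]
            d_nrf2 = (p["k_prod_nrf2"] + p["k_unbind_k1n2"] * latch
                      - p["k_bind_k1n2"] * K * N - p["k_import_nrf2"] * N
                      + p["k_export_nrf2"] * nN - p["k_deg_nrf2"] * N
                      - p["k_mod_free"] * K * N * stress)
            d_nnrf2 = (p["k_import_nrf2"] * N - p["k_export_nrf2"] * nN
                       - p["k_deg_nnrf2"] * nN)
            hill = (p["vmax_msrxn1"] * nN ** p["h_msrxn1"]
                    / (p["K_msrxn1"] ** p["h_msrxn1"] + nN ** p["h_msrxn1"]))
            d_msrxn1 = p["k_basal_msrxn1"] + hill - p["k_deg_msrxn1"] * m
            d_srxn1 = p["k_transl_srxn1"] * m - p["k_deg_srxn1"] * srxn1
            assert abs(rhs[SPECIES_INDEX["Nrf2_free"]] - d_nrf2) < 1e-12
            assert abs(rhs[SPECIES_INDEX["nNrf2"]] - d_nnrf2) < 1e-12
            assert abs(rhs[SPECIES_INDEX["mSRXN1"]] - d_msrxn1) < 1e-10
            assert abs(rhs[SPECIES_INDEX["Srxn1"]] - d_srxn1) < 1e-12


class TestSimulation:
    def test_steady_state_invariance_without_stimulus(self, theta, steady_hl):
        times = tuple(np.linspace(0.0, 48.0, 13))
        cond = Condition(stimulus=StimulusSpec(dose=0.0, dmso_background=False),
                         horizon=48.0, observation_times=times)
        traj = simulate_condition("hinge_latch", theta, cond,
                                  x0=steady_hl.state0)
        drift = (np.abs(traj.states - steady_hl.state0)
                 / (steady_hl.state0 + 1e-9))
        assert drift.max() < 1e-6

    def test_solver_refinement_consistency(self, theta, steady_hl):
        times = tuple(np.arange(0.0, 25.0, 2.0))
        cond = Condition(stimulus=StimulusSpec(compound="DEM", dose=316.0),
                         horizon=24.0, observation_times=times)
        lo = simulate_condition("hinge_latch", theta, cond, x0=steady_hl.state0,
                                rtol=1e-8, atol=1e-10)
        hi = simulate_condition("hinge_latch", theta, cond, x0=steady_hl.state0,
                                rtol=1e-10, atol=1e-12)
        scale = np.maximum(np.abs(hi.states), 1e-6)
        assert np.max(np.abs(lo.states - hi.states) / scale) < 1e-4

    def test_trajectories_nonnegative(self, dem316_trajectories):
        assert dem316_trajectories.states.min() >= 0.0

    def test_nuclear_nrf2_rises_fast_then_relaxes(self, dem316_trajectories):
        traj = dem316_trajectories
        n = traj["nNrf2"]
        t_peak = traj.times[np.argmax(n)]
        assert 3.0 <= t_peak <= 5.0
        assert n.max() > 3 * n[0]
        assert n[-1] < 0.5 * n.max()   # slow relaxation, not sustained peak

    @pytest.mark.parametrize("variant", ["hinge_latch", "dissociation"])
    def test_nfe2l2_mrna_is_dose_independent(self, theta, steady_hl, variant):
        times = (0.0, 6.0, 24.0, 48.0)
        curves = []
        for dose in (0.0, 100.0, 561.0):
            cond = Condition(stimulus=StimulusSpec(compound="DEM" if dose else "DMSO",
                                                   dose=dose),
                             horizon=48.0, observation_times=times)
            traj = simulate_condition(variant, theta, cond, x0=steady_hl.state0)
            curves.append(traj["mNFE2L2"])
        for c in curves[1:]:
            np.testing.assert_allclose(c, curves[0], rtol=1e-9)

    def test_knockdown_switch_shifts_concentrations(self, theta, steady_hl):
        times = (0.0, 12.0, 24.0)
        cond = Condition(stimulus=StimulusSpec(compound="DMSO", dose=0.0),
                         knockdown=KnockdownSpec(target="KEAP1", factor=0.2),
                         horizon=24.0, observation_times=times)
        traj = simulate_condition("hinge_latch", theta, cond,
                                  x0=steady_hl.state0)
        # 72 h of reduced Keap1 synthesis raises nuclear Nrf2 above baseline
        assert traj["nNrf2"][0] > 2 * steady_hl.state0[SPECIES_INDEX["nNrf2"]]


class TestComplexTotal:
    def test_zero_trajectories(self, dem316_trajectories):
        import pandas as pd
        zeros = pd.DataFrame(0.0, index=range(5),
                             columns=["K1N2_latch", "K1N2_mod"])
        assert np.all(complex_total(zeros) == 0.0)

    def test_is_sum_of_latch_and_modified(self, dem316_trajectories):
        traj = dem316_trajectories
        np.testing.assert_allclose(complex_total(traj),
                                   traj["K1N2_latch"] + traj["K1N2_mod"])

    def test_missing_species_column_rejected(self):
        import pandas as pd
        with pytest.raises(KeyError):
            complex_total(pd.DataFrame({"nNrf2": [1.0]}))

    def test_variant_signature_dip_vs_no_dip(self, theta, steady_hl):
        from nrf2dyn.steady_state import solve_steady_state
        times = tuple(np.arange(0.0, 6.05, 0.1))
        cond = Condition(stimulus=StimulusSpec(compound="DEM", dose=316.0),
                         horizon=6.0, observation_times=times)
        hl = simulate_condition("hinge_latch", theta, cond, x0=steady_hl.state0)
        ss_d = solve_steady_state("dissociation", theta)
        ds = simulate_condition("dissociation", theta, cond, x0=ss_d.state0)
        hl_total, ds_total = complex_total(hl), complex_total(ds)
        assert hl_total.min() >= hl_total[0] * (1 - 1e-9)
        assert ds_total.min() < ds_total[0] * 0.99
        assert ds_total.max() > ds_total.min()   # dip is followed by recovery
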