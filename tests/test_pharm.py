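"""Dose–response fitting, operational model, and bias quantification."""

import numpy as np
import pandas as pd
import pytest

import korbias as kb
from korbias.pharm import DeltaDeltaLog, DeltaLog, TransductionCoefficient


def make_dr(ligand_params, pathway="G", log_conc=None, noise_sd=0.0, replicates=1, seed=0):
    pres = kb.AssayPrescription(
        ligands={lig: {pathway: p} for lig, p in ligand_params.items()},
        noise_sd=noise_sd,
        replicates=replicates,
        seed=seed,
        **({"log_conc": log_conc} if log_conc is not None else {}),
    )
    data, truth = kb.simulate_dose_response(pres)
    return data, truth


class TestOperationalResponse:
    def test_saturating_limit_is_emax_tau_over_tau_plus_one(self):
        # logτ = 0 (τ = 1), n = 1: plateau at Emax/2
        assert kb.operational_response(5.0, 0.0, -8.0) == pytest.approx(50.0, abs=1e-4)

    def test_half_maximal_concentration_closed_form(self):
        logtau, logka = 0.5, -8.0
        tau = 10.0**logtau
        ymax = 100.0 * tau / (tau + 1.0)
        ec50 = 10.0**logka / (tau + 1.0)
        y = kb.operational_response(np.log10(ec50), logtau, logka)
        assert y == pytest.approx(ymax / 2.0, rel=1e-9)

    def test_vanishes_at_zero_concentration_limit(self):
        assert kb.operational_response(-30.0, 1.0, -8.0, n=1.3) == pytest.approx(0.0, abs=1e-10)


class TestLogisticFit:
    def test_noise_free_parameter_recovery(self):
        x = np.linspace(-11, -5, 9)
        y = 0.0 + (100.0 - 0.0) / (1.0 + 10.0 ** (-8.0 - x))
        df = pd.DataFrame({"ligand": "L", "pathway": "G", "replicate": 1, "log_conc_M": x, "response": y})
        fit = kb.fit_logistic(df, hill_fixed=1.0)[("L", "G")]
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, abs=1e-6)
        assert fit.logec50 == pytest.approx(-8.0, abs=1e-6)

    def test_flat_data_flagged_degenerate(self):
        df = pd.DataFrame({"ligand": "L", "pathway": "G", "replicate": 1,
                           "log_conc_M": np.linspace(-11, -5, 6), "response": 7.0})
        fit = kb.fit_logistic(df)[("L", "G")]
        assert "degenerate_flat" in fit.flags

    def test_ec50_ratio_of_shifted_curves(self):
        x = np.linspace(-11, -5, 9)
        rows = []
        for lig, logec50 in (("A", -9.0), ("B", -8.0)):
            y = 100.0 / (1.0 + 10.0 ** (logec50 - x))
            rows.append(pd.DataFrame({"ligand": lig, "pathway": "G", "replicate": 1,
                                      "log_conc_M": x, "response": y}))
        fits = kb.fit_logistic(pd.concat(rows), hill_fixed=1.0)
        ratio = fits[("B", "G")].ec50 / fits[("A", "G")].ec50
        assert ratio == pytest.approx(10.0, rel=1e-6)


class TestNormalization:
    def test_linear_rescale_of_counts(self):
        x = np.linspace(-11, -5, 8)
        raw_ref = 500.0 + 1500.0 / (1.0 + 10.0 ** (-8.0 - x))
        test = np.full_like(x, 1250.0)  # halfway between baseline 500 and plateau 2000
        df = pd.DataFrame({
            "ligand": ["ref"] * 8 + ["test"] * 8,
            "pathway": "G", "replicate": 1,
            "log_conc_M": np.concatenate([x, x]),
            "response": np.concatenate([raw_ref, test]),
        })
        norm = kb.normalize_to_reference(df, "ref")
        np.testing.assert_allclose(norm[norm.ligand == "test"]["response"], 50.0, atol=1e-4)
        # reference plateau maps to 100%
        top_points = norm[(norm.ligand == "ref") & (norm.log_conc_M > -5.5)]["response"]
        assert top_points.iloc[0] == pytest.approx(100.0, abs=0.1)

    def test_idempotent(self):
        data, _ = make_dr({"ref": (0.5, -8.0), "t": (0.0, -7.0)})
        once = kb.normalize_to_reference(data, "ref")
        twice = kb.normalize_to_reference(once, "ref")
        np.testing.assert_allclose(twice["response"], once["response"], atol=1e-6)

    def test_missing_reference_rejected(self):
        data, _ = make_dr({"t": (0.0, -7.0)})
        with pytest.raises(ValueError):
            kb.normalize_to_reference(data, "ref")


class TestOperationalFit:
    def test_noise_free_global_recovery(self):
        data, truth = make_dr({"A": (0.5, -8.0), "B": (-0.3, -7.0)})
        fits = kb.fit_operational(data)
        for lig in ("A", "B"):
            t = truth[truth.ligand == lig].iloc[0]
            assert fits[lig].logtau == pytest.approx(t.logtau, abs=1e-3)
            assert fits[lig].logKA == pytest.approx(t.logKA, abs=1e-3)
            assert fits[lig].n == pytest.approx(1.0, abs=1e-3)

    def test_fitted_ec50_matches_closed_form(self):
        data, _ = make_dr({"A": (0.5, -8.0), "B": (-0.3, -7.0)})
        fits = kb.fit_operational(data)
        p = fits["A"]
        assert abs(p.ec50 - 10.0**p.logKA / (10.0**p.logtau + 1.0)) / p.ec50 < 1e-6

    def test_repeated_runs_deterministic(self):
        data, _ = make_dr({"A": (0.5, -8.0), "B": (0.2, -7.5)}, noise_sd=2.0, replicates=3)
        r1 = kb.fit_operational(data)
        r2 = kb.fit_operational(data)
        assert r1["A"].log_tau_ka == r2["A"].log_tau_ka

    def test_full_agonist_flagged_but_transduction_reported(self):
        # τ far above the bound: only log(τ/K_A) is identifiable
        data, truth = make_dr({"full": (3.5, -5.0), "partial": (-0.2, -7.5)})
        fits = kb.fit_operational(data)
        assert "logtau_near_bound" in fits["full"].flags
        assert np.isfinite(fits["full"].log_tau_ka)

    def test_multiple_pathways_rejected(self):
        pres = kb.example_assay_prescription()
        data, _ = kb.simulate_dose_response(pres)
        with pytest.raises(ValueError):
            kb.fit_operational(data)


class TestBiasArithmetic:
    def test_transduction_coefficient_value_and_propagated_se(self):
        p = kb.OperationalParams("L", "G", 0.5, -8.0, 1.0, 100.0, 8.5, 0.1, 0.2,
                                 np.sqrt(0.05))
        tc = kb.transduction_coefficient(p)
        assert tc.value == pytest.approx(8.5)
        assert tc.se == pytest.approx(np.sqrt(0.05))

    def test_delta_log_difference_and_se(self):
        t = TransductionCoefficient("L", "G", 9.0, 0.1)
        r = TransductionCoefficient("ref", "G", 8.5, 0.1)
        d = kb.delta_log(t, r)
        assert d.value == pytest.approx(0.5)
        assert d.se == pytest.approx(np.sqrt(0.02))

    def test_delta_log_reference_vs_itself_is_zero(self):
        r = TransductionCoefficient("ref", "G", 8.5, 0.1)
        assert kb.delta_log(r, r).value == 0.0

    def test_pathway_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kb.delta_log(
                TransductionCoefficient("L", "G", 9.0, 0.1),
                TransductionCoefficient("ref", "arr", 8.5, 0.1),
            )

    def test_ddelta_decomposition_reproduces_bias_factor_six(self):
        d_g = DeltaLog("nal", "ref", "G", 0.5, 0.05)
        d_arr = DeltaLog("nal", "ref", "arrestin", -0.278, 0.05)
        dd = kb.ddelta_log(d_g, d_arr)
        assert dd.value == pytest.approx(0.778)
        res = kb.bias_factor(dd, df=4)
        assert res.bias_factor == pytest.approx(6.0, abs=0.01)

    def test_ddelta_antisymmetric_in_pathway_order(self):
        d1 = DeltaLog("L", "ref", "G", 0.4, 0.1)
        d2 = DeltaLog("L", "ref", "arr", -0.1, 0.1)
        assert kb.ddelta_log(d1, d2).value == pytest.approx(-kb.ddelta_log(d2, d1).value)

    def test_ligand_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kb.ddelta_log(DeltaLog("A", "ref", "G", 0.0, 0.1),
                          DeltaLog("B", "ref", "arr", 0.0, 0.1))

    @pytest.mark.parametrize("dd,expected", [(0.0, 1.0), (1.0, 10.0)])
    def test_bias_factor_powers_of_ten(self, dd, expected):
        res = kb.bias_factor(DeltaDeltaLog("L", "ref", ("G", "arr"), dd, 0.1), df=4)
        assert res.bias_factor == pytest.approx(expected)
        assert res.ci_low <= res.bias_factor <= res.ci_high

    def test_bias_factor_reciprocal_symmetry(self):
        for d in (0.3, 0.778, 1.5):
            f_pos = kb.bias_factor(DeltaDeltaLog("L", "r", ("G", "a"), d, 0.1), df=4)
            f_neg = kb.bias_factor(DeltaDeltaLog("L", "r", ("G", "a"), -d, 0.1), df=4)
            assert f_neg.bias_factor == pytest.approx(1.0 / f_pos.bias_factor)

    def test_nonpositive_se_omits_ci_with_warning(self):
        res = kb.bias_factor(DeltaDeltaLog("L", "r", ("G", "a"), 0.5, 0.0), df=4)
        assert res.ci_low is None and res.warning is not None


class TestBiasPipeline:
    def test_reference_bias_factor_is_one_regardless_of_noise(self):
        data, _ = kb.simulate_dose_response(kb.example_assay_prescription(seed=11))
        res = kb.compute_bias(data, "U50,488", "G", "arrestin")
        assert res["U50,488"].bias_factor == 1.0
        assert res["U50,488"].ddelta == 0.0

    def test_null_ddelta_recovered_as_factor_one(self):
        # two ligands with identical transduction-coefficient offsets: ΔΔ = 0
        ligands = {
            "ref": {"G": (0.5, -7.5), "arr": (0.4, -7.2)},
            "t": {"G": (0.2, -8.0), "arr": (0.1, -7.7)},  # Δ = 0.2 in both pathways
        }
        data, _ = kb.simulate_dose_response(
            kb.AssayPrescription(ligands=ligands, noise_sd=0.0, replicates=2, seed=0)
        )
        res = kb.compute_bias(data, "ref", "G", "arr")
        assert res["t"].bias_factor == pytest.approx(1.0, abs=1e-3)

    def test_global_mode_recovers_known_bias(self):
        data, _ = kb.simulate_dose_response(
            kb.example_assay_prescription(seed=3, noise_sd=0.0, replicates=1)
        )
        res = kb.compute_bias(data, "U50,488", "G", "arrestin", mode="global")
        assert res["nalfurafine"].bias_factor == pytest.approx(6.0, rel=1e-3)
        assert res["WMS-X600"].bias_factor == pytest.approx(0.1, rel=1e-3)


class TestFoldChange:
    @pytest.mark.parametrize(
        "variant_nM,wt_nM,reported",
        [(108.0, 1.32, 82), (298.0, 1.28, 232), (210.0, 3.91, 54)],
    )
    def test_mutant_potency_losses(self, variant_nM, wt_nM, reported):
        fc = kb.potency_fold_change(variant_nM * 1e-9, wt_nM * 1e-9)
        assert abs(fc.rounded - reported) <= 1

    def test_identity(self):
        assert kb.potency_fold_change(1e-9, 1e-9).fold == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kb.potency_fold_change(0.0, 1e-9)

    def test_fold_change_table_log10(self):
        wt = {("L", "G"): 1e-9, ("L", "arr"): 2e-9}
        mut = {"W287A": {("L", "G"): 1e-7, ("L", "arr"): 2e-9}}
        table = kb.fold_change_table(wt, mut)
        assert table.loc["W287A", ("L", "G")] == pytest.approx(2.0)
        assert table.loc["W287A", ("L", "arr")] == pytest.approx(0.0)
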