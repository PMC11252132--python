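"""Residue selection, tensor fitting, resampling and exchange profiling."""

import math

import numpy as np
import pandas as pd
import pytest

from spinrelax.rates_io import RelaxationTable
from spinrelax.spin_physics import (
    DiffusionTensor,
    etaxy_from_tauc,
    jw_isotropic,
    predict_rates,
    r2r1_from_tauc,
    rex_bracket_factor,
)
from spinrelax.structure_tools import SpinGeometry
from spinrelax.synthetic_data import simulate_vectors
from spinrelax.tensor_fit import (
    CCRCalibration,
    ResamplingConfig,
    SelectionConfig,
    TensorFitResult,
    calibrate_s2,
    ccr_to_pseudo_ratios,
    compare_domain_tensors,
    fit_axial_tensor,
    predict_ratios,
    resample_tensor,
    rex_profile,
    select_residues,
)


def geometry_for(n, bfactors=None):
    vecs = simulate_vectors(n)
    return SpinGeometry(
        residues=np.arange(1, n + 1),
        vectors=vecs,
        n_bfactors=np.asarray(bfactors) if bfactors is not None else np.full(n, 20.0),
        flags=[""] * n,
    )


class TestSelection:
    def ratios_df(self, values, rel_err=0.05):
        idx = pd.Index(np.arange(1, len(values) + 1), name="residue")
        vals = np.asarray(values, dtype=float)
        return pd.DataFrame({"ratio": vals, "ratio_err": rel_err * vals}, index=idx)

    def test_relative_error_criterion_per_dataset_kind(self):
        df = self.ratios_df([150.0] * 10)
        df.loc[3, "ratio_err"] = 0.12 * 150.0  # 12% relative error
        geo = geometry_for(10)
        cfg = SelectionConfig()
        kept, audit = select_residues(df, geo, cfg, kind="r2r1_900")
        assert 3 not in kept and audit[3] == "ratio_error"
        # at 800 MHz the threshold is 15%, so 12% survives
        kept800, _ = select_residues(df, geo, cfg, kind="r2r1_800")
        assert 3 in kept800
        # CCR datasets tolerate up to 25%
        kept_ccr, _ = select_residues(df, geo, cfg, kind="ccr")
        assert 3 in kept_ccr

    def test_bfactor_criterion(self):
        df = self.ratios_df([150.0] * 5)
        geo = geometry_for(5, bfactors=[20, 20, 40, 20, 20])
        kept, audit = select_residues(df, geo, SelectionConfig(), "r2r1_900")
        assert audit[3] == "bfactor" and 3 not in kept

    def test_overlap_exclusion_list(self):
        df = self.ratios_df([150.0] * 5)
        cfg = SelectionConfig(overlap_exclusions=(2, 4))
        kept, audit = select_residues(df, geometry_for(5), cfg, "r2r1_900")
        assert audit[2] == "overlap" and audit[4] == "overlap"
        assert set(kept) == {1, 3, 5}

    def test_sd_trim_removes_outlier_ratio(self):
        rng = np.random.default_rng(0)
        values = 150.0 + rng.normal(scale=3.0, size=30)
        values[10] = values.mean() + 5 * values.std()
        df = self.ratios_df(values)
        kept, audit = select_residues(df, geometry_for(30), SelectionConfig(), "r2r1_900")
        assert audit[11] == "sd_trim"  # residue ids are 1-based

    def test_trim_threshold_tighter_for_ccr(self):
        cfg = SelectionConfig()
        assert cfg.trim_for("ccr") == 1.7
        assert cfg.trim_for("r2r1_900") == 2.0

    def test_empty_survivors_is_an_error(self):
        df = self.ratios_df([150.0] * 3, rel_err=0.5)
        with pytest.raises(ValueError):
            select_residues(df, geometry_for(3), SelectionConfig(), "r2r1_900")


class TestAxialFit:
    def test_noiseless_recovery_of_published_style_truth(self, fc900, truth_tensor):
        vecs = simulate_vectors(120)
        ratios = predict_ratios(
            truth_tensor.Dperp, truth_tensor.Dpar, truth_tensor.alpha,
            truth_tensor.beta, vecs, fc900,
        )
        fit = fit_axial_tensor(ratios, 0.01 * ratios, vecs, fc900)
        t = fit.tensor
        assert t.Dperp == pytest.approx(truth_tensor.Dperp, rel=1e-6)
        assert t.Dpar == pytest.approx(truth_tensor.Dpar, rel=1e-6)
        assert t.alpha == pytest.approx(truth_tensor.alpha, abs=1e-4)
        assert t.beta == pytest.approx(truth_tensor.beta, abs=1e-4)

    def test_isotropic_data_flags_undefined_orientation(self, fc900):
        vecs = simulate_vectors(60)
        ratios = np.full(60, r2r1_from_tauc(26.5, fc900))
        with pytest.warns(UserWarning, match="orientation is undefined"):
            fit = fit_axial_tensor(ratios, 0.01 * ratios, vecs, fc900)
        assert fit.tensor.zeta == pytest.approx(1.0, abs=0.02)

    def test_requires_enough_residues(self, fc900):
        vecs = simulate_vectors(5)
        with pytest.raises(ValueError):
            fit_axial_tensor(np.full(5, 150.0), np.full(5, 1.0), vecs, fc900)

    def test_canonical_result_from_symmetric_starts(self, fc900, truth_tensor):
        """Starting from symmetry-equivalent orientations converges to the
        one canonical (alpha, beta)."""
        vecs = simulate_vectors(80)
        ratios = predict_ratios(
            truth_tensor.Dperp, truth_tensor.Dpar, truth_tensor.alpha,
            truth_tensor.beta, vecs, fc900,
        )
        results = []
        # (alpha+180, 180-beta) is the antipodal representation of the
        # same symmetry axis
        for a0, b0 in [(11.0, 59.0), (191.0, 121.0)]:
            start = DiffusionTensor(0.5e7, 0.8e7, a0, b0)
            fit = fit_axial_tensor(
                ratios, 0.01 * ratios, vecs, fc900, multistart=False, x0=start
            )
            results.append((fit.tensor.alpha, fit.tensor.beta))
        for a, b in results:
            assert a == pytest.approx(results[0][0], abs=1e-3)
            assert b == pytest.approx(results[0][1], abs=1e-3)

    def test_modest_noise_keeps_truth_within_two_scaled_sd(self, fc900, truth_tensor):
        vecs = simulate_vectors(100)
        clean = predict_ratios(
            truth_tensor.Dperp, truth_tensor.Dpar, truth_tensor.alpha,
            truth_tensor.beta, vecs, fc900,
        )
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            noisy = clean * (1 + rng.normal(scale=0.03, size=len(clean)))
            fit = resample_tensor(
                noisy, 0.03 * clean, vecs, fc900,
                ResamplingConfig(repeats=40, seed=seed),
            )
            ok = (
                abs(fit.tensor.Dperp - truth_tensor.Dperp) < 2 * fit.uncertainties["Dperp"]
                and abs(fit.tensor.Dpar - truth_tensor.Dpar) < 2 * fit.uncertainties["Dpar"]
            )
            hits += ok
        assert hits >= n_seeds - 1


class TestCCRPathway:
    def test_round_trip_ratio_tauc_eta(self, fc900):
        calib = CCRCalibration()
        assert calib.S2 == 0.88
        tau = 27.8
        eta = etaxy_from_tauc(tau, calib.S2, fc900)
        table = RelaxationTable(
            pd.DataFrame(
                {"eta_xy": [eta], "eta_xy_err": [0.05 * eta]},
                index=pd.Index([1], name="residue"),
            )
        )
        df = ccr_to_pseudo_ratios(table, calib, fc900)
        assert df.loc[1, "tauC_ns"] == pytest.approx(tau, rel=1e-12)
        assert df.loc[1, "ratio"] == pytest.approx(r2r1_from_tauc(tau, fc900), rel=1e-12)

    def test_doubling_s2_halves_tauc(self, fc900):
        eta = etaxy_from_tauc(27.8, 0.44, fc900)
        table = RelaxationTable(
            pd.DataFrame(
                {"eta_xy": [eta], "eta_xy_err": [1.0]},
                index=pd.Index([1], name="residue"),
            )
        )
        t1 = ccr_to_pseudo_ratios(table, CCRCalibration(S2=0.44), fc900).loc[1, "tauC_ns"]
        t2 = ccr_to_pseudo_ratios(table, CCRCalibration(S2=0.88), fc900).loc[1, "tauC_ns"]
        assert t1 == pytest.approx(2 * t2, rel=1e-12)

    def test_nonpositive_eta_rejected(self, fc900):
        table = RelaxationTable(
            pd.DataFrame(
                {"eta_xy": [-2.0], "eta_xy_err": [1.0]},
                index=pd.Index([1], name="residue"),
            )
        )
        with pytest.raises(ValueError):
            ccr_to_pseudo_ratios(table, CCRCalibration(), fc900)

    def test_calibration_fixed_point_and_proportionality(self):
        assert calibrate_s2([20.0, 30.0], [20.0, 30.0], 0.88) == pytest.approx(0.88)
        # CCR mean 10% high -> S2 raised by 10%
        assert calibrate_s2([27.5], [25.0], 0.88) == pytest.approx(0.88 * 1.1)

    def test_calibration_recovers_generating_s2(self, fc900):
        """eta generated at S2=0.88, converted assuming S2=1, then
        recalibrated against the R2/R1 taucs -> 0.88."""
        rng = np.random.default_rng(7)
        true_taus = rng.uniform(24, 29, size=40)
        etas = np.array([etaxy_from_tauc(t, 0.88, fc900) for t in true_taus])
        from spinrelax.spin_physics import tauc_from_etaxy

        assumed = np.array([tauc_from_etaxy(e, 1.0, fc900) for e in etas])
        s2 = calibrate_s2(assumed, true_taus, 1.0)
        assert s2 == pytest.approx(0.88, rel=1e-9)


class TestResampling:
    def test_defaults_match_study_settings(self):
        cfg = ResamplingConfig()
        assert cfg.deletion_fraction == 0.20
        assert cfg.repeats == 100

    def test_deletion_fraction_bounds(self):
        with pytest.raises(ValueError):
            ResamplingConfig(deletion_fraction=0.5)

    def test_multiplier_is_sqrt_n_over_d(self, fc900, truth_tensor):
        vecs = simulate_vectors(100)
        clean = predict_ratios(
            truth_tensor.Dperp, truth_tensor.Dpar, truth_tensor.alpha,
            truth_tensor.beta, vecs, fc900,
        )
        fit = resample_tensor(
            clean, 0.02 * clean, vecs, fc900, ResamplingConfig(repeats=5, seed=0)
        )
        assert fit.uncertainties["multiplier"] == pytest.approx(math.sqrt(5.0))

    def test_seeded_determinism(self, fc900, truth_tensor):
        vecs = simulate_vectors(60)
        rng = np.random.default_rng(2)
        clean = predict_ratios(
            truth_tensor.Dperp, truth_tensor.Dpar, truth_tensor.alpha,
            truth_tensor.beta, vecs, fc900,
        )
        noisy = clean * (1 + rng.normal(scale=0.02, size=len(clean)))
        cfg = ResamplingConfig(repeats=20, seed=42)
        a = resample_tensor(noisy, 0.02 * clean, vecs, fc900, cfg)
        b = resample_tensor(noisy, 0.02 * clean, vecs, fc900, cfg)
        assert a.uncertainties == b.uncertainties

    def test_too_small_subsets_rejected(self, fc900):
        vecs = simulate_vectors(9)
        with pytest.raises(ValueError):
            resample_tensor(
                np.full(9, 150.0), np.full(9, 1.5), vecs, fc900,
                ResamplingConfig(deletion_fraction=0.3, repeats=5),
            )


class TestRexProfile:
    def make_table(self, fc, rex_at=None, tau_ns=26.5, sigma_r2=1.0, eta_err_frac=0.005):
        jw = lambda w: jw_isotropic(w, tau_ns * 1e-9)
        *_, eta = predict_rates(jw, fc)
        R2c = rex_bracket_factor(fc) * eta
        rows = []
        for res in range(1, 11):
            r2 = R2c + (rex_at or {}).get(res, 0.0)
            rows.append((res, r2, sigma_r2, eta, eta_err_frac * eta))
        df = pd.DataFrame(
            rows, columns=["residue", "R2", "R2_err", "eta_xy", "eta_xy_err"]
        ).set_index("residue")
        return RelaxationTable(df, field_mhz=900.0)

    def test_consistent_pairs_not_flagged(self, fc900):
        prof = rex_profile(self.make_table(fc900), fc900)
        assert np.allclose(prof["Rex"], 0.0, atol=1e-9)
        assert not prof["significant"].any()

    def test_injected_exchange_flagged(self, fc900):
        prof = rex_profile(self.make_table(fc900, rex_at={5: 8.0}), fc900)
        assert prof.loc[5, "Rex"] == pytest.approx(8.0, abs=1e-9)
        assert prof.loc[5, "significant"]
        assert prof["significant"].sum() == 1

    def test_threshold_is_strictly_greater_than_five(self, fc900):
        table = self.make_table(fc900)
        # craft sigma so Rex/sigma = 4.9 exactly
        df = table.data.copy()
        B = rex_bracket_factor(fc900)
        df.loc[5, "R2"] += 4.9
        df.loc[:, "R2_err"] = 1.0
        df.loc[:, "eta_xy_err"] = 1e-12
        prof = rex_profile(RelaxationTable(df), fc900)
        assert prof.loc[5, "Rex"] == pytest.approx(4.9, abs=1e-6)
        assert not prof.loc[5, "significant"]

    def test_missing_pairs_skipped_with_audit(self, fc900):
        table = self.make_table(fc900)
        df = table.data.copy()
        df.loc[3, "eta_xy"] = np.nan
        prof = rex_profile(RelaxationTable(df), fc900)
        assert 3 not in prof.index
        assert prof.attrs["skipped"] == [3]


class TestDomainComparison:
    def fit_for(self, fc, tensor, vecs, noise, seed):
        rng = np.random.default_rng(seed)
        clean = predict_ratios(
            tensor.Dperp, tensor.Dpar, tensor.alpha, tensor.beta, vecs, fc
        )
        noisy = clean * (1 + rng.normal(scale=noise, size=len(clean)))
        return resample_tensor(
            noisy, noise * clean, vecs, fc, ResamplingConfig(repeats=30, seed=seed)
        )

    def test_identical_fits_indistinguishable_and_symmetric(self, fc900, truth_tensor):
        vecs = simulate_vectors(60)
        fit = self.fit_for(fc900, truth_tensor, vecs, 0.02, 1)
        report = compare_domain_tensors(fit, fit)
        assert report["verdict"] == "indistinguishable"
        assert all(v == 0 for v in report["z_scores"].values())

    def test_distinct_domains_detected(self, fc900):
        # the two published-style per-domain tensors at modest noise
        pcasp = DiffusionTensor(0.52e7, 0.78e7, 18.0, 43.0)
        ig3 = DiffusionTensor(0.62e7, 0.72e7, 47.0, 131.0)
        vecs_a = simulate_vectors(55)
        vecs_b = simulate_vectors(55, scheme="uniform", seed=9)
        fa = self.fit_for(fc900, pcasp, vecs_a, 0.01, 3)
        fb = self.fit_for(fc900, ig3, vecs_b, 0.01, 4)
        fwd = compare_domain_tensors(fa, fb)
        rev = compare_domain_tensors(fb, fa)
        assert fwd["verdict"] == "distinct"
        assert fwd["z_scores"] == rev["z_scores"]

    def test_requires_resamples(self, fc900, truth_tensor):
        bare = TensorFitResult(tensor=truth_tensor, residues=np.arange(10), chi2=0.0)
        with pytest.raises(ValueError):
            compare_domain_tensors(bare, bare)
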