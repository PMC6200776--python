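"""Tests for the per-experiment estimators and aggregation."""

import numpy as np
import pandas as pd
import pytest

import bretfit as bf
from bretfit.fitting import IdentifiabilityError, InputDataError

from conftest import association_design, competition_design, saturation_design


class TestRatioAndBaseline:
    def test_ratio_from_channels_round_trip(self):
        table = bf.simulate_plate(saturation_design(noise_sd=1e-3))
        channels = bf.emit_channels(table, donor_level=1e6, seed=0, donor_cv=0.05)
        channels = channels.assign(bret_ratio=np.nan)
        out = bf.compute_bret_ratio(channels)
        np.testing.assert_allclose(out["bret_ratio"], table["bret_ratio"], rtol=1e-12)

    def test_simple_ratio(self):
        table = bf.simulate_plate(saturation_design()).head(1).copy()
        table["donor_em"], table["acceptor_em"], table["bret_ratio"] = 1e6, 2e4, np.nan
        assert bf.compute_bret_ratio(table)["bret_ratio"].iloc[0] == pytest.approx(0.02)

    def test_nonpositive_donor_excluded(self, caplog):
        table = bf.simulate_plate(saturation_design()).head(3).copy()
        table["acceptor_em"] = 2e4
        table["donor_em"] = [1e6, 0.0, 1e6]
        table["bret_ratio"] = np.nan
        with caplog.at_level("WARNING"):
            out = bf.compute_bret_ratio(table)
        assert len(out) == 2
        assert "nonpositive donor" in caplog.text

    def test_no_channels_no_ratio_errors(self):
        table = bf.simulate_plate(saturation_design()).copy()
        table["bret_ratio"] = np.nan
        with pytest.raises(InputDataError):
            bf.compute_bret_ratio(table)

    def test_baseline_correct_zeroes_vehicle_and_is_shift_invariant(self):
        table = bf.simulate_plate(association_design(noise_sd=1e-4, n_experiments=2))
        corrected = bf.baseline_correct(table)
        veh0 = corrected[
            (corrected["well_type"] == "vehicle") & (corrected["time_min"] == 0.0)
        ]
        for _, grp in veh0.groupby("experiment_id"):
            assert grp["bret_ratio"].mean() == pytest.approx(0.0, abs=1e-12)
        shifted = table.copy()
        shifted["bret_ratio"] = shifted["bret_ratio"] + 0.123
        np.testing.assert_allclose(
            bf.baseline_correct(shifted)["bret_ratio"],
            corrected["bret_ratio"],
            atol=1e-12,
        )

    def test_baseline_correct_recovers_specific_signal(self, nrp1_rates):
        table = bf.simulate_plate(association_design(noise_sd=0.0, n_experiments=1))
        corrected = bf.baseline_correct(table)
        spec = corrected[corrected["well_type"] == "total"]
        expected = bf.association_signal(
            spec["time_min"].to_numpy(),
            spec["probe_conc_nM"].to_numpy() * 1e-9,
            nrp1_rates,
            0.02,
        )
        np.testing.assert_allclose(spec["bret_ratio"], expected, atol=1e-12)

    def test_baseline_correct_missing_vehicle_names_experiment(self):
        table = bf.simulate_plate(
            association_design(noise_sd=0.0, n_experiments=1, include_vehicle=False)
        )
        with pytest.raises(InputDataError, match="E01"):
            bf.baseline_correct(table)


class TestSaturationFit:
    @pytest.mark.parametrize("kd_nM", [2.03, 4.41])
    def test_noiseless_recovery(self, kd_nM):
        gt = bf.EquilibriumBindingParams(
            kd=kd_nM * 1e-9, bmax=0.02, ns_slope=1e5, baseline=0.05
        )
        table = bf.simulate_plate(saturation_design(noise_sd=0.0, ground_truth=gt))
        summary = bf.fit_saturation(table)
        assert summary.mean["kd_nM"] == pytest.approx(kd_nM, rel=1e-6)
        assert summary.mean["bmax"] == pytest.approx(0.02, rel=1e-6)
        assert summary.mean["ns_slope"] == pytest.approx(1e5, rel=1e-4)

    def test_null_nonspecific_component(self):
        gt = bf.EquilibriumBindingParams(kd=4.41e-9, bmax=0.02, ns_slope=0.0, baseline=0.05)
        table = bf.simulate_plate(saturation_design(noise_sd=0.0, ground_truth=gt))
        summary = bf.fit_saturation(table)
        assert abs(summary.mean["ns_slope"]) < 1e-6 * 0.02 / 4.41e-9

    def test_all_nsb_table_rejected(self):
        table = bf.simulate_plate(saturation_design(noise_sd=0.0))
        with pytest.raises(InputDataError, match="NSB"):
            bf.fit_saturation(table[table["well_type"] == "nsb"])


class TestAssociationFit:
    def test_single_curve_noiseless_recovery(self, vegfr2_rates):
        # 1 nM at the slower receptor: k_obs = 0.0754 min^-1
        t = np.arange(0.0, 20.01, 0.5)
        L = 1e-9
        y = bf.association_signal(t, L, vegfr2_rates, 0.02)
        fit = bf.fit_association_single(t, y)
        assert fit.converged
        assert fit.parameters["k_obs"] == pytest.approx(0.0754, rel=1e-6)
        beq = 0.02 * L / (L + vegfr2_rates.kinetic_kd)
        assert fit.parameters["b_eq"] == pytest.approx(beq, rel=1e-6)

    def test_flat_trace_flagged(self):
        fit = bf.fit_association_single(np.arange(10.0), np.zeros(10))
        assert not fit.converged
        assert np.isnan(fit.parameters["k_obs"])

    def test_single_fit_rates_regress_to_global_rates(self, nrp1_rates):
        # k_obs from individual fits is linear in L: slope kon, intercept koff
        t = np.arange(0.0, 20.01, 0.5)
        concs = np.array([1e-9, 2.5e-9, 5e-9, 10e-9, 20e-9])
        kobs_hat = []
        for L in concs:
            y = bf.association_signal(t, L, nrp1_rates, 0.02)
            kobs_hat.append(bf.fit_association_single(t, y).parameters["k_obs"])
        slope, intercept = np.polyfit(concs, kobs_hat, 1)
        assert slope == pytest.approx(nrp1_rates.kon, rel=1e-4)
        assert intercept == pytest.approx(nrp1_rates.koff, rel=1e-4)

    def test_global_noiseless_recovery_nrp1(self, nrp1_rates):
        table = bf.baseline_correct(
            bf.simulate_plate(association_design(noise_sd=0.0))
        )
        summary = bf.fit_association_global(table)
        assert summary.mean["kon"] == pytest.approx(7.11e7, rel=1e-4)
        assert summary.mean["koff"] == pytest.approx(0.26, rel=1e-4)

    def test_global_kinetic_kd_vegfr2(self, vegfr2_rates):
        table = bf.baseline_correct(
            bf.simulate_plate(association_design(noise_sd=0.0, rates=vegfr2_rates))
        )
        summary = bf.fit_association_global(table)
        assert summary.mean["kinetic_kd_nM"] == pytest.approx(0.06 / 1.54e7 * 1e9, rel=1e-4)

    def test_row_order_invariance(self):
        table = bf.baseline_correct(
            bf.simulate_plate(association_design(noise_sd=1e-3, n_experiments=1))
        )
        shuffled = table.sample(frac=1.0, random_state=0)
        a = bf.fit_association_global(table)
        b = bf.fit_association_global(shuffled)
        assert a.mean["kon"] == pytest.approx(b.mean["kon"], rel=1e-6)

    def test_single_concentration_raises_identifiability(self, nrp1_rates):
        with pytest.warns(UserWarning):
            design = bf.SimulationDesign(
                mode="association",
                ground_truth=bf.AssociationTruth(rates=nrp1_rates),
                probe_concs=(5e-9,),
                timepoints=tuple(np.arange(0.0, 20.01, 0.5)),
                replicates=1,
                n_experiments=1,
                noise_sd=0.0,
            )
        table = bf.baseline_correct(bf.simulate_plate(design))
        with pytest.raises(IdentifiabilityError, match="fit_association_single"):
            bf.fit_association_global(table)


class TestCompetitionFit:
    def test_noiseless_pooled_pki(self):
        table = bf.simulate_plate(competition_design(noise_sd=0.0))
        results, summary = bf.fit_competition(table, 4.41e-9)
        assert summary.mean["pki"] == pytest.approx(9.54, abs=0.01)

    def test_per_curve_ic50s_match_closed_form(self):
        design = competition_design(noise_sd=0.0, n_experiments=1)
        gt = design.ground_truth
        results, _ = bf.fit_competition(bf.simulate_plate(design), gt.probe.kd)
        for L, curve in results[0].per_probe.items():
            expected = bf.ic50_from_ki(gt.ki, L, gt.probe.kd)
            assert curve["ic50"] == pytest.approx(expected, rel=1e-6)

    def test_regression_on_exact_points(self):
        ki, kd = 0.10e-9, 1.11e-9
        L = [0.5e-9, 1e-9, 2e-9, 3e-9, 5e-9]
        points = [(l, bf.ic50_from_ki(ki, l, kd)) for l in L]
        reg = bf.fit_ic50_regression(points)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)
        assert reg.intercept == pytest.approx(ki, rel=1e-10)
        assert reg.kd_estimate == pytest.approx(kd, rel=1e-8)

    def test_regression_nonpositive_slope_flagged(self):
        points = [(1e-9, 5e-10), (2e-9, 4e-10), (3e-9, 3e-10)]
        reg = bf.fit_ic50_regression(points)
        assert reg.slope < 0 and reg.kd_estimate is None

    def test_probe_dependence_anova_null(self):
        # same Ki at every probe concentration: ANOVA should not reject
        table = bf.simulate_plate(competition_design(noise_sd=5e-4, n_experiments=4))
        results, _ = bf.fit_competition(table, 4.41e-9)
        f_stat, p = bf.pki_probe_anova(results)
        assert p > 0.01

    def test_invalid_probe_kd(self):
        table = bf.simulate_plate(competition_design(n_experiments=1))
        with pytest.raises(ValueError):
            bf.fit_competition(table, 0.0)


class TestConcentrationResponseFit:
    def test_noiseless_pec50_recovery(self):
        design = bf.default_design("concentration_response", noise_sd=0.0, n_experiments=2)
        summary = bf.fit_concentration_response(bf.simulate_plate(design))
        assert summary.mean["pec50"] == pytest.approx(8.16, abs=1e-4)
        assert summary.mean["emax"] == pytest.approx(100.0, rel=1e-4)

    def test_scale_equivariance(self):
        design = bf.default_design("concentration_response", noise_sd=0.0, n_experiments=1)
        table = bf.simulate_plate(design)
        doubled = table.copy()
        doubled["bret_ratio"] = 2.0 * doubled["bret_ratio"]
        a = bf.fit_concentration_response(table)
        b = bf.fit_concentration_response(doubled)
        assert b.mean["emax"] == pytest.approx(2 * a.mean["emax"], rel=1e-6)
        assert b.mean["pec50"] == pytest.approx(a.mean["pec50"], abs=1e-6)

    def test_flat_response_flagged(self):
        design = bf.default_design("concentration_response", noise_sd=0.0, n_experiments=1)
        table = bf.simulate_plate(design)
        table["bret_ratio"] = 1.0
        with pytest.warns(UserWarning, match="unconverged"):
            summary = bf.fit_concentration_response(table)
        fit = summary.per_experiment[0]
        assert not fit.converged
        assert np.isnan(fit.parameters["pec50"])
        assert fit.parameters["emax"] == pytest.approx(fit.parameters["basal"])


class TestAggregation:
    @staticmethod
    def _fits(values, key="kd_nM"):
        return [
            bf.FitResult({key: v}, {key: 0.0}, 0.0, 10, True, f"E{i:02d}")
            for i, v in enumerate(values, 1)
        ]

    def test_mean_and_sem(self):
        summary = bf.aggregate_parameters(self._fits([2.0, 4.0]))
        assert summary.mean["kd_nM"] == 3.0
        assert summary.sem["kd_nM"] == pytest.approx(1.0)

    def test_identical_fits_zero_sem(self):
        summary = bf.aggregate_parameters(self._fits([5.0] * 4))
        assert summary.sem["kd_nM"] == 0.0

    def test_single_fit_sem_absent(self):
        summary = bf.aggregate_parameters(self._fits([5.0]))
        assert summary.sem["kd_nM"] is None

    def test_sem_formula(self):
        rng = np.random.default_rng(0)
        values = rng.normal(10.0, 2.0, 20)
        for vals in (values[:5], values):
            s = bf.aggregate_parameters(self._fits(vals))
            assert s.sem["kd_nM"] == pytest.approx(
                np.std(vals, ddof=1) / np.sqrt(len(vals))
            )

    def test_log_scale_aggregation(self):
        summary = bf.aggregate_parameters(
            self._fits([1e-9, 1e-8], key="ki"), scales={"ki": "log"}
        )
        assert summary.mean["log10_ki"] == pytest.approx(-8.5)

    def test_unconverged_excluded_with_warning(self):
        fits = self._fits([2.0, 4.0])
        fits.append(bf.FitResult({"kd_nM": 99.0}, {}, 0.0, 10, False, "E03"))
        with pytest.warns(UserWarning, match="unconverged"):
            summary = bf.aggregate_parameters(fits)
        assert summary.mean["kd_nM"] == 3.0
        assert summary.n == 2


class TestPower:
    def test_null_delta_gives_alpha(self):
        assert bf.power_delta_pki(5, 0.1, 0.0, alpha=0.05) == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_n(self):
        powers = [bf.power_delta_pki(n, 0.15, 0.3) for n in (3, 5, 8, 12)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_matches_monte_carlo_oracle(self):
        # 1e5 simulated two-sample t tests at n=5, sd=0.1, delta=0.3
        n, sd, delta, alpha, reps = 5, 0.1, 0.3, 0.05, 100_000
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, sd, (reps, n))
        b = rng.normal(delta, sd, (reps, n))
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        sp = np.sqrt(((n - 1) * va + (n - 1) * vb) / (2 * n - 2))
        tstat = (b.mean(axis=1) - a.mean(axis=1)) / (sp * np.sqrt(2.0 / n))
        from scipy import stats

        tcrit = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
        mc_power = np.mean(np.abs(tstat) > tcrit)
        assert bf.power_delta_pki(n, sd, delta, alpha) == pytest.approx(mc_power, abs=0.01)

    def test_invalid_alpha(self):
        with pytest.raises(InputDataError):
            bf.power_delta_pki(5, 0.1, 0.3, alpha=1.5)


class TestRecoveryUnderNoise:
    """Parameter recovery at the reference design: 5 experiments, duplicate
    wells, noise at 5% of the specific window; bias under 10%."""

    def test_saturation_bias(self):
        table = bf.simulate_plate(
            saturation_design(noise_sd=0.001, n_experiments=5, seed=101)
        )
        summary = bf.fit_saturation(table)
        assert abs(summary.mean["kd_nM"] - 4.41) / 4.41 < 0.10

    def test_association_bias(self):
        table = bf.baseline_correct(
            bf.simulate_plate(association_design(noise_sd=0.001, n_experiments=5, seed=102))
        )
        summary = bf.fit_association_global(table)
        assert abs(summary.mean["kon"] - 7.11e7) / 7.11e7 < 0.10
        assert abs(summary.mean["koff"] - 0.26) / 0.26 < 0.10

    def test_cross_mode_kd_consistency(self):
        """Saturation Kd, kinetic Kd and the IC50-regression Kd agree when the
        data share one ground truth (Kd = koff/kon)."""
        kd = 0.26 / 7.11e7  # 3.657 nM
        gt_sat = bf.EquilibriumBindingParams(kd=kd, bmax=0.02, ns_slope=1e5, baseline=0.05)
        sat = bf.fit_saturation(
            bf.simulate_plate(
                saturation_design(noise_sd=0.001, n_experiments=5, seed=7, ground_truth=gt_sat)
            )
        )
        kin = bf.fit_association_global(
            bf.baseline_correct(
                bf.simulate_plate(association_design(noise_sd=0.001, n_experiments=5, seed=8))
            )
        )
        comp_design = bf.SimulationDesign(
            mode="competition",
            ground_truth=bf.CompetitionTruth(probe=gt_sat, ki=1e-9),
            probe_concs=(0.5e-9, 1e-9, 2e-9, 3e-9, 5e-9),
            competitor_concs=(0.0,) + tuple(np.geomspace(1e-11, 1e-7, 11)),
            replicates=2,
            n_experiments=5,
            # lower noise here: the ratio estimator Kd = intercept/slope is
            # heavy-tailed once noise rivals the smallest probe's specific
            # window, so consistency is checked where it is well-behaved
            noise_sd=5e-4,
            seed=9,
        )
        _, comp = bf.fit_competition(bf.simulate_plate(comp_design), kd)
        kd_nM = kd * 1e9
        # each route recovers the shared truth within 3x its own SEM, and the
        # routes agree pairwise within combined Monte-Carlo error
        estimates = [
            (sat.mean["kd_nM"], sat.sem["kd_nM"]),
            (kin.mean["kinetic_kd_nM"], kin.sem["kinetic_kd_nM"]),
            (comp.mean["kd_estimate_nM"], comp.sem["kd_estimate_nM"]),
        ]
        for value, sem in estimates:
            assert abs(value - kd_nM) < 3 * sem + 0.02 * kd_nM
        for (va, sa), (vb, sb) in zip(estimates, estimates[1:]):
            assert abs(va - vb) < 3 * np.hypot(sa, sb) + 0.02 * kd_nM
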