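"""Breeding simulator: calibration, Mendelian inheritance, full experiments."""

import numpy as np
import pandas as pd
import pytest

from litvar.config import SimConfig
from litvar.exceptions import CalibrationError, ValidationError
from litvar.simulate import (
    _SeasonEffects,
    breed_next_generation,
    run_experiment,
    sample_parity_counts,
    simulate_base_population,
    simulate_doe_records,
    simulate_observed_variances,
)


class TestConfigValidation:
    def test_paper_design_accepted(self):
        cfg = SimConfig(does_per_line=125, sires_per_line=25, dams_per_sire=5)
        assert cfg.does_per_line == 125

    def test_mismatched_mating_structure_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(does_per_line=100, sires_per_line=25, dams_per_sire=5)

    def test_bad_probability_vector_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(parity_count_distribution=(0.5, 0.5, 0.1, 0, 0, 0, 0, 0))

    def test_infeasible_calibration_reported(self):
        # a heritability this large cannot coexist with the requested SD
        # given the estimator noise of the parity distribution
        cfg = SimConfig(h2_ve=0.9)
        with pytest.raises(CalibrationError):
            cfg.ve_trait_calibration()


class TestParityCounts:
    def test_degenerate_distribution(self, rng):
        cfg = SimConfig(parity_count_distribution=(0, 0, 1.0, 0, 0, 0, 0, 0))
        counts = sample_parity_counts(cfg, 500, rng)
        assert (counts == 4).all()

    def test_default_mean_four_and_a_half(self, rng):
        cfg = SimConfig()
        counts = sample_parity_counts(cfg, 100_000, rng)
        assert counts.min() >= 2 and counts.max() <= 9
        assert abs(counts.mean() - 4.5) < 0.05


class TestBasePopulation:
    def test_counts_and_sexes(self, rng):
        pop = simulate_base_population(SimConfig(), rng)
        assert (pop["sex"] == "F").sum() == 250
        assert (pop["sex"] == "M").sum() == 50
        assert (pop["sire"] == "0").all()

    def test_zero_heritability_zero_breeding_values(self, rng):
        pop = simulate_base_population(SimConfig(h2_ve=0.0), rng)
        assert np.allclose(pop["v_ve"], 0.0)

    def test_independent_traits_uncorrelated(self, rng):
        cfg = SimConfig(does_per_line=2500, sires_per_line=2500, dams_per_sire=1,
                        rg_ve_ls=0.0)
        pop = simulate_base_population(cfg, rng)
        r = np.corrcoef(pop["v_ve"], pop["u_ls"])[0, 1]
        assert abs(r) < 0.03

    def test_planted_genetic_correlation_recovered(self, rng):
        cfg = SimConfig(does_per_line=2500, sires_per_line=2500, dams_per_sire=1,
                        rg_ve_ls=0.8)
        pop = simulate_base_population(cfg, rng)
        r = np.corrcoef(pop["v_ve"], pop["u_ls"])[0, 1]
        assert r == pytest.approx(0.8, abs=0.03)


class TestObservedVarianceCalibration:
    def test_base_moments_match_targets(self, rng):
        cfg = SimConfig()
        n = 100_000
        cal = cfg.ve_trait_calibration()
        v = rng.normal(0, np.sqrt(cal["sigma2_v"]), n)
        npar = sample_parity_counts(cfg, n, rng)
        obs = simulate_observed_variances(v, npar, cfg, rng)
        assert obs.mean() == pytest.approx(cfg.ve_base_mean, rel=0.02)
        assert obs.std() == pytest.approx(cfg.ve_base_sd, rel=0.05)

    def test_parent_offspring_regression_recovers_h2(self, rng):
        cfg = SimConfig()
        n = 10_000
        cal = cfg.ve_trait_calibration()
        sv = np.sqrt(cal["sigma2_v"])
        v_par = rng.normal(0, sv, n)
        # offspring from unrelated co-parent: half the parent + Mendelian noise
        v_off = 0.5 * v_par + rng.normal(0, sv * np.sqrt(0.75), n)
        obs_par = simulate_observed_variances(v_par, sample_parity_counts(cfg, n, rng), cfg, rng)
        obs_off = simulate_observed_variances(v_off, sample_parity_counts(cfg, n, rng), cfg, rng)
        slope = np.polyfit(obs_par, obs_off, 1)[0]
        assert 2 * slope == pytest.approx(cfg.h2_ve, abs=0.02)


class TestMechanisticRecords:
    def _flat_config(self, **kw):
        return SimConfig(mode="mechanistic", year_season_sd=0.0,
                         parity_lactation_effects=(0.0, 0.0, 0.0), h2_ve=0.0, **kw)

    def test_planted_residual_variance_recovered(self, rng):
        # choose the base mean so the baseline residual variance is exactly 9
        probe = self._flat_config()
        defl = probe.ve_base_mean / np.exp(probe.eta0)
        cfg = self._flat_config(ve_base_mean=9.0 * defl, ls_base_mean=20.0)
        seasons = _SeasonEffects(0.0, rng)
        sizes = []
        for d in range(2500):
            rec = simulate_doe_records(f"d{d}", 4, cfg, seasons, rng)
            sizes.extend(rec["litter_size"])
        resid_var = np.var(sizes) - 1.0 / 12.0  # remove integer-rounding variance
        assert resid_var == pytest.approx(9.0, rel=0.05)

    def test_doubling_baseline_doubles_intra_doe_variance(self, rng):
        from litvar.variance import intra_doe_variance

        out = []
        probe = self._flat_config()
        defl = probe.ve_base_mean / np.exp(probe.eta0)
        for mean in (4.0, 8.0):
            cfg = self._flat_config(ve_base_mean=mean * defl, ls_base_mean=25.0)
            seasons = _SeasonEffects(0.0, rng)
            ve = [
                intra_doe_variance(
                    simulate_doe_records(f"d{d}", 9, cfg, seasons, rng)["litter_size"].to_numpy(float)
                )
                for d in range(3000)
            ]
            out.append(np.mean(ve))
        assert out[1] / out[0] == pytest.approx(2.0, abs=0.1)

    def test_first_parity_smaller_litters(self, rng):
        cfg = SimConfig(mode="mechanistic")
        seasons = _SeasonEffects(cfg.year_season_sd, rng)
        recs = pd.concat(
            [simulate_doe_records(f"d{d}", 5, cfg, seasons, rng) for d in range(2000)]
        )
        first = recs[recs["parity"] == 1]["litter_size"].mean()
        later = recs[recs["parity"] > 1]["litter_size"].mean()
        assert first < later


class TestBreeding:
    def test_mating_table_and_null_variance(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(h2_ve=0.0, h2_ls=0.0, repeatability_ls=0.0)
        sires = pd.DataFrame({"id": [f"s{i}" for i in range(25)], "v_ve": 0.0, "u_ls": 0.0})
        dams = pd.DataFrame({"id": [f"d{i}" for i in range(125)], "v_ve": 0.0, "u_ls": 0.0})
        off = breed_next_generation(dams, sires, cfg, rng)
        assert len(off) == 125
        assert np.allclose(off["v_ve"], 0.0) and np.allclose(off["u_ls"], 0.0)

    def test_full_sib_breeding_value_covariance(self):
        rng = np.random.default_rng(1)
        cfg = SimConfig(does_per_line=10_000, sires_per_line=10_000, dams_per_sire=1)
        g = cfg.genetic_covariance()
        n = 10_000
        sires = pd.DataFrame({"id": [f"s{i}" for i in range(n)],
                              "v_ve": rng.normal(0, np.sqrt(g[0, 0]), n),
                              "u_ls": rng.normal(0, np.sqrt(g[1, 1]), n)})
        dams = pd.DataFrame({"id": [f"d{i}" for i in range(n)],
                             "v_ve": rng.normal(0, np.sqrt(g[0, 0]), n),
                             "u_ls": rng.normal(0, np.sqrt(g[1, 1]), n)})
        sib1 = breed_next_generation(dams, sires, cfg, rng)
        sib2 = breed_next_generation(dams, sires, cfg, rng)
        cov = np.cov(sib1["v_ve"], sib2["v_ve"])[0, 1]
        se = g[0, 0] / np.sqrt(n)  # rough MC error scale
        assert cov == pytest.approx(0.5 * g[0, 0], abs=4 * se)

    def test_parent_count_validation(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig()
        sires = pd.DataFrame({"id": ["s0"], "v_ve": 0.0, "u_ls": 0.0}, index=[0])
        dams = pd.DataFrame({"id": ["d0"], "v_ve": 0.0, "u_ls": 0.0}, index=[0])
        with pytest.raises(ValidationError):
            breed_next_generation(dams, sires, cfg, rng)


class TestRunExperiment:
    def test_same_seed_bit_identical(self, small_config):
        a = run_experiment(small_config)
        b = run_experiment(small_config)
        pd.testing.assert_frame_equal(a.ve_records, b.ve_records)
        pd.testing.assert_frame_equal(a.pedigree.frame, b.pedigree.frame)
        pd.testing.assert_frame_equal(a.litter_records, b.litter_records)

    def test_structure_of_default_run(self, calibrated_experiment):
        data = calibrated_experiment
        ped = data.pedigree.frame
        does = ped[ped["sex"] == "F"]
        assert sorted(does["generation"].unique()) == list(range(11))
        for g in range(1, 11):
            for line in ("High", "Low"):
                assert ((does["generation"] == g) & (does["line"] == line)).sum() == 125
        # pedigree is generation-consistent: parents precede offspring
        pos = {a: i for i, a in enumerate(data.pedigree.ids)}
        for _, row in ped.iterrows():
            for p in (row["sire"], row["dam"]):
                if p != "0":
                    assert pos[p] < pos[row["id"]]

    def test_matched_differentials_hit_targets(self, calibrated_experiment):
        cfg = calibrated_experiment.config
        log = calibrated_experiment.selection_log
        targets = cfg.resolved_target_differentials()
        for line, key, sign in (("High", "high", 1), ("Low", "low", -1)):
            sub = log[log["line"] == line].sort_values("generation")
            got = sub["dam_differential_unweighted"].to_numpy()
            want = sign * np.asarray(targets[key])
            assert np.allclose(got, want, atol=0.16)

    def test_high_line_gains_variance_breeding_value(self, calibrated_experiment):
        ped = calibrated_experiment.pedigree.frame
        d10 = ped[(ped["generation"] == 10) & (ped["sex"] == "F")]
        hi = d10[d10["line"] == "High"]["v_ve"].mean()
        lo = d10[d10["line"] == "Low"]["v_ve"].mean()
        assert hi > lo

    def test_no_genetic_variance_no_response(self):
        """Planted h2 = 0: replicate-mean final-generation difference is ~0."""
        diffs = []
        for s in range(10):
            cfg = SimConfig(
                n_generations=4, does_per_line=25, sires_per_line=5,
                dams_per_sire=5, h2_ve=0.0, seed=6000 + s,
            )
            data = run_experiment(cfg)
            ve = data.ve_records
            last = ve[ve["generation"] == 4]
            diffs.append(
                last[last["line"] == "High"]["ve"].mean()
                - last[last["line"] == "Low"]["ve"].mean()
            )
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 4 * se + 0.05

    def test_no_selection_no_divergence(self):
        """selected_fraction = 1 leaves the lines statistically identical."""
        diffs = []
        for s in range(10):
            cfg = SimConfig(
                n_generations=4, does_per_line=25, sires_per_line=5,
                dams_per_sire=5, selected_fraction=1.0, seed=7000 + s,
            )
            data = run_experiment(cfg)
            ped = data.pedigree.frame
            last = ped[(ped["generation"] == 4) & (ped["sex"] == "F")]
            diffs.append(
                last[last["line"] == "High"]["v_ve"].mean()
                - last[last["line"] == "Low"]["v_ve"].mean()
            )
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 4 * se

    def test_mechanistic_precorrection_nearly_neutral(self):
        """With no systematic effects, corrected and raw variances agree."""
        cfg = SimConfig(
            mode="mechanistic", n_generations=2, does_per_line=25,
            sires_per_line=5, dams_per_sire=5, year_season_sd=0.0,
            parity_lactation_effects=(0.0, 0.0, 0.0), seed=3,
        )
        data = run_experiment(cfg)
        ve = data.ve_records
        r = np.corrcoef(ve["ve"], ve["vr"])[0, 1]
        assert r > 0.99
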