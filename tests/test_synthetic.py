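"""Generator contracts: determinism, moment matching, constructive noise
injection and ground-truth recoverability."""

import math

import numpy as np
import pandas as pd
import pytest

from thermacclim import respirometry as resp
from thermacclim.allometry import fit_mass_regression
from thermacclim.cardiac import cam_window_slope, compute_cam_table
from thermacclim.respirometry import RespirometryConfig, estimate_smr_from_traces
from thermacclim.synthetic import (
    SyntheticConfig,
    generate_cardiac_runs,
    generate_cohort,
    generate_respirometry_traces,
)


class TestConfigValidation:
    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="n_individuals"):
            SyntheticConfig(n_individuals=0)

    def test_negative_sd_rejected_naming_field(self):
        with pytest.raises(ValueError, match="trait_sds"):
            SyntheticConfig(
                trait_means={"WAM": {12: 1.8, 28: 4.2}},
                trait_sds={"WAM": {12: -0.5, 28: 1.2}},
            )

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="proportions"):
            SyntheticConfig(populations={"A": 0.5, "B": 0.2})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd_o2"):
            SyntheticConfig(noise_sd_o2=-1.0)


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        cfg = SyntheticConfig(n_individuals=50, seed=7)
        a, ta = generate_cohort(cfg)
        b, tb = generate_cohort(SyntheticConfig(n_individuals=50, seed=7))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta.records, tb.records)

    def test_identical_seed_identical_traces_and_runs(self, noise_free_config):
        cfg = noise_free_config
        cohort, truth = generate_cohort(cfg)
        t1 = generate_respirometry_traces(cohort, truth, cfg)
        t2 = generate_respirometry_traces(cohort, truth, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        r1, b1 = generate_cardiac_runs(cohort, truth, cfg)
        r2, b2 = generate_cardiac_runs(cohort, truth, cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(SyntheticConfig(n_individuals=20, seed=1))
        b, _ = generate_cohort(SyntheticConfig(n_individuals=20, seed=2))
        assert not a["WAM"].equals(b["WAM"])


class TestCohortStructure:
    def test_one_row_per_individual_per_temperature(self, small_cohort):
        _cfg, cohort, _truth = small_cohort
        counts = cohort.groupby("individual_id")["acclimation_temp"].agg(
            ["count", "nunique"]
        )
        assert (counts["count"] == 2).all()
        assert (counts["nunique"] == 2).all()

    def test_null_coupling_with_zero_noise_gives_flat_plasticity(self):
        cfg = SyntheticConfig(
            n_individuals=100,
            seed=3,
            plasticity_baseline_slope=0.0,
            plasticity_noise_sd=0.0,
        )
        _cohort, truth = generate_cohort(cfg)
        plast = truth.plasticity["log2_plasticity_WAM"].to_numpy()
        assert np.ptp(plast) == pytest.approx(0.0, abs=1e-12)

    def test_moment_matching_at_large_n(self):
        """Sample mean and SD of the mass-corrected values stay within
        three standard errors of the configured targets."""
        cfg = SyntheticConfig(n_individuals=5000, seed=3)
        _cohort, truth = generate_cohort(cfg)
        for trait in cfg.trait_means:
            for temp in (12, 28):
                sub = truth.records[truth.records.acclimation_temp == temp]
                v = sub[f"{trait}_corrected_true"].to_numpy()
                m, s = cfg.trait_means[trait][temp], cfg.trait_sds[trait][temp]
                se_mean = s / math.sqrt(v.size)
                se_sd = s / math.sqrt(2 * v.size)
                assert abs(v.mean() - m) < 3 * se_mean, (trait, temp, "mean")
                assert abs(v.std(ddof=1) - s) < 3.5 * se_sd, (trait, temp, "sd")

    def test_allometric_exponent_recovered_within_ci(self):
        cfg = SyntheticConfig(n_individuals=500, seed=13, allometric_exponent_b=0.8)
        cohort, _truth = generate_cohort(cfg)
        t12 = cohort[cohort.acclimation_temp == 12]
        fit = fit_mass_regression(
            t12["WAM"].to_numpy(), t12["body_mass_g"].to_numpy(), transform="log10"
        )
        assert abs(fit.slope_b - 0.8) <= 1.96 * fit.slope_se


class TestRespirometryTraces:
    def test_zero_noise_every_period_is_exact_line(self, noise_free_config):
        cfg = noise_free_config
        cohort, truth = generate_cohort(cfg)
        traces = generate_respirometry_traces(cohort.head(2), truth, cfg)
        for _, grp in traces.groupby(["individual_id", "period_id"]):
            fit = resp.fit_period_slope(
                grp["time_s"].to_numpy(), grp["o2_umol_per_l"].to_numpy()
            )
            assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_contaminated_periods_exactly_fail_filter(self):
        cfg = SyntheticConfig(
            n_individuals=2,
            seed=17,
            noise_sd_o2=0.0,
            activity_sigma=0.0,
            fraction_noisy_periods=0.2,
        )
        cohort, truth = generate_cohort(cfg)
        traces = generate_respirometry_traces(cohort, truth, cfg)
        for _, grp in traces.groupby(["individual_id", "acclimation_temp"]):
            failed = set()
            contaminated = set()
            for pid, per in grp.groupby("period_id"):
                fit = resp.fit_period_slope(
                    per["time_s"].to_numpy(), per["o2_umol_per_l"].to_numpy()
                )
                if not fit.r_squared >= 0.9:
                    failed.add(pid)
                if per["contaminated"].iloc[0]:
                    contaminated.add(pid)
            assert len(contaminated) == round(0.2 * cfg.n_periods)
            assert failed == contaminated

    def test_missing_true_smr_rejected(self, noise_free_config):
        cfg = noise_free_config
        cohort, truth = generate_cohort(cfg)
        truth.records = truth.records.iloc[1:]
        with pytest.raises(ValueError, match="no true SMR"):
            generate_respirometry_traces(cohort, truth, cfg)

    def test_default_noise_smr_recovery(self):
        """With study-condition noise (25 periods, activity scatter,
        sensor noise) the pipeline SMR lands within 7.5% of truth for at
        least 90% of individuals; the tolerance reflects the sampling
        noise of a 10th percentile estimated from ~25 replicates."""
        cfg = SyntheticConfig(n_individuals=20, seed=42)
        cohort, truth = generate_cohort(cfg)
        traces = generate_respirometry_traces(cohort, truth, cfg)
        rcfg = RespirometryConfig(
            chamber_volume_l=cfg.chamber_volume_l,
            background_slope=cfg.background_slope,
        )
        smr = estimate_smr_from_traces(
            traces.drop(columns=["contaminated"]), cohort, rcfg
        )
        m = smr.merge(
            truth.records[["individual_id", "acclimation_temp", "WAM_observed_true"]],
            on=["individual_id", "acclimation_temp"],
        )
        m = m[m.smr_mg_o2_h.notna()]
        rel_err = (m.smr_mg_o2_h / m.WAM_observed_true - 1.0).abs()
        assert (rel_err < 0.075).mean() >= 0.90


class TestCardiacRuns:
    def test_zero_noise_recovers_true_cam_exactly(self, noise_free_config):
        cfg = noise_free_config
        cohort, truth = generate_cohort(cfg)
        runs, blanks = generate_cardiac_runs(cohort, truth, cfg)
        cam = compute_cam_table(
            runs, blanks, chamber_volume_l=cfg.cardiac_chamber_volume_l
        )
        for sub in ("GLU", "FA", "LKA", "END"):
            got = cam[cam.substrate == sub].set_index(
                ["individual_id", "acclimation_temp"]
            )["cam_pmol_s"]
            want = truth.records.set_index(["individual_id", "acclimation_temp"])[
                f"CaM_{sub}_observed_true"
            ]
            np.testing.assert_allclose(got, want[got.index], rtol=1e-9)

    def test_background_contribution_is_the_correction(self, noise_free_config):
        """At zero noise, uncorrected minus corrected rate equals the
        configured background leak exactly."""
        cfg = noise_free_config
        cohort, truth = generate_cohort(cfg)
        runs, blanks = generate_cardiac_runs(cohort.head(1), truth, cfg)
        grp = runs[runs.substrate == "GLU"].sort_values("time_s")
        raw_slope = cam_window_slope(
            grp["time_s"].to_numpy(), grp["o2_umol_per_l"].to_numpy()
        )
        uncorrected = raw_slope * cfg.cardiac_chamber_volume_l * 1e6
        true = truth.records["CaM_GLU_observed_true"].iloc[0]
        bg_pmol = (
            cfg.cardiac_background_slope_umol_l_s * cfg.cardiac_chamber_volume_l * 1e6
        )
        assert uncorrected - true == pytest.approx(bg_pmol, rel=1e-9)

    def test_minimum_blanks_per_chamber_day(self, noise_free_config):
        cfg = noise_free_config
        cohort, truth = generate_cohort(cfg)
        _runs, blanks = generate_cardiac_runs(cohort, truth, cfg)
        per_day = blanks.groupby(["chamber_id", "day"])["blank_id"].nunique()
        assert (per_day >= 3).all()
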