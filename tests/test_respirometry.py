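"""Slope extraction, quality filtering, MO2 conversion and CFD-percentile SMR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermacclim.respirometry import (
    RespirometryConfig,
    SlopeFit,
    background_correct,
    compute_mo2,
    compute_smr,
    empirical_quantile,
    filter_slopes,
    fit_period_slope,
)


def brute_force_ols(x, y):
    """Longhand normal equations, independent of the implementation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, 1.0 - ss_res / ss_tot


class TestFitPeriodSlope:
    def test_exact_linear_decline(self):
        # 0.2 µmol min⁻¹ l⁻¹ decline sampled every 5 s for 6 min
        t = np.arange(0, 361, 5.0)
        o2 = 250.0 - 0.2 * (t / 60.0)
        fit = fit_period_slope(t, o2, period_id="p1")
        assert fit.k == pytest.approx(0.2, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == t.size

    def test_constant_o2_has_undefined_r2_and_fails_filter(self):
        t = np.arange(0, 100, 5.0)
        fit = fit_period_slope(t, np.full(t.size, 240.0))
        assert fit.k == 0.0
        assert np.isnan(fit.r_squared)
        assert filter_slopes([fit], RespirometryConfig()) == []

    def test_matches_longhand_ols_oracle(self, rng):
        t = np.sort(rng.uniform(0, 360, size=50))
        t += np.arange(50) * 1e-6  # ensure strictly increasing
        o2 = 250 - 0.005 * t + rng.normal(0, 0.5, size=50)
        fit = fit_period_slope(t, o2)
        slope, r2 = brute_force_ols(t, o2)
        assert fit.k == pytest.approx(-slope * 60.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    @pytest.mark.parametrize(
        "t, o2, match",
        [
            ([0, 5], [250, 249], "3 samples"),
            ([0, 5, 5], [250, 249, 248], "strictly increasing"),
            ([0, 5, 10], [250, np.nan, 248], "non-finite"),
        ],
    )
    def test_rejects_bad_periods(self, t, o2, match):
        with pytest.raises(ValueError, match=match):
            fit_period_slope(t, o2)


class TestFilterSlopes:
    @staticmethod
    def make(r2, k=0.2):
        return SlopeFit(period_id="p", k=k, r_squared=r2, n_points=10)

    def test_drops_low_r2(self):
        fits = [self.make(1.0)] * 20 + [self.make(0.5)] * 5
        assert len(filter_slopes(fits, RespirometryConfig())) == 20

    def test_identity_when_all_pass(self):
        fits = [self.make(1.0)] * 25
        assert filter_slopes(fits, RespirometryConfig()) == fits

    def test_retained_count_monotone_in_threshold(self, rng):
        fits = [self.make(r) for r in rng.uniform(0, 1, size=100)]
        counts = [
            len(filter_slopes(fits, RespirometryConfig(min_r_squared=th)))
            for th in np.linspace(0.0, 1.0, 21)
        ]
        assert counts == sorted(counts, reverse=True)


class TestBackgroundCorrect:
    def test_subtracts_chamber_background(self):
        fit = SlopeFit("p", k=0.25, r_squared=1.0, n_points=10, chamber_id="C1")
        cfg = RespirometryConfig(background_slope={"C1": 0.05})
        assert background_correct(fit, cfg).k == pytest.approx(0.20)

    def test_zero_background_is_identity(self):
        fit = SlopeFit("p", k=0.25, r_squared=1.0, n_points=10)
        assert background_correct(fit, RespirometryConfig()) == fit

    def test_negative_result_flagged_missing(self):
        fit = SlopeFit("p", k=0.03, r_squared=1.0, n_points=10)
        cfg = RespirometryConfig(background_slope=0.05)
        assert background_correct(fit, cfg) is None

    def test_unknown_chamber_raises(self):
        fit = SlopeFit("p", k=0.2, r_squared=1.0, n_points=10, chamber_id="C9")
        cfg = RespirometryConfig(background_slope={"C1": 0.05})
        with pytest.raises(KeyError, match="C9"):
            background_correct(fit, cfg)


class TestComputeMo2:
    def test_dimensional_analysis(self):
        # K=0.2 µmol min⁻¹ l⁻¹, 1 l chamber, 50 g fish at density 1:
        # V = 0.95 l; 0.2·0.95·60·32/1000 = 0.3648 mg O2 h⁻¹
        cfg = RespirometryConfig(chamber_volume_l=1.0, o2_molar_mass_g_per_mol=32.0)
        assert compute_mo2(0.2, 50.0, cfg) == pytest.approx(0.3648, abs=1e-12)

    def test_zero_slope_gives_zero(self):
        assert compute_mo2(0.0, 10.0, RespirometryConfig()) == 0.0

    def test_linear_in_effective_volume(self):
        # doubling V (at zero organism volume) doubles MO2 at fixed K
        small = RespirometryConfig(chamber_volume_l=1.0)
        big = RespirometryConfig(chamber_volume_l=2.0)
        assert compute_mo2(0.3, 0.0, big) == pytest.approx(
            2.0 * compute_mo2(0.3, 0.0, small)
        )

    def test_organism_filling_chamber_raises(self):
        cfg = RespirometryConfig(chamber_volume_l=0.1)
        with pytest.raises(ValueError, match="volume"):
            compute_mo2(0.2, 200.0, cfg)


class TestComputeSmr:
    def test_interpolated_tenth_percentile(self):
        # sorted 1..20: position 1 + 0.10·19 = 2.9 → value 2.9
        mr = compute_smr(np.arange(1.0, 21.0), RespirometryConfig())
        assert mr.mo2 == pytest.approx(2.9, abs=1e-12)
        assert mr.n_replicates_used == 20

    def test_constant_rates(self):
        mr = compute_smr([3.3] * 25, RespirometryConfig())
        assert mr.mo2 == pytest.approx(3.3)

    def test_too_few_replicates_raises_with_count(self):
        with pytest.raises(ValueError, match="19"):
            compute_smr(np.ones(19), RespirometryConfig(), individual_id="F1")

    def test_permutation_invariant(self, rng):
        rates = rng.uniform(1, 5, size=30)
        a = compute_smr(rates, RespirometryConfig()).mo2
        b = compute_smr(rng.permutation(rates), RespirometryConfig()).mo2
        assert a == b

    @given(st.lists(st.floats(0.1, 100.0), min_size=20, max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_smr_within_observed_range(self, rates):
        mr = compute_smr(rates, RespirometryConfig())
        assert min(rates) <= mr.mo2 <= max(rates)

    def test_quantile_matches_sorted_order_statistic_oracle(self, rng):
        for n in range(20, 41):
            rates = rng.uniform(0.5, 8.0, size=n)
            v = np.sort(rates)
            h = (n - 1) * 0.10
            lo = int(np.floor(h))
            expected = v[lo] + (h - lo) * (v[lo + 1] - v[lo])
            assert empirical_quantile(rates, 0.10) == pytest.approx(
                expected, abs=1e-12
            )


def test_pipeline_scale_equivariance(rng):
    """Scaling all O2 values by c scales K, MO2 and SMR by c."""
    cfg = RespirometryConfig(min_replicates=20)
    t = np.arange(0, 361, 5.0)
    c = 3.7
    rates, rates_scaled = [], []
    for _ in range(25):
        o2 = 250 - 0.004 * t + rng.normal(0, 0.2, t.size)
        k = fit_period_slope(t, o2).k
        k_scaled = fit_period_slope(t, c * o2).k
        assert k_scaled == pytest.approx(c * k, rel=1e-12)
        rates.append(compute_mo2(k, 10.0, cfg))
        rates_scaled.append(compute_mo2(k_scaled, 10.0, cfg))
    smr = compute_smr(rates, cfg).mo2
    smr_scaled = compute_smr(rates_scaled, cfg).mo2
    assert smr_scaled == pytest.approx(c * smr, rel=1e-12)


def test_config_validation():
    with pytest.raises(ValueError, match="smr_percentile"):
        RespirometryConfig(smr_percentile=1.5)
    with pytest.raises(ValueError, match="min_replicates"):
        RespirometryConfig(min_replicates=0)
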