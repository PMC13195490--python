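"""Validation statistics, per-pixel trends, stratum series, age projection."""

import numpy as np
import pytest

from shrubcasa import (
    CarbonPoolLedger,
    gc_m2_to_tco2_ha,
    leakage_share,
    paired_validation,
    pixel_trend,
    project_by_age,
    stratum_timeseries,
)
from shrubcasa.validation import TrendClass


class TestPairedValidation:
    def test_perfect_agreement(self):
        x = [10.0, 20.0, 30.0, 40.0]
        s = paired_validation(x, x)
        assert s.pearson_r == pytest.approx(1.0)
        assert s.slope == pytest.approx(1.0)
        assert s.r_squared == pytest.approx(1.0)
        assert s.rmse == 0.0

    def test_constant_shift(self):
        mea = np.array([10.0, 20.0, 30.0, 40.0])
        s = paired_validation(mea + 5.0, mea)
        assert s.slope == pytest.approx(1.0)
        assert s.r_squared == pytest.approx(1.0)
        assert s.rmse == pytest.approx(5.0)
        assert s.rmse_fitted == pytest.approx(0.0, abs=1e-9)

    def test_five_point_hand_case(self):
        """All statistics match brute-force closed-form evaluation."""
        mea = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        est = np.array([1.2, 1.9, 3.4, 3.9, 5.6])
        s = paired_validation(est, mea)
        # brute force
        slope = np.sum((mea - 3) * (est - est.mean())) / np.sum((mea - 3) ** 2)
        intercept = est.mean() - slope * 3
        pred = intercept + slope * mea
        r = np.corrcoef(mea, est)[0, 1]
        r2 = 1 - np.sum((est - pred) ** 2) / np.sum((est - est.mean()) ** 2)
        assert s.slope == pytest.approx(slope, abs=1e-10)
        assert s.intercept == pytest.approx(intercept, abs=1e-10)
        assert s.pearson_r == pytest.approx(r, abs=1e-10)
        assert s.r_squared == pytest.approx(r2, abs=1e-10)
        assert s.rmse == pytest.approx(
            np.sqrt(np.mean((est - mea) ** 2)), abs=1e-10)
        assert s.r_squared == pytest.approx(s.pearson_r ** 2, abs=1e-10)

    def test_random_inputs_match_closed_form(self, rng):
        mea = rng.uniform(0, 100, 50)
        est = 1.1 * mea + rng.normal(0, 5, 50)
        s = paired_validation(est, mea)
        sxx = np.sum((mea - mea.mean()) ** 2)
        sxy = np.sum((mea - mea.mean()) * (est - est.mean()))
        assert s.slope == pytest.approx(sxy / sxx, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_validation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            paired_validation([1.0, 2.0], [1.0, 2.0])


class TestPixelTrend:
    def test_linear_series_classified_increase(self):
        years = {2013 + i: np.full((3, 3), 100.0 + 5.0 * i) + 0.01 *
                 np.arange(9).reshape(3, 3) * (i % 2) for i in range(6)}
        slope, p, cls, fr = pixel_trend(years)
        assert np.all(np.asarray(cls) == TrendClass.INCREASE)
        assert fr["increase"] == 1.0

    def test_constant_series_stable(self):
        years = {2013 + i: np.full((3, 3), 50.0) for i in range(5)}
        slope, p, cls, fr = pixel_trend(years)
        assert np.all(np.asarray(slope) == 0)
        assert fr["stable"] == 1.0

    def test_needs_four_years(self):
        years = {2013 + i: np.zeros((2, 2)) for i in range(3)}
        with pytest.raises(ValueError, match="4 years"):
            pixel_trend(years)

    def test_type_one_error_near_alpha(self):
        """White-noise series: non-stable fraction ~ alpha over 10,000 cells."""
        rng = np.random.default_rng(12345)
        years = {2013 + i: rng.normal(0, 1, (100, 100)) for i in range(11)}
        *_, fr = pixel_trend(years, alpha=0.05)
        assert fr["stable"] == pytest.approx(0.95, abs=0.015)


class TestStratumTimeseries:
    def test_constructed_linear_trend(self):
        """Grids built as 100 + 2.63 (year - 2013) recover that coefficient."""
        zones = np.tile([1, 2, 3], (3, 1))
        years = {y: np.full((3, 3), 100.0 + 2.63 * (y - 2013))
                 for y in range(2013, 2024)}
        df, coef = stratum_timeseries(years, zones)
        assert coef == pytest.approx(2.63, rel=1e-9)

    def test_constant_grids_zero_coefficient(self):
        zones = np.ones((2, 2), int)
        years = {y: np.full((2, 2), 7.0) for y in range(2013, 2018)}
        _, coef = stratum_timeseries(years, zones)
        assert coef == pytest.approx(0.0, abs=1e-9)

    def test_uniform_grid_zonal_means(self):
        zones = np.array([[1, 2], [3, 1]])
        years = {y: np.full((2, 2), 3.5) for y in range(2013, 2018)}
        df, _ = stratum_timeseries(years, zones)
        for name in ("SHADY_SLOPE", "SUNNY_SLOPE", "GULLY_BOTTOM"):
            assert np.allclose(df[name], 3.5)


def _linear_ledgers(ages, slopes, intercepts):
    out = []
    for age in ages:
        pools = {p: slopes[p] * age + intercepts[p]
                 for p in ("above", "below", "herb", "litter", "soil")}
        out.append(CarbonPoolLedger(f"p{age}", age, "X", **pools))
    return out


class TestProjection:
    slopes = {"above": 100.0, "below": 30.0, "herb": 2.0, "litter": 0.0,
              "soil": 150.0}
    intercepts = {"above": -300.0, "below": -80.0, "herb": 10.0,
                  "litter": 12.0, "soil": 600.0}

    def test_closed_loop_linear_models(self):
        """Ledgers from known linear age models reproduce the closed form."""
        leds = _linear_ledgers([5, 6, 7, 8, 9, 10], self.slopes,
                               self.intercepts)
        proj = project_by_age(leds, max_age=10, leakage=0.0)
        for _, row in proj.table.iterrows():
            age = row["age"]
            for pool in ("above", "below", "herb", "soil"):
                expect = max(self.slopes[pool] * age + self.intercepts[pool],
                             0.0)
                assert row[pool] == pytest.approx(expect, rel=1e-9), (age, pool)
            assert row["litter"] == pytest.approx(12.0, rel=1e-12)
            gross = (row["above"] + row["below"] + row["herb"]
                     + row["litter"] + row["soil"])
            assert row["gross_tco2_ha"] == pytest.approx(
                gc_m2_to_tco2_ha(gross), rel=1e-12)

    def test_leakage_exceeding_year1_gross(self):
        leds = _linear_ledgers([5, 7, 9], self.slopes, self.intercepts)
        proj = project_by_age(leds, max_age=10, leakage=1e4)
        assert proj.table["net_tco2_ha"].iloc[0] < 0

    def test_needs_three_ages(self):
        leds = _linear_ledgers([5, 6], self.slopes, self.intercepts)
        with pytest.raises(ValueError, match="3 distinct ages"):
            project_by_age(leds, max_age=10, leakage=0.0)

    def test_cumulative_curve_non_decreasing_with_nonneg_slopes(self):
        leds = _linear_ledgers([5, 6, 7, 8, 9, 10], self.slopes,
                               self.intercepts)
        proj = project_by_age(leds, max_age=12, leakage=3.31)
        assert np.all(np.diff(proj.table["net_tco2_ha"]) >= -1e-9)

    def test_first_net_positive_year_reported(self):
        leds = _linear_ledgers([5, 6, 7, 8, 9, 10], self.slopes,
                               self.intercepts)
        proj = project_by_age(leds, max_age=10, leakage=3.31,
                              baseline_tco2_ha=25.0)
        y = proj.first_net_positive_year
        assert y is not None
        assert proj.table["net_tco2_ha"].iloc[y - 1] > 0
        if y > 1:
            assert proj.table["net_tco2_ha"].iloc[y - 2] <= 0


class TestLeakageShare:
    def test_worked_example(self):
        # machinery emissions over a 10-year cumulative sequestration
        assert leakage_share(3.31, 91.0) == pytest.approx(3.637, abs=0.001)
        assert round(leakage_share(3.31, 91.0), 1) == 3.6

    def test_rejects_nonpositive_gross(self):
        with pytest.raises(ValueError):
            leakage_share(3.31, 0.0)
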