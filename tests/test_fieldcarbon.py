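"""Allometric fitting/recovery, pool carbon arithmetic, ledger conservation."""

import numpy as np
import pandas as pd
import pytest

from shrubcasa import (
    AllometricModel,
    CarbonFractions,
    CarbonPoolLedger,
    Component,
    ModelForm,
    build_ledger,
    fit_allometric,
    herb_litter_carbon,
    net_sequestration,
    predict_biomass,
    soil_carbon_density,
)

ABOVE_TRUTH = (0.228, 0.1, 2.488, 0.006)
BELOW_TRUTH = (0.018, 0.1, 3.981, 0.073)


def _power_samples(coef, n=28, seed=0, sigma=0.0):
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.8, 3.0, n)
    h = rng.uniform(0.8, 2.8, n)
    a, b, c, d4 = coef
    w = a * d ** b * h ** c + d4
    if sigma > 0:
        w = w * rng.lognormal(0.0, sigma, n)
    return d, h, w


class TestAllometricFit:
    @pytest.mark.parametrize("truth", [ABOVE_TRUTH, BELOW_TRUTH])
    def test_noise_free_power_recovery(self, truth):
        """Noise-free samples recover the generating coefficients, R^2 = 1."""
        d, h, w = _power_samples(truth)
        m = AllometricModel(form=ModelForm.POWER_DH).fit(d, h, w)
        np.testing.assert_allclose(m.coef_, truth, rtol=1e-4)
        assert m.r_squared_ == pytest.approx(1.0, abs=1e-10)

    def test_noise_free_cubic_recovery(self):
        truth = (0.194, -0.503, 0.526, 0.021)  # (c0, c1, c2, c3)
        rng = np.random.default_rng(1)
        h = rng.uniform(0.9, 2.8, 24)
        w = truth[0] + truth[1] * h + truth[2] * h ** 2 + truth[3] * h ** 3
        assert np.all(w > 0)
        m = AllometricModel(form=ModelForm.CUBIC_H).fit(np.ones_like(h), h, w)
        np.testing.assert_allclose(m.coef_, truth, rtol=1e-6)
        assert m.r_squared_ == pytest.approx(1.0, abs=1e-12)

    def test_constant_biomass_degenerate(self):
        with pytest.raises(ValueError, match="SST = 0"):
            AllometricModel(form=ModelForm.CUBIC_H).fit(
                np.ones(8), np.linspace(1, 2, 8), np.full(8, 1.5))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 6"):
            AllometricModel().fit(np.ones(5), np.ones(5), np.ones(5))

    def test_noisy_fit_within_bootstrap_interval(self):
        """With lognormal noise the estimate stays inside a seeded bootstrap CI."""
        d, h, w = _power_samples(ABOVE_TRUTH, n=28, seed=3, sigma=0.1)
        m = AllometricModel(form=ModelForm.POWER_DH, seed=3).fit(d, h, w)
        assert m.r_squared_ < 1.0
        rng = np.random.default_rng(99)
        boot = []
        for _ in range(60):
            idx = rng.integers(0, len(d), len(d))
            try:
                bm = AllometricModel(form=ModelForm.POWER_DH, seed=0).fit(
                    d[idx], h[idx], w[idx])
            except (ValueError, RuntimeError):
                continue
            boot.append(bm.coef_)
        boot = np.array(boot)
        lo, hi = np.percentile(boot, [0.5, 99.5], axis=0)
        for truth_i, lo_i, hi_i in zip(ABOVE_TRUTH, lo, hi):
            assert lo_i <= truth_i <= hi_i

    def test_exclusion_flag(self):
        d, h, w = _power_samples(ABOVE_TRUTH, n=20)
        w_bad = w.copy()
        w_bad[:2] = 50.0  # gross outliers the analyst flags
        excl = np.zeros(20, bool)
        excl[:2] = True
        m = fit_allometric(zip(d, h, w_bad), ModelForm.POWER_DH, exclude=excl)
        np.testing.assert_allclose(m.coef_, ABOVE_TRUTH, rtol=1e-4)


class TestPredictBiomass:
    above = AllometricModel.from_coefficients(ModelForm.POWER_DH, ABOVE_TRUTH)
    below = AllometricModel.from_coefficients(ModelForm.POWER_DH, BELOW_TRUTH,
                                              Component.BELOW)

    def test_unit_plant_above(self):
        assert self.above.predict(1.0, 1.0) == pytest.approx(0.234, rel=1e-9)

    def test_unit_plant_below(self):
        assert self.below.predict(1.0, 1.0) == pytest.approx(0.091, rel=1e-9)

    def test_quadrat_density(self):
        dens = predict_biomass(self.above, [(1.0, 1.0)] * 10, 25.0)
        assert dens == pytest.approx(10 * 0.234 / 25.0, rel=1e-12)

    def test_empty_quadrat(self):
        assert predict_biomass(self.above, [], 25.0) == 0.0

    def test_negative_prediction_clipped_with_warning(self):
        m = AllometricModel.from_coefficients(ModelForm.CUBIC_H,
                                              (-1.0, 0.0, 0.0, 0.0))
        with pytest.warns(RuntimeWarning, match="clipped"):
            dens = predict_biomass(m, [(1.0, 1.0)], 25.0)
        assert dens == 0.0


class TestHerbLitterCarbon:
    def test_herb_example(self):
        # 1 kg fresh, dry ratio 0.5, 1 m^2, herb fraction 0.40 -> 200 gC/m2
        assert herb_litter_carbon(1.0, 100.0, 50.0, 1.0, 0.40) == \
            pytest.approx(200.0)

    def test_zero_fresh(self):
        assert herb_litter_carbon(0.0, 100.0, 50.0, 1.0, 0.40) == 0.0

    def test_fully_dry_litter(self):
        assert herb_litter_carbon(1.0, 100.0, 100.0, 1.0, 0.37) == \
            pytest.approx(370.0)

    def test_dry_exceeding_fresh_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            herb_litter_carbon(1.0, 100.0, 120.0, 1.0, 0.40)


class TestSoilCarbon:
    def test_surveyed_layer_example(self):
        # 10-year 0-10 cm means: SOC 6.2 g/kg, BD 1.25 g/cm3, 10 cm
        total, per_layer = soil_carbon_density([("0-10", 1.25, 6.2)])
        assert per_layer["0-10"] == pytest.approx(775.0)
        assert total == pytest.approx(775.0)

    def test_zero_soc(self):
        total, _ = soil_carbon_density([("0-10", 1.2, 0.0)])
        assert total == 0.0

    def test_linearity_in_soc(self):
        layers = [("0-10", 1.2, 3.0), ("10-20", 1.3, 2.0), ("20-50", 1.25, 2.5)]
        doubled = [(l, bd, 2 * soc) for l, bd, soc in layers]
        assert soil_carbon_density(doubled)[0] == \
            pytest.approx(2 * soil_carbon_density(layers)[0], rel=1e-12)

    def test_duplicate_layer_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            soil_carbon_density([("0-10", 1.2, 3.0), ("0-10", 1.3, 2.0)])

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError, match="unknown soil layer"):
            soil_carbon_density([("50-80", 1.2, 3.0)])


class TestLedger:
    def test_hand_built_single_plant_plot(self):
        """Single plant, single subplot pair, single soil point: hand arithmetic."""
        above = AllometricModel.from_coefficients(ModelForm.POWER_DH,
                                                  ABOVE_TRUTH)
        below = AllometricModel.from_coefficients(ModelForm.POWER_DH,
                                                  BELOW_TRUTH, Component.BELOW)
        plants = pd.DataFrame([{"plot": "p1", "quadrat": 1,
                                "D_cm": 1.0, "H_m": 1.0}])
        hl = pd.DataFrame([
            {"plot": "p1", "subplot": 1, "compartment": "herb",
             "fresh_kg": 1.0, "sub_fresh_g": 100.0, "sub_dry_g": 50.0,
             "area_m2": 1.0},
            {"plot": "p1", "subplot": 1, "compartment": "litter",
             "fresh_kg": 1.0, "sub_fresh_g": 100.0, "sub_dry_g": 100.0,
             "area_m2": 1.0},
        ])
        soil = pd.DataFrame([{"plot": "p1", "point": 1, "layer": "0-10",
                              "bd_g_cm3": 1.25, "soc_g_kg": 6.2}])
        led = build_ledger({"plot": "p1", "age_yr": 8, "site_type": "X",
                            "quadrat_area_m2": 25.0},
                           plants, hl, soil, above, below)
        assert led.above == pytest.approx(0.234 / 25.0 * 0.5465 * 1000)
        assert led.below == pytest.approx(0.091 / 25.0 * 0.4526 * 1000)
        assert led.herb == pytest.approx(200.0)
        assert led.litter == pytest.approx(370.0)
        assert led.soil == pytest.approx(775.0)
        assert led.total == led.above + led.below + led.herb + led.litter + led.soil

    def test_missing_compartment_named(self):
        above = AllometricModel.from_coefficients(ModelForm.POWER_DH,
                                                  ABOVE_TRUTH)
        with pytest.raises(ValueError, match="soil"):
            build_ledger({"plot": "p1"},
                         pd.DataFrame([{"plot": "p1", "quadrat": 1,
                                        "D_cm": 1.0, "H_m": 1.0}]),
                         pd.DataFrame([
                             {"plot": "p1", "subplot": 1,
                              "compartment": "herb", "fresh_kg": 1.0,
                              "sub_fresh_g": 100.0, "sub_dry_g": 50.0,
                              "area_m2": 1.0},
                             {"plot": "p1", "subplot": 1,
                              "compartment": "litter", "fresh_kg": 1.0,
                              "sub_fresh_g": 100.0, "sub_dry_g": 50.0,
                              "area_m2": 1.0}]),
                         pd.DataFrame(columns=["plot", "point", "layer",
                                               "bd_g_cm3", "soc_g_kg"]),
                         above, above)


class TestNetSequestration:
    project = CarbonPoolLedger("p", 8, "GULLY_BOTTOM", 500, 200, 30, 15, 1500)

    def test_simple_arithmetic(self):
        ctl = CarbonPoolLedger("c", np.nan, "GRASSLAND", 0, 0, 30, 10, 500)
        ns = net_sequestration(self.project, ctl, leakage=1.0)
        assert ns.net == pytest.approx(ns.gross - ns.baseline - 1.0)

    def test_equal_ledgers_and_no_leakage(self):
        ns = net_sequestration(self.project, self.project, leakage=0.0)
        assert ns.net == pytest.approx(0.0, abs=1e-12)

    def test_default_leakage_applied(self):
        ctl = CarbonPoolLedger("c", np.nan, "GRASSLAND", 0, 0, 0, 0, 0)
        ns = net_sequestration(self.project, ctl)
        assert ns.leakage == 3.31

    def test_poolwise_equals_totalwise(self):
        ctl = CarbonPoolLedger("c", np.nan, "GRASSLAND", 0, 0, 25, 8, 900)
        a = net_sequestration(self.project, ctl, leakage=2.0, poolwise=True)
        b = net_sequestration(self.project, ctl, leakage=2.0, poolwise=False)
        assert a.net == pytest.approx(b.net, rel=1e-12)


def test_carbon_fraction_validation():
    with pytest.raises(ValueError):
        CarbonFractions(above=1.2)
    f = CarbonFractions()
    assert (f.above, f.below, f.herb, f.litter) == (0.5465, 0.4526, 0.40, 0.37)
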