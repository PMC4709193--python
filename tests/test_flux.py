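"""Flux engine: decay model, loss factor, emission and sequestration terms."""

import numpy as np
import pytest

from juriflux.flux import (CO2_PER_C, LoggingFactors, LossFactorInputs,
                           SequestrationRates, SoilParams,
                           decay_fraction_in_window, forest_loss_emissions,
                           logging_emissions, loss_factor, mean_decay_fraction,
                           net_flux, sequestration, wetland_soil_emissions)


class TestDecay:
    def test_first_year_cohort_fully_decays(self):
        # 9 years of decay at 0.24/yr exceed 1: fully emitted
        assert decay_fraction_in_window(1, 0.24, 10) == pytest.approx(1.0)

    def test_last_year_cohort_has_no_decay_time(self):
        assert decay_fraction_in_window(10, 0.24, 10) == 0.0

    def test_cohort_mean_at_reference_rate(self):
        # (5*1 + 0.96 + 0.72 + 0.48 + 0.24 + 0) / 10
        assert mean_decay_fraction(0.24, 10) == pytest.approx(0.74, abs=1e-12)

    def test_cohort_year_outside_period_rejected(self):
        with pytest.raises(ValueError):
            decay_fraction_in_window(0, 0.24, 10)
        with pytest.raises(ValueError):
            decay_fraction_in_window(11, 0.24, 10)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            decay_fraction_in_window(1, 0.0, 10)

    def test_vectorized_over_rate_draws(self):
        rates = np.array([0.1, 0.24, 1.0])
        out = mean_decay_fraction(rates, 10)
        assert out.shape == (3,)
        assert np.all(np.diff(out) > 0)  # monotone in the rate


class TestLossFactor:
    def test_full_combustion_emits_everything(self):
        inp = LossFactorInputs(burned_frac=1.0, combustion_completeness=1.0,
                               charcoal_frac=0.0, extraction_frac=0.0,
                               necromass_frac=0.0, root_shoot=0.0)
        assert loss_factor(inp, 10) == pytest.approx(1.0)

    def test_pure_decay_equals_cohort_mean(self):
        inp = LossFactorInputs(burned_frac=0.0, decay_rate=0.24,
                               extraction_frac=0.0, necromass_frac=0.0,
                               root_shoot=0.0)
        assert loss_factor(inp, 10) == pytest.approx(0.74, abs=1e-12)

    def test_roots_add_proportionally_under_full_emission(self):
        r = 0.37
        inp = LossFactorInputs(burned_frac=1.0, combustion_completeness=1.0,
                               charcoal_frac=0.0, extraction_frac=0.0,
                               necromass_frac=0.0, root_shoot=r)
        assert loss_factor(inp, 10) == pytest.approx(1.0 + r)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            loss_factor(LossFactorInputs(burned_frac=1.2), 10)


class TestForestLossEmissions:
    def test_single_stratum_arithmetic(self):
        total = forest_loss_emissions({"h1": 90.0}, {"h1": 150.0}, 0.74)
        assert total == pytest.approx(9990.0)

    def test_zero_loss_factor_gives_zero(self):
        assert forest_loss_emissions({"h1": 90.0}, {"h1": 150.0}, 0.0) == 0.0

    def test_linear_in_area(self):
        afd = {"a": 10.0, "b": 20.0}
        cd = {"a": 100.0, "b": 200.0}
        one = forest_loss_emissions(afd, cd, 0.74)
        two = forest_loss_emissions({k: 2 * v for k, v in afd.items()}, cd, 0.74)
        assert two == pytest.approx(2 * one)

    def test_stratum_mismatch_rejected(self):
        with pytest.raises(KeyError):
            forest_loss_emissions({"a": 1.0}, {"b": 100.0}, 0.74)


class TestWetlandSoil:
    def test_mangrove_layer_fractions(self):
        soil = SoilParams(mangrove_top_stock=100.0, mangrove_deep_stock=200.0)
        # 10 ha * (0.75*100 + 0.35*200) = 1450 MgC
        out = wetland_soil_emissions({"mangrove": 10.0}, soil)
        assert out == pytest.approx(1450.0)

    def test_shallow_peat_limits_drained_layer(self):
        deep = SoilParams(peat_depth=200.0, drainage_depth=60.0,
                          peat_c_density=0.5)
        shallow = SoilParams(peat_depth=40.0, drainage_depth=60.0,
                             peat_c_density=0.5)
        assert wetland_soil_emissions({"peat": 1.0}, deep) == pytest.approx(30.0)
        assert wetland_soil_emissions({"peat": 1.0}, shallow) == pytest.approx(20.0)

    def test_zero_area_gives_zero(self):
        assert wetland_soil_emissions({"peat": 0.0, "mangrove": 0.0},
                                      SoilParams()) == 0.0

    def test_unknown_wetland_type_rejected(self):
        with pytest.raises(KeyError):
            wetland_soil_emissions({"bog": 1.0}, SoilParams())


class TestLogging:
    def test_no_activity_no_emissions(self):
        parts = logging_emissions(0.0, LoggingFactors())
        assert all(v == 0.0 for v in parts.values())

    def test_components_sum_to_total(self):
        parts = logging_emissions(
            100.0, LoggingFactors(),
            road_afd={"h": 5.0}, road_cd={"h": 150.0}, road_lfd=0.74)
        assert parts["total"] == pytest.approx(
            parts["felling"] + parts["skidding"] + parts["haul_roads"]
            + parts["wood_products"])
        assert parts["haul_roads"] == pytest.approx(5 * 150 * 0.74)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            logging_emissions(-1.0, LoggingFactors())


class TestSequestration:
    def test_fiber_for_one_year(self):
        out = sequestration({"fiber": 100.0}, SequestrationRates(),
                            accrual_years=1.0)
        assert out == pytest.approx(980.0)

    def test_no_regrowth_no_logging_is_zero(self):
        assert sequestration({}, SequestrationRates()) == 0.0

    def test_native_vs_oil_palm_rate_ratio(self):
        rates = SequestrationRates()
        native = sequestration({"native": 50.0}, rates, accrual_years=1.0)
        palm = sequestration({"oil_palm": 50.0}, rates, accrual_years=1.0)
        assert native / palm == pytest.approx(3.85 / 2.97)

    def test_unknown_regrowth_type_rejected(self):
        with pytest.raises(KeyError):
            sequestration({"bamboo": 1.0}, SequestrationRates())


class TestNetFlux:
    def test_net_is_loss_minus_gain(self):
        res = net_flux(10.0, 3.0)
        assert res.net == 7.0

    def test_zero_gain_passthrough(self):
        res = net_flux(5.0, 0.0)
        assert res.net == res.gross_loss

    def test_co2_conversion(self):
        assert net_flux(3.0, 0.0).net_co2 == pytest.approx(11.0)

    def test_co2_round_trips(self):
        x = 123.456
        assert (x * CO2_PER_C) / CO2_PER_C == pytest.approx(x, rel=1e-15)
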