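"""Activity data: loss extraction, gain, roads, records, trend test."""

import numpy as np
import pandas as pd
import pytest

from juriflux.activity import (annualize_gain, classify_logging_roads,
                               extract_loss, summarize_logging_records,
                               trend_test)
from juriflux.rasters import RasterBundle


def _bundle(loss, stratum=None, disturbance=None, pixel=30.0):
    loss = np.asarray(loss, dtype=np.int16)
    stratum = (np.ones_like(loss) if stratum is None
               else np.asarray(stratum, dtype=np.int16))
    disturbance = (np.where(loss > 0, 2, 0).astype(np.int16)
                   if disturbance is None
                   else np.asarray(disturbance, dtype=np.int16))
    return RasterBundle(
        pixel_size_m=pixel,
        layers={"loss_year": loss, "stratum": stratum,
                "disturbance": disturbance},
        codes={"disturbance": {"none": 0, "oil_palm": 1, "agriculture": 2}},
    )


class TestExtractLoss:
    def test_empty_loss_raster(self):
        afd, annual = extract_loss(_bundle(np.zeros((10, 10))), period=(1, 10))
        assert afd == {}
        assert annual.sum() == 0.0

    def test_count_times_pixel_area(self):
        loss = np.zeros((40, 40), dtype=int)
        loss.ravel()[:1000] = 1
        afd, annual = extract_loss(_bundle(loss), period=(1, 10))
        assert afd[(1, "agriculture")] == pytest.approx(90.0)  # 1000 x 0.09 ha
        assert annual[0] == pytest.approx(90.0)

    def test_loss_outside_period_excluded(self):
        loss = np.array([[3, 12], [0, 0]])
        afd, _ = extract_loss(_bundle(loss), period=(1, 10))
        assert sum(afd.values()) == pytest.approx(0.09)

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError):
            RasterBundle(pixel_size_m=30.0,
                         layers={"a": np.zeros((3, 3)), "b": np.zeros((4, 4))})

    def test_unknown_attribution_code_listed(self):
        loss = np.ones((2, 2), dtype=int)
        dist = np.full((2, 2), 9, dtype=int)
        with pytest.raises(KeyError, match="9"):
            extract_loss(_bundle(loss, disturbance=dist), period=(1, 10))


class TestAnnualizeGain:
    def test_source_to_reference_scaling(self):
        assert annualize_gain(1200.0, 12.0, 10.0) == pytest.approx(1000.0)

    def test_zero_gain(self):
        assert annualize_gain(0.0, 12.0, 10.0) == 0.0

    def test_linear_in_area(self):
        a = annualize_gain(500.0, 12.0, 10.0)
        b = annualize_gain(1000.0, 12.0, 10.0)
        assert b == pytest.approx(2 * a)

    def test_mapping_scaled_per_type(self):
        out = annualize_gain({"fiber": 120.0, "native": 60.0}, 12.0, 10.0)
        assert out == {"fiber": pytest.approx(100.0),
                       "native": pytest.approx(50.0)}

    def test_zero_source_period_rejected(self):
        with pytest.raises(ValueError):
            annualize_gain(10.0, 0.0, 10.0)


class TestLoggingRoads:
    def test_narrow_corridor_inside_concession_is_road(self):
        loss = np.zeros((20, 60), dtype=bool)
        loss[5:7, 5:55] = True          # 2 px wide, 50 long
        conc = np.ones_like(loss)
        labels = classify_logging_roads(loss, conc)
        assert np.all(labels[loss] == 1)

    def test_wide_block_is_conversion(self):
        loss = np.zeros((20, 20), dtype=bool)
        loss[4:14, 4:14] = True         # 10 x 10 block
        conc = np.ones_like(loss)
        labels = classify_logging_roads(loss, conc)
        assert np.all(labels[loss] == 2)

    def test_corridor_outside_concession_not_road(self):
        loss = np.zeros((20, 60), dtype=bool)
        loss[5:7, 5:55] = True
        conc = np.zeros_like(loss)
        labels = classify_logging_roads(loss, conc)
        assert np.all(labels == 0)

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(0)
        loss = rng.random((50, 50)) < 0.2
        conc = np.zeros((50, 50), dtype=bool)
        conc[:, 10:40] = True
        labels = classify_logging_roads(loss, conc)
        inside = loss & conc
        assert np.all((labels > 0) == inside)
        assert np.all(np.isin(labels[inside], [1, 2]))

    def test_misaligned_masks_rejected(self):
        with pytest.raises(ValueError):
            classify_logging_roads(np.zeros((3, 3), bool),
                                   np.zeros((4, 4), bool))


class TestLoggingRecords:
    def _records(self, n_years=10, area=100.0, volume=3000.0):
        return pd.DataFrame({
            "permit": ["P1"] * n_years,
            "year": list(range(1, n_years + 1)),
            "area_ha": [area] * n_years,
            "volume_m3": [volume] * n_years,
        })

    def test_complete_records(self):
        out = summarize_logging_records(self._records(), 10, completeness=1.0)
        assert out["asl_ha_yr"] == pytest.approx(100.0)
        assert out["volume_m3_yr"] == pytest.approx(3000.0)
        assert out["asl_ha_period"] == pytest.approx(1000.0)

    def test_proportional_scale_up(self):
        out = summarize_logging_records(self._records(), 10, completeness=0.5,
                                        scale_mode="proportional")
        assert out["asl_ha_yr"] == pytest.approx(200.0)

    def test_observed_mean_mode_does_not_scale(self):
        out = summarize_logging_records(self._records(), 10, completeness=0.5,
                                        scale_mode="observed_mean")
        assert out["asl_ha_yr"] == pytest.approx(100.0)

    def test_missing_volume_keeps_area(self):
        recs = self._records()
        recs.loc[0, "volume_m3"] = np.nan
        with pytest.warns(UserWarning, match="volume"):
            out = summarize_logging_records(recs, 10)
        assert out["asl_ha_yr"] == pytest.approx(100.0)

    def test_empty_table_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = summarize_logging_records(pd.DataFrame(columns=[
                "permit", "year", "area_ha"]), 10)
        assert out["asl_ha_yr"] == 0.0


class TestTrendTest:
    def test_perfectly_linear_series(self):
        out = trend_test([10, 20, 30, 40, 50])
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(10.0)

    def test_constant_series(self):
        out = trend_test([7, 7, 7, 7, 7, 7])
        assert out["slope"] == 0.0
        assert out["r_squared"] == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(100, 1000, 10)
        x = np.arange(1, 11, dtype=float)
        # brute-force OLS via normal equations
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot
        f = (ss_tot - ss_res) / (ss_res / (len(y) - 2))
        out = trend_test(y)
        assert out["slope"] == pytest.approx(beta[1], abs=1e-9)
        assert out["intercept"] == pytest.approx(beta[0], abs=1e-9)
        assert out["r_squared"] == pytest.approx(r2, abs=1e-9)
        assert out["F"] == pytest.approx(f, rel=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            trend_test([1, 2])
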