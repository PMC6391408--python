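"""Tests of the NANI budget sub-procedures: sums, scalings, interpolation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnflux.errors import DegenerateDesignError, InvalidInputError, UnscalableRegionError
from tnflux.nani import (
    CropState,
    NANIComponents,
    assemble_nani,
    calibrate_fixation_rate,
    fertilizer_usage,
    fit_import_regression,
    fixation_from_area,
    hold_constant_after,
    hold_constant_before,
    interpolate_census,
    scale_deposition,
    scale_fertilizer_to_reference,
)

nonneg = st.floats(0, 1e6, allow_nan=False)
signed = st.floats(-1e6, 1e6, allow_nan=False)


class TestAssemble:
    def test_signed_sum(self):
        c = NANIComponents(7200, 4500, 1400, -3000, 78)
        assert assemble_nani(c) == pytest.approx(10022.0)

    def test_all_zero(self):
        assert assemble_nani(NANIComponents(0, 0, 0, 0, 0)) == 0.0

    def test_net_export_watershed_gives_negative_nani(self):
        assert assemble_nani(NANIComponents(0, 0, 0, -100, 0)) == -100.0

    def test_negative_additive_component_rejected(self):
        with pytest.raises(InvalidInputError):
            NANIComponents(-1, 0, 0, 0, 0)

    @settings(derandomize=True, max_examples=50)
    @given(nonneg, nonneg, nonneg, signed, nonneg)
    def test_linearity_in_components(self, f, x, d, i, e):
        c = NANIComponents(f, x, d, i, e)
        doubled = NANIComponents(2 * f, 2 * x, 2 * d, 2 * i, 2 * e)
        assert assemble_nani(doubled) == pytest.approx(2 * assemble_nani(c), rel=1e-12, abs=1e-9)
        # permuting the three unsigned additive components leaves NANI unchanged
        assert assemble_nani(NANIComponents(x, d, f, i, e)) == pytest.approx(
            assemble_nani(c), rel=1e-12, abs=1e-9
        )


class TestFertilizerUsage:
    def test_single_crop(self):
        crops = CropState(areas={"c3_annual": 0.5}, rates={"c3_annual": 10000.0})
        assert fertilizer_usage(crops) == pytest.approx(5000.0)

    def test_two_crops(self):
        crops = CropState(
            areas={"c3_annual": 0.2, "c4_annual": 0.3},
            rates={"c3_annual": 5000.0, "c4_annual": 10000.0},
        )
        assert fertilizer_usage(crops) == pytest.approx(4000.0)

    def test_zero_area(self):
        assert fertilizer_usage(CropState(areas={}, rates={"c3_nfix": 500.0})) == 0.0

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(InvalidInputError):
            CropState(areas={"c3_annual": 0.7, "c4_annual": 0.6}, rates={})


class TestScaleFertilizer:
    def _series(self):
        return pd.DataFrame(
            {
                "watershed_id": ["W1"] * 3,
                "year": [1990, 2000, 2050],
                "value": [45.0, 45.0, 18.0],
            }
        )

    def test_ratio_applied_to_all_years(self):
        huc2 = pd.Series({"W1": "H1"})
        ref = pd.Series({"H1": 100.0})  # input 1987-2012 total is 90
        out = scale_fertilizer_to_reference(self._series(), huc2, ref)
        assert out.loc[out.year == 2050, "value"].iloc[0] == pytest.approx(20.0)
        window = out[out.year.between(1987, 2012)]["value"].sum()
        assert window == pytest.approx(100.0, rel=1e-12)

    def test_identity_when_totals_match(self):
        huc2 = pd.Series({"W1": "H1"})
        out = scale_fertilizer_to_reference(self._series(), huc2, pd.Series({"H1": 90.0}))
        assert np.allclose(out["value"], self._series()["value"])

    def test_zero_zero_region_passes_through(self):
        df = pd.DataFrame({"watershed_id": ["W1"], "year": [2000], "value": [0.0]})
        out = scale_fertilizer_to_reference(df, pd.Series({"W1": "H1"}), pd.Series({"H1": 0.0}))
        assert out["value"].iloc[0] == 0.0

    def test_zero_input_nonzero_reference_unscalable(self):
        df = pd.DataFrame({"watershed_id": ["W1"], "year": [2000], "value": [0.0]})
        with pytest.raises(UnscalableRegionError):
            scale_fertilizer_to_reference(df, pd.Series({"W1": "H1"}), pd.Series({"H1": 5.0}))


class TestFixation:
    def test_published_rate_per_km2(self):
        assert fixation_from_area(1.0, 14300.0) == pytest.approx(14300.0)

    def test_zero_area(self):
        assert fixation_from_area(0.0, 14300.0) == 0.0

    def test_published_constants_are_mutually_consistent(self):
        # 6.9 Tg N at 14,300 kg N km^-2 y^-1 implies ~482,517.5 km^2
        implied_area = 6.9e9 / 14300.0
        assert implied_area == pytest.approx(482517.5, rel=1e-4)
        assert fixation_from_area(implied_area, 14300.0) == pytest.approx(6.9e9, rel=1e-12)

    def test_calibration_reproduces_target_exactly(self):
        areas = np.array([100.0, 250.5, 1000.0])
        rate = calibrate_fixation_rate(areas, 5.0e6)
        assert sum(fixation_from_area(a, rate) for a in areas) == pytest.approx(5.0e6, rel=1e-12)

    def test_calibration_simple_division(self):
        assert calibrate_fixation_rate([1.0], 5.0) == pytest.approx(5.0)

    def test_doubling_areas_halves_rate(self):
        areas = np.array([10.0, 20.0])
        assert calibrate_fixation_rate(2 * areas, 7.0) == pytest.approx(
            calibrate_fixation_rate(areas, 7.0) / 2
        )

    def test_zero_area_impossible(self):
        with pytest.raises(InvalidInputError):
            calibrate_fixation_rate([0.0], 5.0)


class TestImportRegression:
    def _history(self, a=500.0, bf=-0.3, bx=-0.1):
        years = [1987, 1992, 1997, 2002, 2007, 2012]
        f = np.array([800, 900, 1000, 1100, 1200, 1300], float)
        x = np.array([400, 450, 480, 520, 560, 600], float)
        return pd.DataFrame(
            {
                "huc2": "H1",
                "year": years,
                "fertilizer_kg_km2_yr": f,
                "fixation_kg_km2_yr": x,
                "import_kg_km2_yr": a + bf * f + bx * x,
            }
        )

    def test_noiseless_recovery_and_prediction(self):
        reg = fit_import_regression(self._history())
        a, bf, bx = reg.params["H1"]
        assert (a, bf, bx) == pytest.approx((500.0, -0.3, -0.1), abs=1e-8)
        assert reg.predict("H1", 1000.0, 500.0) == pytest.approx(150.0, abs=1e-6)

    def test_constant_fertilizer_degenerate(self):
        hist = self._history()
        hist["fertilizer_kg_km2_yr"] = 1000.0
        with pytest.raises(DegenerateDesignError):
            fit_import_regression(hist)

    def test_too_few_census_years_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_import_regression(self._history().iloc[:3])


class TestScaleDeposition:
    def _frames(self, model_level=8.0, ref_level=10.0):
        years = [2002, 2003, 2004, 2005, 2006, 2050]
        model = pd.DataFrame(
            {"watershed_id": "W1", "year": years, "value": [model_level] * 5 + [6.0]}
        )
        ref = pd.DataFrame(
            {"watershed_id": "W1", "year": years[:5], "value": [ref_level] * 5}
        )
        return model, ref

    def test_overlap_ratio_scales_future(self):
        model, ref = self._frames()
        out = scale_deposition(model, ref)
        assert out.loc[out.year == 2050, "value"].iloc[0] == pytest.approx(7.5)

    def test_identical_series_unchanged(self):
        model, _ = self._frames()
        out = scale_deposition(model, model)
        assert np.allclose(out["value"], model["value"])

    def test_zero_zero_convention(self):
        model, ref = self._frames(model_level=0.0, ref_level=0.0)
        model.loc[model.year == 2050, "value"] = 6.0
        out = scale_deposition(model, ref)
        assert out.loc[out.year == 2050, "value"].iloc[0] == pytest.approx(6.0)

    def test_unscalable(self):
        model, ref = self._frames(model_level=0.0, ref_level=10.0)
        with pytest.raises(UnscalableRegionError):
            scale_deposition(model, ref)


class TestCensusInterpolation:
    def test_linear_between_census_years(self):
        census = pd.Series({1987: 100.0, 1992: 110.0})
        out = interpolate_census(census, [1989])
        assert out.loc[1989] == pytest.approx(104.0)

    def test_constant_census_gives_constant_series(self):
        census = pd.Series({1987: 7.0, 1992: 7.0, 1997: 7.0})
        out = interpolate_census(census, range(1987, 1998))
        assert np.allclose(out, 7.0)

    def test_pre_census_trend_extrapolation(self):
        years = [1987, 1992, 1997, 2002, 2007, 2012]
        census = pd.Series({y: 2.0 * (y - 1987) + 100.0 for y in years})
        out = interpolate_census(census, [1980])
        assert out.loc[1980] == pytest.approx(86.0)

    def test_floor_zero_clamps_extrapolation(self):
        census = pd.Series({1987: 10.0, 1992: 60.0, 1997: 110.0, 2002: 160.0})
        out = interpolate_census(census, [1976], floor_zero=True)
        assert out.loc[1976] == 0.0

    def test_years_after_span_rejected(self):
        census = pd.Series({1987: 1.0, 1992: 2.0})
        with pytest.raises(InvalidInputError):
            interpolate_census(census, [1995])


class TestHoldConstant:
    def test_after_anchor(self):
        s = pd.Series({2005: 70.0, 2006: 74.0, 2007: 78.0})
        out = hold_constant_after(s, 2007, through_year=2095)
        assert out.loc[2095] == 78.0

    def test_missing_anchor_rejected(self):
        with pytest.raises(InvalidInputError):
            hold_constant_after(pd.Series({2005: 1.0}), 2007)

    def test_before_anchor(self):
        s = pd.Series({1979: 10.0, 1980: 12.0})
        out = hold_constant_before(s, 1979, back_to_year=1976)
        assert out.loc[1976] == 10.0
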