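"""Tests of the scenario engine: pairing, projection, decomposition, periods."""

import numpy as np
import pandas as pd
import pytest

from tnflux.errors import ConfigurationError, InvalidInputError, MissingInputError
from tnflux.model import LU_CATEGORIES, ModelCoefficients
from tnflux.nani import CROP_TYPES, ImportRegression
from tnflux.scenarios import (
    END_CENTURY,
    HISTORICAL,
    Period,
    ScenarioSpec,
    World,
    decomposition_runs,
    pair_rcp,
    period_mean,
    run_projection,
)


class TestPairing:
    @pytest.mark.parametrize(
        "ssp,rcp",
        [
            ("SSP1-2.6", "RCP2.6"),
            ("SSP2-4.5", "RCP4.5"),
            ("SSP3-7.0", "RCP8.5"),
            ("SSP4-3.4", "RCP2.6"),
            ("SSP4-6.0", "RCP6.0"),
            ("SSP5-8.5", "RCP8.5"),
        ],
    )
    def test_fixed_pairing_table(self, ssp, rcp):
        assert pair_rcp(ssp) == rcp

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            pair_rcp("SSP9-1.9")

    def test_bad_flags_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec(ssp="SSP1-2.6", precip_mode="rcp")
        with pytest.raises(ConfigurationError):
            ScenarioSpec(ssp="SSP1-2.6", cropland="both")


class TestPeriod:
    def test_canonical_periods_are_30_years(self):
        assert len(HISTORICAL) == len(END_CENTURY) == 30

    def test_inverted_period_rejected(self):
        with pytest.raises(InvalidInputError):
            Period("bad", 2000, 1999)


def toy_world(
    hist_lu=(0.20, 0.05),
    fut_lu=(0.30, 0.10),
    hist_rate=8000.0,
    fut_rate=10000.0,
    n_models=2,
):
    """A minimal hand-built world: one watershed, constant drivers.

    Crop area fraction equals the cropland land-use fraction (a single
    c3_annual crop plus a c3_nfix sliver at 10% of cropland); deposition and
    nonfood export are constants; the import rule is a fixed linear map.
    """
    ws = pd.DataFrame(
        {"watershed_id": ["W1"], "huc2": ["H1"], "area_km2": [1000.0], "in_marb": [True], "in_northeast": [False]}
    )
    hist_years = np.arange(HISTORICAL.start, 2016)
    fut_years = np.arange(2015, 2101)

    def lu_frame(years, crop, dev):
        df = pd.DataFrame({"watershed_id": "W1", "year": years})
        df["frac_cropland"] = crop
        df["frac_developed"] = dev
        rest = (1.0 - crop - dev) / 4
        for c in LU_CATEGORIES:
            if c not in ("cropland", "developed"):
                df[f"frac_{c}"] = rest
        return df

    def crops_frame(years, crop, rate):
        rows = []
        for t in CROP_TYPES:
            area = crop * (0.9 if t == "c3_annual" else (0.1 if t == "c3_nfix" else 0.0))
            r = rate if t == "c3_annual" else (0.0 if t != "c3_nfix" else 0.0)
            rows.append(pd.DataFrame({"watershed_id": "W1", "year": years, "crop_type": t, "area_fraction": area, "rate_kg_km2_yr": r}))
        return pd.concat(rows, ignore_index=True)

    def dep_frame(years, level):
        return pd.DataFrame({"watershed_id": "W1", "year": years, "value": level})

    def feat_frame(years, models, p_ann, p_ext):
        rows = []
        for m in models:
            rows.append(pd.DataFrame({"watershed_id": "W1", "model_id": m, "year": years, "p_annual_mm": p_ann, "p_mam_ext_mm": p_ext}))
        return pd.concat(rows, ignore_index=True)

    models = [f"M{i+1}" for i in range(n_models)]
    return World(
        watersheds=ws,
        landuse={"historical": lu_frame(hist_years, *hist_lu), "SSP4-3.4": lu_frame(fut_years, *fut_lu)},
        crops={"historical": crops_frame(hist_years, hist_lu[0], hist_rate), "SSP4-3.4": crops_frame(fut_years, fut_lu[0], fut_rate)},
        deposition={"historical": dep_frame(hist_years, 1000.0), "RCP2.6": dep_frame(fut_years, 800.0)},
        nonfood=pd.Series({"W1": 20.0}),
        import_reg=ImportRegression({"H1": (-500.0, -0.25, -0.15)}),
        fixation_rate=14300.0,
        features={
            "historical": feat_frame(np.arange(HISTORICAL.start, HISTORICAL.end + 1), models, 900.0, 80.0),
            "RCP2.6": feat_frame(np.arange(END_CENTURY.start, END_CENTURY.end + 1), models, 950.0, 95.0),
        },
        coefficients=ModelCoefficients(),
    )


def expected_flux(crop, dev, rate, dep, p_ann, p_ext, fixation_rate=14300.0, nonfood=20.0):
    """Independent arithmetic oracle for the toy world's flux."""
    fert = crop * 0.9 * rate
    fix = crop * 0.1 * fixation_rate
    imp = -500.0 - 0.25 * fert - 0.15 * fix
    nani = fert + fix + dep + imp - nonfood
    lu_dc = 100.0 * (crop + dev)
    ln = 0.538 + 0.438 * np.arcsinh(nani / 2) + 0.0012 * p_ann + 0.0033 * p_ext + 0.0213 * lu_dc
    return float(np.exp(ln))


class TestRunProjection:
    def test_all_historical_future_run_equals_baseline_values(self, tiny_world):
        world, _ = tiny_world
        spec = ScenarioSpec.all_historical("SSP4-3.4")
        hist = run_projection(world, spec, HISTORICAL)
        fut = run_projection(world, spec, END_CENTURY)
        assert np.array_equal(
            hist.frame["flux_kg_km2_yr"].to_numpy(), fut.frame["flux_kg_km2_yr"].to_numpy()
        )

    def test_matches_hand_computed_flux(self):
        world = toy_world()
        spec = ScenarioSpec(ssp="SSP4-3.4", precip_mode="paired-rcp")
        fld = run_projection(world, spec, END_CENTURY)
        expected = expected_flux(0.30, 0.10, 10000.0, 800.0, 950.0, 95.0)
        assert np.allclose(fld.frame["flux_kg_km2_yr"], expected, rtol=1e-12)

    def test_doubling_lu_dc_multiplies_flux_by_expected_ratio(self):
        w25 = toy_world(hist_lu=(0.20, 0.05), fut_lu=(0.20, 0.05))
        w50 = toy_world(hist_lu=(0.20, 0.05), fut_lu=(0.40, 0.10))
        # isolate the land-use term: same rates, same crop-linked NANI
        spec = ScenarioSpec(ssp="SSP4-3.4", precip_mode="historical", cropland="historical", fertilizer_rate="historical")
        base = run_projection(w25, spec, END_CENTURY).frame["flux_kg_km2_yr"]
        spec_dev = ScenarioSpec(ssp="SSP4-3.4", precip_mode="historical", cropland="historical", fertilizer_rate="historical", developed="future")
        # developed goes 5% -> 10%: +5 percentage points of LU_DC
        bumped = run_projection(w50, spec_dev, END_CENTURY).frame["flux_kg_km2_yr"]
        assert np.allclose(bumped / base, np.exp(0.0213 * 5.0), rtol=1e-12)

    def test_identical_precipitation_gives_identical_model_fields(self):
        world = toy_world(n_models=2)
        fld = run_projection(world, ScenarioSpec(ssp="SSP4-3.4"), END_CENTURY)
        by_model = fld.frame.pivot_table(index=["watershed_id", "year"], columns="model_id", values="flux_kg_km2_yr", aggfunc="first")
        assert np.allclose(by_model["M1"], by_model["M2"])

    def test_determinism(self, tiny_world):
        world, _ = tiny_world
        spec = ScenarioSpec(ssp="SSP4-3.4", precip_mode="paired-rcp")
        a = run_projection(world, spec, END_CENTURY).frame
        b = run_projection(world, spec, END_CENTURY).frame
        pd.testing.assert_frame_equal(a, b)

    def test_missing_precip_source_raises(self):
        world = toy_world()
        world.features.pop("RCP2.6")
        with pytest.raises(MissingInputError, match="RCP2.6"):
            run_projection(world, ScenarioSpec(ssp="SSP4-3.4", precip_mode="paired-rcp"), END_CENTURY)

    def test_monotone_in_landuse_increase(self):
        # future differs from historical only by a larger developed share:
        # every watershed-year-model flux must increase
        world = toy_world(hist_lu=(0.20, 0.05), fut_lu=(0.20, 0.08))
        spec = ScenarioSpec(ssp="SSP4-3.4", precip_mode="historical", cropland="historical", fertilizer_rate="historical", developed="future")
        base = run_projection(world, ScenarioSpec.all_historical("SSP4-3.4"), END_CENTURY).frame
        fut = run_projection(world, spec, END_CENTURY).frame
        assert (fut["flux_kg_km2_yr"].to_numpy() >= base["flux_kg_km2_yr"].to_numpy()).all()


class TestDecomposition:
    def test_null_world_runs_all_identical(self):
        world = toy_world(hist_lu=(0.20, 0.05), fut_lu=(0.20, 0.05), hist_rate=8000.0, fut_rate=8000.0)
        runs = decomposition_runs(world, ScenarioSpec(ssp="SSP4-3.4"), END_CENTURY)
        ref = runs["all_future"].frame["flux_kg_km2_yr"].to_numpy()
        for fld in runs.values():
            assert np.allclose(fld.frame["flux_kg_km2_yr"].to_numpy(), ref, rtol=1e-12)

    def test_matches_enumerated_brute_force(self):
        world = toy_world()
        runs = decomposition_runs(world, ScenarioSpec(ssp="SSP4-3.4"), END_CENTURY)
        cases = {
            "all_future": (0.30, 0.10, 10000.0),
            "cropland_only": (0.30, 0.05, 8000.0),
            "developed_only": (0.20, 0.10, 8000.0),
            "fertilizer_rate_only": (0.20, 0.05, 10000.0),
        }
        for name, (crop, dev, rate) in cases.items():
            expected = expected_flux(crop, dev, rate, 1000.0, 900.0, 80.0)
            got = runs[name].frame["flux_kg_km2_yr"].to_numpy()
            assert np.allclose(got, expected, rtol=1e-12), name

    def test_finite_interaction_is_nonzero(self):
        world = toy_world()
        runs = decomposition_runs(world, ScenarioSpec(ssp="SSP4-3.4"), END_CENTURY)
        base = expected_flux(0.20, 0.05, 8000.0, 1000.0, 900.0, 80.0)
        deltas = {k: runs[k].frame["flux_kg_km2_yr"].iloc[0] - base for k in runs}
        combined = deltas["all_future"]
        singles = deltas["cropland_only"] + deltas["developed_only"] + deltas["fertilizer_rate_only"]
        assert abs(combined - singles) / abs(combined) > 1e-3

    def test_requires_historical_precip_mode(self):
        world = toy_world()
        with pytest.raises(ConfigurationError):
            decomposition_runs(world, ScenarioSpec(ssp="SSP4-3.4", precip_mode="paired-rcp"), END_CENTURY)


class TestPeriodMean:
    def _field(self, values):
        years = np.arange(END_CENTURY.start, END_CENTURY.start + len(values))
        frame = pd.DataFrame(
            {"watershed_id": "W1", "model_id": "M1", "year": years, "flux_kg_km2_yr": values}
        )
        from tnflux.scenarios import TNFluxField

        return TNFluxField(ScenarioSpec(ssp="SSP4-3.4"), Period("p", int(years[0]), int(years[-1])), frame)

    def test_constant_flux(self):
        fld = self._field([100.0] * 30)
        assert period_mean(fld)["flux_kg_km2_yr"].iloc[0] == pytest.approx(100.0)

    def test_arithmetic_mean(self):
        fld = self._field(list(range(1, 31)))
        assert period_mean(fld)["flux_kg_km2_yr"].iloc[0] == pytest.approx(15.5)

    def test_missing_year_rejected(self):
        fld = self._field([100.0] * 30)
        frame = fld.frame[fld.frame.year != fld.frame.year.iloc[3]]
        from tnflux.scenarios import TNFluxField

        broken = TNFluxField(fld.spec, fld.period, frame)
        with pytest.raises(MissingInputError):
            period_mean(broken)
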