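"""Scenario orchestration: TN-flux fields for historical and future runs.

A scenario couples a societal land-use/land-management pathway (SSP) with a
climate forcing outcome (RCP). The engine builds, per (watershed, year,
climate model), the four predictors of the loading model — NANI (honoring
per-factor historical/future flags), the developed-or-cropland percent
cover, and the two precipitation features — and applies the model.

Factor flags drive the single-factor decomposition: the ``cropland`` flag
moves both the cropland share of land use and the crop areas embedded in
NANI (fertilizer usage, fixation, food/feed import); ``developed`` moves
only the developed share of land use; ``fertilizer_rate`` moves application
rates (and import through the regression) on whichever land the cropland
flag selects. Because the model is log-linear, single-factor changes are not
additive at finite perturbations.

When a driver is held at historical levels while evaluating a future
period, its value for future year t is taken from the historical table at
year hist_start + (t - future_start), preserving the interannual
variability the ensemble statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, MissingInputError
from .model import ModelCoefficients, predict_ln_tn_arrays
from .nani import CROP_TYPES, ImportRegression

#: Fixed SSP -> RCP pairing (scenarios without an exact CMIP5 counterpart
#: are paired with the most similar available pathway).
SSP_RCP_PAIRING: dict[str, str] = {
    "SSP1-2.6": "RCP2.6",
    "SSP2-4.5": "RCP4.5",
    "SSP3-7.0": "RCP8.5",
    "SSP4-3.4": "RCP2.6",
    "SSP4-6.0": "RCP6.0",
    "SSP5-8.5": "RCP8.5",
}

SCENARIOS: tuple[str, ...] = tuple(SSP_RCP_PAIRING)

#: Canonical 30-year analysis periods.
HISTORICAL_PERIOD = ("historical", 1976, 2005)
MID_CENTURY_PERIOD = ("mid-century", 2031, 2060)
END_CENTURY_PERIOD = ("end-century", 2071, 2100)


def pair_rcp(ssp_id: str) -> str:
    """RCP pathway paired with an SSP scenario id."""
    try:
        return SSP_RCP_PAIRING[ssp_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario id {ssp_id!r}; known: {sorted(SSP_RCP_PAIRING)}"
        ) from None


@dataclass(frozen=True)
class Period:
    """A labelled span of calendar years (30 years for the canonical ones)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidInputError(f"period {self.label!r}: end before start")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


HISTORICAL = Period(*HISTORICAL_PERIOD)
MID_CENTURY = Period(*MID_CENTURY_PERIOD)
END_CENTURY = Period(*END_CENTURY_PERIOD)


@dataclass(frozen=True)
class ScenarioSpec:
    """One run configuration.

    ``precip_mode`` is "historical" (land-management-only runs) or
    "paired-rcp" (combined runs). The three factor flags select historical
    or future sources per driver. ``nani_mode`` chooses between the
    census-style observed component tables ("observation", historical
    baseline only) and land-use-derived components ("scenario").
    """

    ssp: str
    precip_mode: str = "historical"
    cropland: str = "future"
    developed: str = "future"
    fertilizer_rate: str = "future"
    nani_mode: str = "scenario"

    def __post_init__(self) -> None:
        pair_rcp(self.ssp)  # validates the id
        if self.precip_mode not in ("historical", "paired-rcp"):
            raise ConfigurationError(f"bad precip_mode {self.precip_mode!r}")
        for flag in ("cropland", "developed", "fertilizer_rate"):
            if getattr(self, flag) not in ("historical", "future"):
                raise ConfigurationError(f"bad {flag} flag {getattr(self, flag)!r}")
        if self.nani_mode not in ("observation", "scenario"):
            raise ConfigurationError(f"bad nani_mode {self.nani_mode!r}")

    @property
    def rcp(self) -> str:
        return pair_rcp(self.ssp)

    @classmethod
    def all_historical(cls, ssp: str = "SSP2-4.5", nani_mode: str = "scenario") -> "ScenarioSpec":
        return cls(
            ssp=ssp,
            precip_mode="historical",
            cropland="historical",
            developed="historical",
            fertilizer_rate="historical",
            nani_mode=nani_mode,
        )


@dataclass(frozen=True)
class TNFluxField:
    """Predicted flux per (watershed, year, model) for one configuration."""

    spec: ScenarioSpec
    period: Period
    frame: pd.DataFrame  # watershed_id, model_id, year, flux_kg_km2_yr

    def __post_init__(self) -> None:
        if (self.frame["flux_kg_km2_yr"] <= 0).any():
            raise InvalidInputError("TN flux must be strictly positive")


@dataclass
class World:
    """All driver tables a projection needs, keyed by scenario source.

    Dictionary keys are "historical" plus SSP ids (land use, crops) or RCP
    ids (deposition, precipitation features).
    """

    watersheds: pd.DataFrame  # watershed_id, huc2, area_km2 (+ region flags)
    landuse: dict  # key -> frame: watershed_id, year, frac_<category>...
    crops: dict  # key -> frame: watershed_id, year, crop_type, area_fraction, rate_kg_km2_yr
    deposition: dict  # key -> frame: watershed_id, year, value
    nonfood: pd.Series  # watershed_id -> constant export (kg N km^-2 y^-1)
    import_reg: ImportRegression
    fixation_rate: float
    features: dict  # key -> frame: watershed_id, model_id, year, p_annual_mm, p_mam_ext_mm
    coefficients: ModelCoefficients = field(default_factory=ModelCoefficients)
    nani_observed: Optional[pd.DataFrame] = None  # watershed_id, year, five components

    @property
    def areas(self) -> pd.Series:
        return self.watersheds.set_index("watershed_id")["area_km2"]

    @property
    def huc2_map(self) -> pd.Series:
        return self.watersheds.set_index("watershed_id")["huc2"]


def _year_map(period: Period, hist_period: Period, flag: str) -> dict:
    """Target year -> source year, offset-mapped for historical-flag sources."""
    if flag == "future":
        return {int(y): int(y) for y in period.years}
    return {
        int(y): int(hist_period.start + (y - period.start)) for y in period.years
    }


def _pull_years(source: pd.DataFrame, ymap: dict, key: str, cols, index_cols=("watershed_id",)) -> pd.DataFrame:
    """Source rows at mapped years, re-labelled with the target year."""
    inv: dict[int, list[int]] = {}
    for tgt, src in ymap.items():
        inv.setdefault(src, []).append(tgt)
    sub = source[source["year"].isin(inv)]
    have = set(sub["year"].unique())
    missing = sorted(set(inv) - have)
    if missing:
        raise MissingInputError(f"source {key!r}: no data for year {missing[0]}")
    frames = []
    for src, tgts in inv.items():
        block = sub[sub["year"] == src]
        for tgt in tgts:
            f = block[list(index_cols) + list(cols)].copy()
            f["year"] = tgt
            frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _crops_wide(crops: pd.DataFrame) -> pd.DataFrame:
    wide = crops.pivot_table(
        index=["watershed_id", "year"],
        columns="crop_type",
        values=["area_fraction", "rate_kg_km2_yr"],
        fill_value=0.0,
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return wide.reset_index()


def _scenario_nani(world: World, spec: ScenarioSpec, period: Period, hist_period: Period) -> pd.DataFrame:
    """Land-use-derived NANI per (watershed, year) honoring factor flags."""
    key_c = "historical" if spec.cropland == "historical" else spec.ssp
    key_r = "historical" if spec.fertilizer_rate == "historical" else spec.ssp
    ymap_c = _year_map(period, hist_period, spec.cropland)
    ymap_r = _year_map(period, hist_period, spec.fertilizer_rate)
    for key in (key_c, key_r):
        if key not in world.crops:
            raise MissingInputError(f"no crop table for source {key!r}")
    areas = _pull_years(
        _crops_wide(world.crops[key_c]),
        ymap_c,
        key_c,
        [f"area_fraction_{t}" for t in CROP_TYPES],
    )
    rates = _pull_years(
        _crops_wide(world.crops[key_r]),
        ymap_r,
        key_r,
        [f"rate_kg_km2_yr_{t}" for t in CROP_TYPES],
    )
    df = areas.merge(rates, on=["watershed_id", "year"], how="inner")
    fert = np.zeros(len(df))
    for t in CROP_TYPES:
        fert += df[f"area_fraction_{t}"].to_numpy() * df[f"rate_kg_km2_yr_{t}"].to_numpy()
    df["fertilizer"] = fert
    df["fixation"] = df["area_fraction_c3_nfix"].to_numpy() * world.fixation_rate
    df["huc2"] = df["watershed_id"].map(world.huc2_map)
    imp = np.empty(len(df))
    for huc2, grp in df.groupby("huc2"):
        imp[grp.index.to_numpy()] = world.import_reg.predict(
            huc2, grp["fertilizer"].to_numpy(), grp["fixation"].to_numpy()
        )
    df["food_feed_import"] = imp
    dep_key = spec.rcp if spec.precip_mode == "paired-rcp" else "historical"
    dep_flag = "future" if spec.precip_mode == "paired-rcp" else "historical"
    if dep_key not in world.deposition:
        raise MissingInputError(f"no deposition table for source {dep_key!r}")
    dep = _pull_years(world.deposition[dep_key], _year_map(period, hist_period, dep_flag), dep_key, ["value"])
    df = df.merge(dep.rename(columns={"value": "deposition"}), on=["watershed_id", "year"], how="left")
    if df["deposition"].isna().any():
        bad = df.loc[df["deposition"].isna()].iloc[0]
        raise MissingInputError(
            f"deposition missing for watershed {bad['watershed_id']!r} year {bad['year']}"
        )
    df["nonfood_crop_export"] = df["watershed_id"].map(world.nonfood)
    df["nani"] = (
        df["fertilizer"]
        + df["fixation"]
        + df["deposition"]
        + df["food_feed_import"]
        - df["nonfood_crop_export"]
    )
    return df[["watershed_id", "year", "nani"]]


def _observed_nani(world: World, period: Period, hist_period: Period) -> pd.DataFrame:
    if world.nani_observed is None:
        raise MissingInputError("world carries no observed NANI component table")
    comp = _pull_years(
        world.nani_observed,
        _year_map(period, hist_period, "historical"),
        "nani_observed",
        ["fertilizer", "fixation", "deposition", "food_feed_import", "nonfood_crop_export"],
    )
    comp["nani"] = (
        comp["fertilizer"]
        + comp["fixation"]
        + comp["deposition"]
        + comp["food_feed_import"]
        - comp["nonfood_crop_export"]
    )
    return comp[["watershed_id", "year", "nani"]]


def _lu_dc(world: World, spec: ScenarioSpec, period: Period, hist_period: Period) -> pd.DataFrame:
    key_c = "historical" if spec.cropland == "historical" else spec.ssp
    key_d = "historical" if spec.developed == "historical" else spec.ssp
    for key in (key_c, key_d):
        if key not in world.landuse:
            raise MissingInputError(f"no land-use table for source {key!r}")
    crop = _pull_years(
        world.landuse[key_c], _year_map(period, hist_period, spec.cropland), key_c, ["frac_cropland"]
    )
    dev = _pull_years(
        world.landuse[key_d], _year_map(period, hist_period, spec.developed), key_d, ["frac_developed"]
    )
    df = crop.merge(dev, on=["watershed_id", "year"], how="inner")
    df["lu_dc"] = 100.0 * (df["frac_cropland"] + df["frac_developed"])
    return df[["watershed_id", "year", "lu_dc"]]


def run_projection(
    world: World,
    spec: ScenarioSpec,
    period: Period,
    hist_period: Period = HISTORICAL,
) -> TNFluxField:
    """Evaluate the loading model over a period for one scenario spec.

    Returns a flux field indexed by (watershed, year, climate model); the
    model set is that of the precipitation source (historical ensemble or
    the paired RCP ensemble).
    """
    if spec.nani_mode == "observation":
        nani = _observed_nani(world, period, hist_period)
    else:
        nani = _scenario_nani(world, spec, period, hist_period)
    lu = _lu_dc(world, spec, period, hist_period)
    drivers = nani.merge(lu, on=["watershed_id", "year"], how="inner")

    if spec.precip_mode == "historical":
        pkey, pflag = "historical", "historical"
    else:
        pkey, pflag = spec.rcp, "future"
    if pkey not in world.features:
        raise MissingInputError(f"no precipitation features for source {pkey!r}")
    feats = _pull_years(
        world.features[pkey],
        _year_map(period, hist_period, pflag),
        pkey,
        ["p_annual_mm", "p_mam_ext_mm"],
        index_cols=("watershed_id", "model_id"),
    )
    df = feats.merge(drivers, on=["watershed_id", "year"], how="left")
    if df["nani"].isna().any() or df["lu_dc"].isna().any():
        bad = df.loc[df["nani"].isna() | df["lu_dc"].isna()].iloc[0]
        raise MissingInputError(
            f"driver missing for watershed {bad['watershed_id']!r} year {bad['year']}"
        )
    ln_flux = predict_ln_tn_arrays(
        df["nani"], df["p_annual_mm"], df["p_mam_ext_mm"], df["lu_dc"], world.coefficients
    )
    out = df[["watershed_id", "model_id", "year"]].copy()
    out["flux_kg_km2_yr"] = np.exp(ln_flux)
    out = out.sort_values(["watershed_id", "model_id", "year"], ignore_index=True)
    return TNFluxField(spec=spec, period=period, frame=out)


def decomposition_runs(
    world: World,
    base_spec: ScenarioSpec,
    period: Period,
    hist_period: Period = HISTORICAL,
) -> dict:
    """The factorial driver-attribution runs (precipitation held historical).

    Returns flux fields for: "all_future" (all three factors future),
    "cropland_only", "developed_only", and "fertilizer_rate_only". NANI is
    land-use-derived ("scenario" mode) in every run, for both periods, so
    the decomposition compares like with like.
    """
    if base_spec.precip_mode != "historical":
        raise ConfigurationError("decomposition runs require precip_mode='historical'")
    if base_spec.nani_mode != "scenario":
        raise ConfigurationError("decomposition runs require nani_mode='scenario'")
    combos = {
        "all_future": dict(cropland="future", developed="future", fertilizer_rate="future"),
        "cropland_only": dict(cropland="future", developed="historical", fertilizer_rate="historical"),
        "developed_only": dict(cropland="historical", developed="future", fertilizer_rate="historical"),
        "fertilizer_rate_only": dict(cropland="historical", developed="historical", fertilizer_rate="future"),
    }
    return {
        name: run_projection(world, replace(base_spec, **flags), period, hist_period)
        for name, flags in combos.items()
    }


def period_mean(field: TNFluxField, period: Period | None = None) -> pd.DataFrame:
    """Per-(watershed, model) mean annual flux over a period."""
    period = period or field.period
    frame = field.frame[field.frame["year"].between(period.start, period.end)]
    counts = frame.groupby(["watershed_id", "model_id"], observed=True)["year"].nunique()
    if (counts != len(period)).any():
        bad = counts[counts != len(period)].index[0]
        raise MissingInputError(
            f"period {period.label!r} not fully covered for {bad}"
        )
    out = (
        frame.groupby(["watershed_id", "model_id"], observed=True)["flux_kg_km2_yr"]
        .mean()
        .reset_index()
    )
    return out
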