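"""Reduction of daily precipitation to the two model predictors.

The loading model consumes two precipitation features per watershed-year (and
per climate model): the calendar-year total P_Annual, and the extreme
springtime total P_MAM,ext — the amount of precipitation falling on
March-May days that strictly exceed the 95th percentile of daily March-May
precipitation over a fixed 1981-2010 baseline. Thresholds are frozen from the
baseline and reused for all historical and future years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientBaselineError, InvalidInputError

#: Default baseline window for the extreme-precipitation percentile.
DEFAULT_BASELINE = (1981, 2010)
#: Spring season months (March-May).
SEASON_MONTHS = (3, 4, 5)
DEFAULT_PERCENTILE = 0.95


@dataclass(frozen=True)
class DailyPrecipSeries:
    """A contiguous daily precipitation series for one watershed and model.

    ``values`` is indexed by a daily DatetimeIndex with no gaps; amounts are
    in mm and nonnegative.
    """

    watershed_id: str
    model_id: str
    scenario_id: str
    values: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise InvalidInputError("daily series must be indexed by dates")
        full = pd.date_range(idx[0], idx[-1], freq="D")
        if len(full) != len(idx) or not (idx == full).all():
            raise InvalidInputError("daily series has missing or out-of-order days")
        if (self.values < 0).any():
            raise InvalidInputError("negative precipitation")

    def year_covered(self, year: int) -> bool:
        idx = self.values.index
        return idx[0] <= pd.Timestamp(year, 1, 1) and idx[-1] >= pd.Timestamp(year, 12, 31)


@dataclass(frozen=True)
class ExtremeThreshold:
    """Frozen per-(watershed, model) extreme-day threshold in mm."""

    watershed_id: str
    model_id: str
    threshold_mm: float
    baseline: tuple = DEFAULT_BASELINE
    season: tuple = SEASON_MONTHS
    percentile: float = DEFAULT_PERCENTILE

    def __post_init__(self) -> None:
        if self.threshold_mm < 0:
            raise InvalidInputError("threshold must be nonnegative")


def annual_total(series: DailyPrecipSeries, year: int) -> float:
    """Calendar-year precipitation total in mm."""
    if not series.year_covered(year):
        raise InvalidInputError(f"year {year} not fully covered by series")
    v = series.values
    return float(v[(v.index.year == year)].sum())


def extreme_threshold(
    series: DailyPrecipSeries,
    baseline: tuple = DEFAULT_BASELINE,
    season: tuple = SEASON_MONTHS,
    percentile: float = DEFAULT_PERCENTILE,
    wet_day_only: bool = False,
) -> ExtremeThreshold:
    """Percentile of in-season daily precipitation over the baseline years.

    Linear interpolation between order statistics; by default the population
    includes all in-season days (zeros included); ``wet_day_only`` restricts
    it to days with positive precipitation.
    """
    idx = series.values.index
    if not (idx[0] <= pd.Timestamp(baseline[0], 1, 1) and idx[-1] >= pd.Timestamp(baseline[1], 12, 31)):
        raise InsufficientBaselineError(
            f"series does not cover baseline {baseline[0]}-{baseline[1]}"
        )
    mask = idx.month.isin(season) & (idx.year >= baseline[0]) & (idx.year <= baseline[1])
    pop = series.values.to_numpy()[np.asarray(mask)]
    if wet_day_only:
        pop = pop[pop > 0]
    if pop.size == 0:
        raise InsufficientBaselineError("empty percentile population")
    thr = float(np.quantile(pop, percentile, method="linear"))
    return ExtremeThreshold(
        watershed_id=series.watershed_id,
        model_id=series.model_id,
        threshold_mm=thr,
        baseline=tuple(baseline),
        season=tuple(season),
        percentile=percentile,
    )


def extreme_mam_total(series: DailyPrecipSeries, threshold: ExtremeThreshold, year: int) -> float:
    """Total precipitation on in-season days strictly exceeding the threshold."""
    idx = series.values.index
    season = threshold.season
    last_month = max(season)
    end = (pd.Timestamp(year, last_month, 1) + pd.offsets.MonthEnd(0)).day
    if not (
        idx[0] <= pd.Timestamp(year, min(season), 1)
        and idx[-1] >= pd.Timestamp(year, last_month, end)
    ):
        raise InvalidInputError(f"season of year {year} not covered")
    mask = (idx.year == year) & idx.month.isin(season)
    vals = series.values.to_numpy()[np.asarray(mask)]
    return float(vals[vals > threshold.threshold_mm].sum())


# ---------------------------------------------------------------------------
# Vectorized frame-level interface used by the pipeline
# ---------------------------------------------------------------------------

def compute_thresholds(
    frame: pd.DataFrame,
    baseline: tuple = DEFAULT_BASELINE,
    season: tuple = SEASON_MONTHS,
    percentile: float = DEFAULT_PERCENTILE,
    wet_day_only: bool = False,
) -> pd.DataFrame:
    """Per-(watershed, model) extreme thresholds from a long daily frame.

    ``frame`` columns: watershed_id, model_id, date, pr_mm. Returns a frame
    with columns watershed_id, model_id, threshold_mm.
    """
    date = pd.to_datetime(frame["date"])
    mask = date.dt.month.isin(season) & date.dt.year.between(baseline[0], baseline[1])
    pop = frame.loc[mask]
    if pop.empty:
        raise InsufficientBaselineError(
            f"no in-season days within baseline {baseline[0]}-{baseline[1]}"
        )
    if wet_day_only:
        pop = pop[pop["pr_mm"] > 0]
    thr = (
        pop.groupby(["watershed_id", "model_id"], observed=True)["pr_mm"]
        .quantile(percentile, interpolation="linear")
        .rename("threshold_mm")
        .reset_index()
    )
    return thr


def compute_features(
    frame: pd.DataFrame,
    thresholds: pd.DataFrame | None = None,
    baseline: tuple = DEFAULT_BASELINE,
    season: tuple = SEASON_MONTHS,
    percentile: float = DEFAULT_PERCENTILE,
) -> pd.DataFrame:
    """Annual and extreme-springtime totals per (watershed, model, year).

    If ``thresholds`` is None they are computed from the frame's own baseline
    window (appropriate for historical series); future-scenario frames should
    pass thresholds frozen from the matching historical series.
    """
    if thresholds is None:
        thresholds = compute_thresholds(frame, baseline, season, percentile)
    df = frame.copy()
    date = pd.to_datetime(df["date"])
    df["year"] = date.dt.year
    df["_mam"] = date.dt.month.isin(season)
    p_annual = (
        df.groupby(["watershed_id", "model_id", "year"], observed=True)["pr_mm"]
        .sum()
        .rename("p_annual_mm")
    )
    mam = df[df["_mam"]].merge(thresholds, on=["watershed_id", "model_id"], how="left")
    if mam["threshold_mm"].isna().any():
        missing = mam.loc[mam["threshold_mm"].isna(), ["watershed_id", "model_id"]].iloc[0]
        raise InvalidInputError(
            f"no threshold for watershed {missing['watershed_id']} model {missing['model_id']}"
        )
    mam["_ext"] = np.where(mam["pr_mm"] > mam["threshold_mm"], mam["pr_mm"], 0.0)
    p_ext = (
        mam.groupby(["watershed_id", "model_id", "year"], observed=True)["_ext"].sum().rename("p_mam_ext_mm")
    )
    out = pd.concat([p_annual, p_ext], axis=1).fillna({"p_mam_ext_mm": 0.0}).reset_index()
    return out
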