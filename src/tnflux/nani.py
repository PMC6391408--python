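"""Net anthropogenic nitrogen input (NANI) accounting.

NANI is the sum of five signed components per watershed-year, all in
kg N km^-2 y^-1: fertilizer input, agricultural nitrogen fixation,
atmospheric deposition, and net food/feed import are added; nonfood crop
export (cotton, tobacco) is subtracted. Net food/feed import is negative
for net-exporting regions, so NANI itself may be negative.

Two assembly modes exist downstream: "observation mode" builds the budget
from census-style component tables (linearly interpolated between census
years), while "scenario mode" derives fertilizer from crop areas and
application rates, fixation from nitrogen-fixing crop area times a
calibrated constant rate, and food/feed import from a per-region (HUC2)
regression on fertilizer and fixation. The bespoke sub-procedures of both
modes live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InvalidInputError, UnscalableRegionError

#: The five crop types carrying fertilizer application rates.
CROP_TYPES: tuple[str, ...] = (
    "c3_annual",
    "c4_annual",
    "c3_perennial",
    "c4_perennial",
    "c3_nfix",
)

#: Agricultural census years used for component interpolation.
CENSUS_YEARS: tuple[int, ...] = (1987, 1992, 1997, 2002, 2007, 2012)

#: Component names, with sign convention (+1 added, -1 subtracted).
COMPONENT_SIGNS: dict[str, int] = {
    "fertilizer": +1,
    "fixation": +1,
    "deposition": +1,
    "food_feed_import": +1,  # already signed: negative = net export
    "nonfood_crop_export": -1,
}


@dataclass(frozen=True)
class NANIComponents:
    """The five budget terms for one watershed-year (kg N km^-2 y^-1)."""

    fertilizer: float
    fixation: float
    deposition: float
    food_feed_import: float
    nonfood_crop_export: float

    def __post_init__(self) -> None:
        vals = (
            self.fertilizer,
            self.fixation,
            self.deposition,
            self.food_feed_import,
            self.nonfood_crop_export,
        )
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError("NANI components must be finite")
        for name in ("fertilizer", "fixation", "deposition", "nonfood_crop_export"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class CropState:
    """Area fractions and fertilizer rates for the five crop types.

    ``areas`` and ``rates`` map crop type -> area fraction of the watershed
    in [0, 1] and application rate in kg N km^-2 y^-1.
    """

    areas: dict
    rates: dict

    def __post_init__(self) -> None:
        unknown = set(self.areas) - set(CROP_TYPES)
        if unknown:
            raise InvalidInputError(f"unknown crop types {sorted(unknown)}")
        a = np.array([self.areas.get(t, 0.0) for t in CROP_TYPES])
        r = np.array([self.rates.get(t, 0.0) for t in CROP_TYPES])
        if (a < 0).any() or a.sum() > 1 + 1e-9:
            raise InvalidInputError("crop area fractions must be >= 0 and sum to <= 1")
        if (r < 0).any():
            raise InvalidInputError("fertilizer rates must be nonnegative")


@dataclass(frozen=True)
class ImportRegression:
    """Per-HUC2 linear rule: import = intercept + b_f * fertilizer + b_fx * fixation."""

    params: dict  # huc2 -> (intercept, slope_fertilizer, slope_fixation)

    def predict(self, huc2: str, fertilizer, fixation):
        if huc2 not in self.params:
            raise InvalidInputError(f"no import regression for HUC2 {huc2!r}")
        a, bf, bx = self.params[huc2]
        return a + bf * np.asarray(fertilizer, dtype=float) + bx * np.asarray(fixation, dtype=float)


def assemble_nani(c: NANIComponents) -> float:
    """Signed five-component sum; nonfood crop export is subtracted."""
    return (
        c.fertilizer
        + c.fixation
        + c.deposition
        + c.food_feed_import
        - c.nonfood_crop_export
    )


def fertilizer_usage(crops: CropState) -> float:
    """Area-weighted fertilizer application summed over crop types."""
    return float(
        sum(crops.areas.get(t, 0.0) * crops.rates.get(t, 0.0) for t in CROP_TYPES)
    )


def scale_fertilizer_to_reference(
    series: pd.DataFrame,
    huc2_map: pd.Series,
    reference: pd.Series,
    ref_years: tuple = (1987, 2012),
) -> pd.DataFrame:
    """Rescale per-watershed fertilizer series to regional reference totals.

    One multiplicative factor per HUC2 — the ratio of the reference
    1987-2012 total to the input series' 1987-2012 total — is applied to all
    years, future included, so the scaled 1987-2012 regional totals match
    the reference exactly.

    Parameters
    ----------
    series : frame with columns watershed_id, year, value
    huc2_map : Series mapping watershed_id -> huc2
    reference : Series mapping huc2 -> reference total over ``ref_years``
    """
    df = series.copy()
    df["huc2"] = df["watershed_id"].map(huc2_map)
    if df["huc2"].isna().any():
        bad = df.loc[df["huc2"].isna(), "watershed_id"].iloc[0]
        raise InvalidInputError(f"watershed {bad!r} has no HUC2 assignment")
    in_window = df["year"].between(ref_years[0], ref_years[1])
    totals = df[in_window].groupby("huc2")["value"].sum()
    factors = {}
    for huc2 in df["huc2"].unique():
        tot = float(totals.get(huc2, 0.0))
        ref = float(reference.get(huc2, 0.0))
        if tot == 0.0:
            if ref != 0.0:
                raise UnscalableRegionError(
                    f"HUC2 {huc2!r}: zero input total against nonzero reference {ref}"
                )
            factors[huc2] = 1.0
        else:
            factors[huc2] = ref / tot
    out = series.copy()
    out["value"] = df["value"] * df["huc2"].map(factors)
    return out


def fixation_from_area(c3_nfix_area_km2: float, rate_kg_km2_yr: float) -> float:
    """Nitrogen fixation in kg N y^-1: nitrogen-fixing crop area times rate."""
    if c3_nfix_area_km2 < 0 or rate_kg_km2_yr < 0:
        raise InvalidInputError("area and rate must be nonnegative")
    return c3_nfix_area_km2 * rate_kg_km2_yr


def calibrate_fixation_rate(c3_nfix_areas_km2, target_total_kg: float) -> float:
    """Constant fixation rate reproducing a continental-scale fixation total.

    The published calibration divides the 2007 continental fixation estimate
    (6.9 Tg N) by the total nitrogen-fixing crop area, yielding
    14,300 kg N km^-2 y^-1.
    """
    total_area = float(np.sum(np.asarray(c3_nfix_areas_km2, dtype=float)))
    if total_area <= 0:
        raise InvalidInputError("calibration impossible: zero total nitrogen-fixing area")
    return target_total_kg / total_area


def fit_import_regression(history: pd.DataFrame) -> ImportRegression:
    """Per-HUC2 OLS of food/feed import on fertilizer and fixation.

    ``history`` columns: huc2, year, import_kg_km2_yr, fertilizer_kg_km2_yr,
    fixation_kg_km2_yr — one row per census year per region (at least 4).
    """
    params = {}
    for huc2, grp in history.groupby("huc2"):
        if len(grp) < 4:
            raise InvalidInputError(f"HUC2 {huc2!r}: need >= 4 census-year records")
        X = np.column_stack(
            [
                np.ones(len(grp)),
                grp["fertilizer_kg_km2_yr"].to_numpy(),
                grp["fixation_kg_km2_yr"].to_numpy(),
            ]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDesignError(
                f"HUC2 {huc2!r}: collinear fertilizer/fixation history"
            )
        y = grp["import_kg_km2_yr"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        params[huc2] = (float(beta[0]), float(beta[1]), float(beta[2]))
    return ImportRegression(params=params)


def scale_deposition(
    model_dep: pd.DataFrame,
    reference_dep: pd.DataFrame,
    overlap_years: tuple = (2002, 2003, 2004, 2005, 2006),
) -> pd.DataFrame:
    """Adjust modelled deposition to a reference via overlap-period means.

    Per watershed, factor = mean(reference over overlap) / mean(model over
    overlap); all modelled values (future included) are multiplied by the
    factor. A zero/zero overlap passes through unchanged (factor 1); a zero
    model mean against a nonzero reference is unscalable.

    Frames carry columns watershed_id, year, value.
    """
    years = list(overlap_years)
    m_mean = model_dep[model_dep["year"].isin(years)].groupby("watershed_id")["value"].mean()
    r_mean = reference_dep[reference_dep["year"].isin(years)].groupby("watershed_id")["value"].mean()
    factors = {}
    for ws in model_dep["watershed_id"].unique():
        m = float(m_mean.get(ws, np.nan))
        r = float(r_mean.get(ws, np.nan))
        if np.isnan(m) or np.isnan(r):
            raise InvalidInputError(f"watershed {ws!r}: overlap years not covered")
        if m == 0.0:
            if r != 0.0:
                raise UnscalableRegionError(
                    f"watershed {ws!r}: zero model mean against reference {r}"
                )
            factors[ws] = 1.0
        else:
            factors[ws] = r / m
    out = model_dep.copy()
    out["value"] = out["value"] * out["watershed_id"].map(factors)
    return out


def interpolate_census(
    census: pd.Series,
    target_years,
    floor_zero: bool = False,
) -> pd.Series:
    """Annual series from census-year values.

    Piecewise-linear between adjacent census years; years before the first
    census year extrapolate the OLS linear trend fitted to all census points.
    Years after the last census year are out of range (use
    :func:`hold_constant_after` for that rule). ``floor_zero`` clamps
    negative values at 0 (used for fixation; import may be negative).
    """
    census = census.sort_index()
    if len(census) < 2:
        raise InvalidInputError("need at least 2 census points")
    years = np.asarray(list(target_years))
    first, last = census.index.min(), census.index.max()
    if (years > last).any():
        raise InvalidInputError(
            f"target years beyond the census span (last census year {last})"
        )
    out = np.interp(years, census.index.to_numpy(float), census.to_numpy(float))
    before = years < first
    if before.any():
        slope, intercept = np.polyfit(census.index.to_numpy(float), census.to_numpy(float), 1)
        out[before] = intercept + slope * years[before]
    if floor_zero:
        out = np.maximum(out, 0.0)
    return pd.Series(out, index=pd.Index(years, name="year"))


def hold_constant_after(series: pd.Series, anchor_year: int, through_year: int | None = None) -> pd.Series:
    """Freeze a series at its anchor-year value for all later years.

    Used for nonfood crop export (held at the 2007 value after 2007); if
    ``through_year`` extends past the series, the result is padded with the
    anchor value.
    """
    if anchor_year not in series.index:
        raise InvalidInputError(f"anchor year {anchor_year} not in series")
    out = series.sort_index().copy()
    anchor_val = float(out.loc[anchor_year])
    out.loc[out.index > anchor_year] = anchor_val
    if through_year is not None and through_year > out.index.max():
        extra = pd.Series(
            anchor_val, index=pd.RangeIndex(out.index.max() + 1, through_year + 1)
        )
        out = pd.concat([out, extra])
        out.index.name = series.index.name
    return out


def hold_constant_before(series: pd.Series, anchor_year: int, back_to_year: int | None = None) -> pd.Series:
    """Backward variant: freeze at the anchor value for all earlier years.

    Used for atmospheric deposition before 1979, which is assumed to remain
    at 1979 levels.
    """
    if anchor_year not in series.index:
        raise InvalidInputError(f"anchor year {anchor_year} not in series")
    out = series.sort_index().copy()
    anchor_val = float(out.loc[anchor_year])
    out.loc[out.index < anchor_year] = anchor_val
    if back_to_year is not None and back_to_year < out.index.min():
        extra = pd.Series(
            anchor_val, index=pd.RangeIndex(back_to_year, out.index.min())
        )
        out = pd.concat([extra, out])
        out.index.name = series.index.name
    return out


def clamp_nonnegative(values, name: str):
    """Clamp negative predicted fertilizer/fixation to zero with a warning."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        warnings.warn(f"negative predicted {name} clamped to 0", stacklevel=2)
        arr = np.maximum(arr, 0.0)
    return arr
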