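"""Ensemble robustness classification and regional aggregation.

A projected change is "robust" when more than 50% of the climate models show
a significant difference between the future and historical 30-year samples
(two-sided t-test at the 95% level) and more than 80% of the models agree on
the sign of the change. Both inequalities are strict; a model with zero mean
difference counts toward neither sign.

Regional loads are plain area-weighted sums: load [kg N y^-1] = sum over
member watersheds of flux [kg N km^-2 y^-1] times area [km^2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError


@dataclass(frozen=True)
class RegionDef:
    """A named set of member watersheds (e.g. CONUS, MARB, Northeast)."""

    region_id: str
    members: tuple

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise InvalidInputError(f"region {self.region_id!r} has no members")


@dataclass(frozen=True)
class ChangeResult:
    """Summary of a projected change for one watershed or region."""

    unit_id: str
    hist_mean: float
    fut_mean: float
    percent_change: float
    percent_change_sd: float
    robust: bool
    n_models: int
    n_significant: int
    n_sign_agree: int

    def __post_init__(self) -> None:
        if self.n_significant > self.n_models or self.n_sign_agree > self.n_models:
            raise InvalidInputError("counts cannot exceed the number of models")


def aggregate_load(period_means: pd.DataFrame, region: RegionDef, areas: pd.Series) -> pd.Series:
    """Regional nitrogen load per climate model.

    ``period_means`` columns: watershed_id, model_id, flux_kg_km2_yr (30-year
    period means); ``areas`` maps watershed_id -> km^2. Returns a Series
    indexed by model_id in kg N y^-1.
    """
    members = list(region.members)
    sub = period_means[period_means["watershed_id"].isin(members)]
    have = set(sub["watershed_id"].unique())
    missing = [m for m in members if m not in have]
    if missing:
        raise InvalidInputError(
            f"region {region.region_id!r}: no flux for watershed {missing[0]!r}"
        )
    area_missing = [m for m in members if m not in areas.index]
    if area_missing:
        raise InvalidInputError(
            f"region {region.region_id!r}: no area for watershed {area_missing[0]!r}"
        )
    sub = sub.copy()
    sub["load"] = sub["flux_kg_km2_yr"] * sub["watershed_id"].map(areas)
    return sub.groupby("model_id", observed=True)["load"].sum()


def percent_change(hist: float, fut: float) -> float:
    """Percent change of future vs historical; historical must be positive."""
    if hist <= 0:
        raise InvalidInputError(f"historical value must be positive, got {hist}")
    return 100.0 * (fut - hist) / hist


def classify_robust(
    hist_samples: np.ndarray,
    fut_samples: np.ndarray,
    alpha: float = 0.05,
    sig_frac: float = 0.5,
    sign_frac: float = 0.8,
) -> dict:
    """Apply the significance + sign-agreement robustness rule to one unit.

    ``hist_samples`` and ``fut_samples`` are (n_models, n_years) arrays of
    annual values (30 years per period in the canonical setup). Per model a
    Welch two-sided t-test compares the two samples; significance is counted
    when p < alpha, and the sign of change comes from the difference of the
    model's period means. Robust iff the significant fraction strictly
    exceeds ``sig_frac`` and the majority-sign fraction strictly exceeds
    ``sign_frac``.
    """
    hist = np.atleast_2d(np.asarray(hist_samples, dtype=float))
    fut = np.atleast_2d(np.asarray(fut_samples, dtype=float))
    if hist.shape[0] != fut.shape[0]:
        raise InvalidInputError("historical and future must cover the same models")
    if hist.shape[1] < 2 or fut.shape[1] < 2:
        raise InvalidInputError("need at least 2 annual values per sample")
    n_models = hist.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(fut, hist, axis=1, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)  # identical samples: no evidence of change
    n_significant = int(np.sum(pvals < alpha))
    diffs = fut.mean(axis=1) - hist.mean(axis=1)
    n_pos = int(np.sum(diffs > 0))
    n_neg = int(np.sum(diffs < 0))
    n_sign_agree = max(n_pos, n_neg)
    robust = (n_significant / n_models > sig_frac) and (n_sign_agree / n_models > sign_frac)
    return {
        "robust": bool(robust),
        "n_models": n_models,
        "n_significant": n_significant,
        "n_sign_agree": n_sign_agree,
        "sign": 1 if n_pos > n_neg else (-1 if n_neg > n_pos else 0),
    }


def ensemble_summary(per_model_changes) -> tuple[float, float]:
    """Ensemble mean and sample SD (n-1 denominator) of per-model changes."""
    arr = np.asarray(per_model_changes, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("need at least 2 models for an ensemble summary")
    return float(arr.mean()), float(arr.std(ddof=1))


def scenario_agreement(changes: pd.DataFrame, min_agree: int = 5) -> pd.DataFrame:
    """Direction-agreement mask across scenarios.

    ``changes`` columns: unit_id, scenario, change. Per unit, if at least
    ``min_agree`` scenarios share the sign of change the across-scenario mean
    is emitted; otherwise the unit is masked (NaN mean, emitted=False). A
    zero change counts toward neither direction.
    """
    rows = []
    for unit, grp in changes.groupby("unit_id"):
        vals = grp["change"].to_numpy(float)
        n_pos = int(np.sum(vals > 0))
        n_neg = int(np.sum(vals < 0))
        emitted = max(n_pos, n_neg) >= min_agree
        rows.append(
            {
                "unit_id": unit,
                "mean_change": float(vals.mean()) if emitted else np.nan,
                "emitted": emitted,
                "n_scenarios": len(vals),
            }
        )
    return pd.DataFrame(rows)


def change_result(
    unit_id: str,
    hist_annual: np.ndarray,
    fut_annual: np.ndarray,
    alpha: float = 0.05,
    sig_frac: float = 0.5,
    sign_frac: float = 0.8,
) -> ChangeResult:
    """Full change summary for one unit from (n_models, n_years) samples.

    Percent change is summarized per model first (each model's own
    historical mean as the base), then averaged across the ensemble.
    """
    hist = np.atleast_2d(np.asarray(hist_annual, dtype=float))
    fut = np.atleast_2d(np.asarray(fut_annual, dtype=float))
    cls = classify_robust(hist, fut, alpha=alpha, sig_frac=sig_frac, sign_frac=sign_frac)
    hist_means = hist.mean(axis=1)
    fut_means = fut.mean(axis=1)
    per_model_pct = np.array(
        [percent_change(h, f) for h, f in zip(hist_means, fut_means)]
    )
    mean_pct, sd_pct = ensemble_summary(per_model_pct)
    return ChangeResult(
        unit_id=unit_id,
        hist_mean=float(hist_means.mean()),
        fut_mean=float(fut_means.mean()),
        percent_change=mean_pct,
        percent_change_sd=sd_pct,
        robust=cls["robust"],
        n_models=cls["n_models"],
        n_significant=cls["n_significant"],
        n_sign_agree=cls["n_sign_agree"],
    )
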