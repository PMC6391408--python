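"""Seeded synthetic worlds with the statistical structure the analysis assumes.

The real analysis consumes watershed-resolved land-use trajectories,
crop-level fertilizer rates, census-style nitrogen budgets, and daily
multi-model precipitation. None of those archives are redistributable here,
so this module generates worlds that emulate their structure:

* daily precipitation as an occurrence-amount (Bernoulli-Gamma) process per
  watershed and climate model, with multiplicative scenario trends;
* land-use trajectories smooth in time and continuous at the 2015
  historical/future junction, following scenario archetypes (bioenergy
  expansion, food-demand expansion, stable/decline);
* nitrogen-budget components whose continental mean shares match the
  historically observed structure (fertilizer ~ +72% of NANI, fixation
  ~ +45%, deposition ~ +14%, food/feed import ~ -30%, nonfood crop export
  ~ +0.78%);
* calibration datasets drawn from the loading model itself with ln-scale
  Gaussian noise set to a target population R-squared.

Ground truth (generating coefficients, import-regression rule, share
targets) is always returned alongside the data so recovery tests never
re-derive it. All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InvalidInputError
from .model import LU_CATEGORIES, CalibrationDataset, ModelCoefficients
from .nani import CROP_TYPES, ImportRegression, calibrate_fixation_rate, fit_import_regression
from .precip import compute_features, compute_thresholds
from .scenarios import (
    END_CENTURY,
    HISTORICAL,
    Period,
    SSP_RCP_PAIRING,
    World,
    pair_rcp,
)

#: Internal stream ids keeping the generators independent under one seed.
_STREAMS = {
    "watersheds": 1,
    "precip": 2,
    "landuse": 3,
    "calibration": 4,
    "nani": 5,
}

#: The historical junction year between the two archive eras.
JUNCTION_YEAR = 2015
FUTURE_END = 2100


@dataclass(frozen=True)
class ScenarioParams:
    """Archetype parameters for one societal pathway.

    crop_delta / dev_delta : absolute change in area fraction by 2100
    rate_mult : fertilizer application-rate multiplier reached by 2100
    """

    crop_delta: float
    dev_delta: float
    rate_mult: float


#: Scenario archetypes mirroring the pathway narratives: bioenergy-driven
#: cropland expansion (SSP4-3.4, SSP1-2.6), food-demand expansion (SSP3-7.0,
#: SSP4-6.0), and stable-or-declining agriculture (SSP2-4.5, SSP5-8.5).
DEFAULT_SCENARIO_PARAMS: dict[str, ScenarioParams] = {
    "SSP1-2.6": ScenarioParams(0.03, 0.010, 1.05),
    "SSP2-4.5": ScenarioParams(0.00, 0.010, 0.92),
    "SSP3-7.0": ScenarioParams(0.08, 0.005, 1.20),
    "SSP4-3.4": ScenarioParams(0.10, 0.010, 1.25),
    "SSP4-6.0": ScenarioParams(0.06, 0.010, 1.15),
    "SSP5-8.5": ScenarioParams(-0.01, 0.020, 0.85),
}

#: Mean precipitation multiplier reached by 2100 per climate pathway.
DEFAULT_PRECIP_TRENDS: dict[str, float] = {
    "RCP2.6": 1.03,
    "RCP4.5": 1.05,
    "RCP6.0": 1.07,
    "RCP8.5": 1.10,
}

#: NOx deposition multiplier reached by 2100 (declining emissions controls).
DEFAULT_DEPOSITION_TRENDS: dict[str, float] = {
    "RCP2.6": 0.60,
    "RCP4.5": 0.70,
    "RCP6.0": 0.75,
    "RCP8.5": 0.85,
}

#: Observed continental mean component shares, in percent of NANI.
NANI_SHARE_TARGETS: dict[str, float] = {
    "fertilizer": 72.0,
    "fixation": 45.0,
    "deposition": 14.0,
    "food_feed_import": -30.0,
    "nonfood_crop_export": 0.78,
}

#: Base fertilizer application rates per crop type (kg N km^-2 y^-1).
BASE_CROP_RATES: dict[str, float] = {
    "c3_annual": 8000.0,
    "c4_annual": 12000.0,
    "c3_perennial": 6000.0,
    "c4_perennial": 7000.0,
    "c3_nfix": 1000.0,
}


def _default_models() -> dict:
    # Small default ensembles preserving the 21/16/20/12/21 proportions.
    return {"historical": 7, "RCP2.6": 5, "RCP4.5": 6, "RCP6.0": 4, "RCP8.5": 7}


@dataclass(frozen=True)
class WorldConfig:
    """Everything a synthetic world generation run depends on."""

    n_watersheds: int = 50
    n_huc2: int = 5
    n_models: dict = field(default_factory=_default_models)
    hist_years: tuple = (1976, 2005)
    baseline_years: tuple = (1981, 2010)
    seed: int = 0
    coefficients: ModelCoefficients = field(default_factory=ModelCoefficients)
    target_r_squared: float = 0.67
    n_calibration: int = 280
    wet_day_prob: float = 0.30
    gamma_shape: float = 0.7
    gamma_scale: float = 11.7  # mean annual total ~ 900 mm
    precip_trends: dict = field(default_factory=lambda: dict(DEFAULT_PRECIP_TRENDS))
    deposition_trends: dict = field(default_factory=lambda: dict(DEFAULT_DEPOSITION_TRENDS))
    scenario_params: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIO_PARAMS))
    nani_share_targets: dict = field(default_factory=lambda: dict(NANI_SHARE_TARGETS))
    census_years: tuple = (1987, 1992, 1997, 2002, 2007, 2012)
    # Historical-era drift into the 2015 junction: fractional reduction of
    # cropland/developed at the start of the record, and the starting
    # fertilizer-rate multiplier (rates ramp from it to 1.0 at the junction).
    hist_crop_drift: float = 0.10
    hist_dev_drift: float = 0.15
    hist_rate_start: float = 0.8

    def __post_init__(self) -> None:
        if self.n_watersheds <= 0 or self.n_huc2 <= 0:
            raise InvalidInputError("counts must be positive")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "WorldConfig":
        """Full-size preset: 2105 watersheds, published ensemble sizes."""
        return cls(
            n_watersheds=2105,
            n_huc2=18,
            n_models={"historical": 21, "RCP2.6": 16, "RCP4.5": 20, "RCP6.0": 12, "RCP8.5": 21},
            seed=seed,
        )

    def with_scaled_scenario(self, ssp: str, eps: float) -> "WorldConfig":
        """Shrink one scenario's perturbations by a factor eps (linear-limit runs)."""
        p = self.scenario_params[ssp]
        scaled = ScenarioParams(
            crop_delta=p.crop_delta * eps,
            dev_delta=p.dev_delta * eps,
            rate_mult=1.0 + (p.rate_mult - 1.0) * eps,
        )
        params = dict(self.scenario_params)
        params[ssp] = scaled
        return dc_replace(self, scenario_params=params)

    def flat_history(self) -> "WorldConfig":
        """Drift-free historical era: drivers constant at junction values.

        Used for linear-limit experiments where the entire future-vs-
        historical driver perturbation must scale with a single factor.
        """
        return dc_replace(self, hist_crop_drift=0.0, hist_dev_drift=0.0, hist_rate_start=1.0)


def _rng(cfg: WorldConfig, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), _STREAMS[stream], *extra])


def _model_ids(n: int) -> list[str]:
    return [f"M{i + 1:02d}" for i in range(n)]


def _watershed_ids(n: int) -> list[str]:
    return [f"W{i + 1:04d}" for i in range(n)]


def generate_watersheds(cfg: WorldConfig) -> pd.DataFrame:
    """Watershed table: id, HUC2 assignment, area, region memberships.

    Areas are log-normal; the first ~40% of watersheds form a MARB-like
    basin and the following ~15% a Northeast-like region (disjoint by
    construction); CONUS is the full set.
    """
    rng = _rng(cfg, "watersheds")
    n = cfg.n_watersheds
    ids = _watershed_ids(n)
    areas = rng.lognormal(mean=np.log(2000.0), sigma=0.6, size=n)
    huc2 = [f"H{(i % cfg.n_huc2) + 1:02d}" for i in range(n)]
    n_marb = max(1, int(round(0.4 * n)))
    n_ne = max(1, int(round(0.15 * n)))
    in_marb = np.zeros(n, dtype=bool)
    in_marb[:n_marb] = True
    in_ne = np.zeros(n, dtype=bool)
    in_ne[n_marb : n_marb + n_ne] = True
    return pd.DataFrame(
        {
            "watershed_id": ids,
            "huc2": huc2,
            "area_km2": areas,
            "in_marb": in_marb,
            "in_northeast": in_ne,
        }
    )


def _precip_trend_factor(years: np.ndarray, trend_2100: float) -> np.ndarray:
    ramp = np.clip((years - JUNCTION_YEAR) / (FUTURE_END - JUNCTION_YEAR), 0.0, 1.0)
    return 1.0 + (trend_2100 - 1.0) * ramp


def generate_daily_precip(
    cfg: WorldConfig,
    scenario: str,
    years: tuple,
) -> pd.DataFrame:
    """Daily Bernoulli-Gamma precipitation, long format.

    Columns: watershed_id, model_id, scenario_id, date, pr_mm. The model
    ensemble of an RCP reuses the leading historical model ids, so each
    model's parameter jitter is consistent across eras and its extreme
    threshold can be frozen from the historical baseline. Future scenarios
    scale the Gamma scale parameter (mean and tail together) by a linear
    ramp reaching the configured multiplier at 2100.
    """
    if scenario == "historical":
        trend_2100 = 1.0
        scen_idx = 0
    else:
        trend_2100 = cfg.precip_trends[scenario]
        scen_idx = 1 + sorted(cfg.precip_trends).index(scenario)
    n_models = cfg.n_models[scenario] if scenario in cfg.n_models else cfg.n_models["historical"]
    n_ws = cfg.n_watersheds
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    n_days = len(dates)
    year_arr = dates.year.to_numpy()

    # Parameter jitter: per-watershed wet-day prob and scale, per-model multipliers.
    ws_rng = _rng(cfg, "precip", 0)
    p_wet = np.clip(cfg.wet_day_prob * ws_rng.lognormal(0.0, 0.15, n_ws), 0.0, 0.9)
    ws_scale = cfg.gamma_scale * ws_rng.lognormal(0.0, 0.2, n_ws)
    max_m = max(cfg.n_models.values())
    m_rng = _rng(cfg, "precip", 1)
    m_scale_mult = np.clip(m_rng.normal(1.0, 0.06, max_m), 0.7, 1.3)[:n_models]
    m_pwet_mult = np.clip(m_rng.normal(1.0, 0.04, max_m), 0.7, 1.3)[:n_models]

    draw_rng = _rng(cfg, "precip", 2, scen_idx, years[0] % (2**20))
    trend = _precip_trend_factor(year_arr, trend_2100)  # (n_days,)
    u = draw_rng.random((n_ws, n_models, n_days))
    amt = draw_rng.gamma(cfg.gamma_shape, 1.0, (n_ws, n_models, n_days))
    scale = ws_scale[:, None, None] * m_scale_mult[None, :, None] * trend[None, None, :]
    pwet = p_wet[:, None, None] * m_pwet_mult[None, :, None]
    pr = np.where(u < pwet, amt * scale, 0.0)

    ws_ids = _watershed_ids(n_ws)
    model_ids = _model_ids(n_models)
    ws_codes = np.repeat(np.arange(n_ws, dtype=np.int32), n_models * n_days)
    m_codes = np.tile(np.repeat(np.arange(n_models, dtype=np.int32), n_days), n_ws)
    date_col = np.tile(dates.to_numpy(), n_ws * n_models)
    return pd.DataFrame(
        {
            "watershed_id": pd.Categorical.from_codes(ws_codes, ws_ids),
            "model_id": pd.Categorical.from_codes(m_codes, model_ids),
            "scenario_id": scenario,
            "date": date_col,
            "pr_mm": pr.ravel(),
        }
    )


def _base_fractions(cfg: WorldConfig) -> pd.DataFrame:
    """Per-watershed land-use fractions at the 2015 junction (sum to 1)."""
    rng = _rng(cfg, "landuse", 0)
    alphas = {"cropland": 3.0, "developed": 1.0, "forest": 4.0, "other": 1.0, "pasture": 2.0, "rangeland": 2.0}
    draw = rng.dirichlet([alphas[c] for c in LU_CATEGORIES], size=cfg.n_watersheds)
    df = pd.DataFrame(draw, columns=[f"frac_{c}" for c in LU_CATEGORIES])
    df.insert(0, "watershed_id", _watershed_ids(cfg.n_watersheds))
    return df


def _crop_type_shares(cfg: WorldConfig) -> np.ndarray:
    rng = _rng(cfg, "landuse", 1)
    return rng.dirichlet([3.0, 3.0, 1.0, 1.0, 1.5], size=cfg.n_watersheds)


def _rate_jitter(cfg: WorldConfig) -> np.ndarray:
    rng = _rng(cfg, "landuse", 2)
    return rng.lognormal(0.0, 0.1, cfg.n_watersheds)


def generate_landuse(cfg: WorldConfig, scenario: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annual six-category fractions and crop states for one source.

    ``scenario`` is "historical" (1976-2015, mild multiplicative drift into
    the junction values) or an SSP id (2015-2100, archetype ramp continuous
    at 2015). Fractions sum to 1 every watershed-year.

    Returns (landuse frame, crops frame).
    """
    base = _base_fractions(cfg)
    n = cfg.n_watersheds
    base_crop = base["frac_cropland"].to_numpy()
    base_dev = base["frac_developed"].to_numpy()

    if scenario == "historical":
        years = np.arange(cfg.hist_years[0], JUNCTION_YEAR + 1)
        span = JUNCTION_YEAR - cfg.hist_years[0]
        back = (JUNCTION_YEAR - years) / span  # 1 at start, 0 at junction
        crop = base_crop[None, :] * (1.0 - cfg.hist_crop_drift * back[:, None])
        dev = base_dev[None, :] * (1.0 - cfg.hist_dev_drift * back[:, None])
        # rates grew into the junction
        rate_ramp = cfg.hist_rate_start + (1.0 - cfg.hist_rate_start) * (1.0 - back)
    else:
        if scenario not in cfg.scenario_params:
            raise InvalidInputError(f"no scenario parameters for {scenario!r}")
        p = cfg.scenario_params[scenario]
        years = np.arange(JUNCTION_YEAR, FUTURE_END + 1)
        ramp = (years - JUNCTION_YEAR) / (FUTURE_END - JUNCTION_YEAR)
        # Cap deltas so cropland + developed never exceeds 98% of the cell.
        avail = 0.98 - base_crop - base_dev
        crop_delta = np.minimum(p.crop_delta, np.maximum(avail - p.dev_delta, 0.0))
        crop_delta = np.maximum(crop_delta, -base_crop)
        dev_delta = np.maximum(np.minimum(p.dev_delta, avail), -base_dev)
        crop = base_crop[None, :] + crop_delta[None, :] * ramp[:, None]
        dev = base_dev[None, :] + dev_delta[None, :] * ramp[:, None]
        rate_ramp = 1.0 + (p.rate_mult - 1.0) * ramp

    # Remaining categories shrink or grow proportionally so sums stay 1.
    rem_base = 1.0 - base_crop - base_dev
    rem = 1.0 - crop - dev
    others = [c for c in LU_CATEGORIES if c not in ("cropland", "developed")]
    frames = []
    n_years = len(years)
    out = {
        "watershed_id": np.tile(base["watershed_id"].to_numpy(), n_years),
        "year": np.repeat(years, n),
        "frac_cropland": crop.ravel(),
        "frac_developed": dev.ravel(),
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(rem_base[None, :] > 0, rem / rem_base[None, :], 0.0)
    for c in others:
        out[f"frac_{c}"] = (base[f"frac_{c}"].to_numpy()[None, :] * ratio).ravel()
    landuse = pd.DataFrame(out)

    shares = _crop_type_shares(cfg)  # (n_ws, 5)
    jitter = _rate_jitter(cfg)
    crops_frames = []
    for k, t in enumerate(CROP_TYPES):
        area = (crop * shares[:, k][None, :]).ravel()
        rate = (BASE_CROP_RATES[t] * jitter[None, :] * rate_ramp[:, None]).ravel()
        crops_frames.append(
            pd.DataFrame(
                {
                    "watershed_id": out["watershed_id"],
                    "year": out["year"],
                    "crop_type": t,
                    "area_fraction": area,
                    "rate_kg_km2_yr": rate,
                }
            )
        )
    crops = pd.concat(crops_frames, ignore_index=True)
    return landuse, crops


def generate_calibration_dataset(
    cfg: WorldConfig,
    noise_sd: float | None = None,
    replicate: int = 0,
) -> tuple[CalibrationDataset, dict]:
    """Catchment-year records drawn from the loading model itself.

    Predictors span realistic ranges; ln-flux is the model's linear
    predictor under ``cfg.coefficients`` (land-use term on cropland +
    developed percent) plus Gaussian noise. When ``noise_sd`` is None it is
    set from the empirical signal variance so the population R-squared
    equals ``cfg.target_r_squared``.
    """
    rng = _rng(cfg, "calibration", replicate)
    n = cfg.n_calibration
    nani = rng.gamma(2.0, 2500.0, n) - 500.0
    p_annual = np.clip(rng.normal(900.0, 250.0, n), 100.0, None)
    p_ext = p_annual * rng.beta(2.0, 30.0, n)
    lu = rng.dirichlet([3.0, 1.0, 4.0, 1.0, 2.0, 2.0], size=n)  # ordered as LU_CATEGORIES
    lu_pct = 100.0 * lu
    lu_dc = lu_pct[:, 0] + lu_pct[:, 1]

    c = cfg.coefficients
    signal = (
        c.intercept
        + c.coef_fnani * np.arcsinh(nani / 2.0)
        + c.coef_pannual * p_annual
        + c.coef_pext * p_ext
        + c.coef_lu * lu_dc
    )
    if noise_sd is None:
        r2 = cfg.target_r_squared
        noise_sd = float(np.std(signal) * np.sqrt((1.0 - r2) / r2))
    ln_flux = signal + rng.normal(0.0, noise_sd, n)

    frame = pd.DataFrame(
        {
            "catchment_id": [f"C{i + 1:04d}" for i in range(n)],
            "year": 2000 + (np.arange(n) % 13),
            "tn_flux_kg_km2_yr": np.exp(ln_flux),
            "nani_kg_km2_yr": nani,
            "p_annual_mm": p_annual,
            "p_mam_ext_mm": p_ext,
        }
    )
    for k, cat in enumerate(LU_CATEGORIES):
        frame[f"lu_{cat}_pct"] = lu_pct[:, k]
    truth = {
        "coefficients": c,
        "noise_sd": noise_sd,
        "lu_subset": frozenset({"cropland", "developed"}),
        "target_r_squared": cfg.target_r_squared,
    }
    return CalibrationDataset(frame), truth


def _fertilizer_by_ws_year(crops: pd.DataFrame) -> pd.DataFrame:
    df = crops.copy()
    df["fert"] = df["area_fraction"] * df["rate_kg_km2_yr"]
    return df.groupby(["watershed_id", "year"], as_index=False)["fert"].sum()


def _nfix_frac_by_ws_year(crops: pd.DataFrame) -> pd.DataFrame:
    sub = crops[crops["crop_type"] == "c3_nfix"]
    return sub[["watershed_id", "year", "area_fraction"]].rename(
        columns={"area_fraction": "nfix_frac"}
    )


def generate_nani_world(
    cfg: WorldConfig,
    watersheds: pd.DataFrame,
    crops_hist: pd.DataFrame,
) -> dict:
    """Nitrogen-budget structures anchored to the historical crop world.

    Builds, from the historical crop table: the calibrated fixation rate,
    the per-HUC2 import rule (a known linear truth, so the fitted regression
    has recoverable coefficients), deposition and nonfood-export fields, the
    observed component table for the historical period, and census-year
    observation tables. Component magnitudes are set so the area-weighted
    continental mean shares match the configured targets.
    """
    rng = _rng(cfg, "nani")
    areas = watersheds.set_index("watershed_id")["area_km2"]
    huc2_map = watersheds.set_index("watershed_id")["huc2"]
    w = areas / areas.sum()
    hy0, hy1 = cfg.hist_years
    targets = cfg.nani_share_targets

    fert = _fertilizer_by_ws_year(crops_hist)
    fert_hist = fert[fert["year"].between(hy0, hy1)]
    fbar = float((fert_hist.groupby("watershed_id")["fert"].mean() * w).sum())
    nani0 = fbar / (targets["fertilizer"] / 100.0)

    nfix = _nfix_frac_by_ws_year(crops_hist)
    nfix_2007 = nfix[nfix["year"] == 2007].set_index("watershed_id")["nfix_frac"]
    nfix_areas = (nfix_2007 * areas).reindex(areas.index).fillna(0.0)
    fix_target_total = (targets["fixation"] / 100.0) * nani0 * areas.sum()
    fixation_rate = calibrate_fixation_rate(nfix_areas.to_numpy(), fix_target_total)

    # Known linear import rule per HUC2 (negative slopes: more production,
    # more net export), intercept set so the continental mean share hits its
    # target over the historical period.
    fix = nfix.copy()
    fix["fixv"] = fix["nfix_frac"] * fixation_rate
    drv = fert.merge(fix[["watershed_id", "year", "fixv"]], on=["watershed_id", "year"])
    drv["huc2"] = drv["watershed_id"].map(huc2_map)
    drv["aw"] = drv["watershed_id"].map(w)
    import_params = {}
    drv_hist = drv[drv["year"].between(hy0, hy1)]
    for i, (huc2, grp) in enumerate(sorted(drv_hist.groupby("huc2"), key=lambda kv: kv[0])):
        bf = -0.25 * (1.0 + 0.1 * rng.standard_normal())
        bx = -0.15 * (1.0 + 0.1 * rng.standard_normal())
        aw = grp["aw"] / grp["aw"].sum()
        fbar_h = float((grp["fert"] * aw).sum())
        xbar_h = float((grp["fixv"] * aw).sum())
        a = (targets["food_feed_import"] / 100.0) * nani0 - bf * fbar_h - bx * xbar_h
        import_params[huc2] = (float(a), float(bf), float(bx))
    import_reg_truth = ImportRegression(params=import_params)

    # Deposition: log-normal spatial field, mild upward drift, rescaled so
    # the historical continental mean share is exact.
    dep_ws = rng.lognormal(0.0, 0.3, len(areas))
    dep_years = np.arange(hy0, JUNCTION_YEAR + 1)
    drift = 1.0 + 0.003 * (dep_years - hy0)
    dep_vals = dep_ws[None, :] * drift[:, None]
    dep_frame = pd.DataFrame(
        {
            "watershed_id": np.tile(areas.index.to_numpy(), len(dep_years)),
            "year": np.repeat(dep_years, len(areas)),
            "value": dep_vals.ravel(),
        }
    )
    hist_mean = float(
        (dep_frame[dep_frame["year"].between(hy0, hy1)].groupby("watershed_id")["value"].mean() * w).sum()
    )
    dep_frame["value"] *= (targets["deposition"] / 100.0) * nani0 / hist_mean

    # Nonfood crop export: tiny constant field, exact mean share.
    nf = rng.lognormal(0.0, 0.2, len(areas))
    nf *= (targets["nonfood_crop_export"] / 100.0) * nani0 / float((pd.Series(nf, index=areas.index) * w).sum())
    nonfood = pd.Series(nf, index=areas.index, name="nonfood")

    # Observed component table for the historical period.
    obs = (
        drv[drv["year"].between(hy0, hy1)][["watershed_id", "year", "fert", "fixv", "huc2"]]
        .reset_index(drop=True)
    )
    imp = np.empty(len(obs))
    for huc2, grp in obs.groupby("huc2"):
        a, bf, bx = import_params[huc2]
        imp[grp.index.to_numpy()] = a + bf * grp["fert"].to_numpy() + bx * grp["fixv"].to_numpy()
    obs["food_feed_import"] = imp
    obs = obs.merge(
        dep_frame.rename(columns={"value": "deposition"}), on=["watershed_id", "year"]
    )
    obs["nonfood_crop_export"] = obs["watershed_id"].map(nonfood)
    obs = obs.rename(columns={"fert": "fertilizer", "fixv": "fixation"})
    nani_observed = obs[
        ["watershed_id", "year", "fertilizer", "fixation", "deposition", "food_feed_import", "nonfood_crop_export"]
    ].sort_values(["watershed_id", "year"], ignore_index=True)

    # Census-year observation tables at HUC2 aggregate scale (noiseless, so
    # the fitted import regression recovers the generating rule exactly).
    cens = drv[drv["year"].isin(cfg.census_years)].copy()
    rows = []
    for (huc2, year), grp in cens.groupby(["huc2", "year"]):
        aw = grp["aw"] / grp["aw"].sum()
        f = float((grp["fert"] * aw).sum())
        x = float((grp["fixv"] * aw).sum())
        a, bf, bx = import_params[huc2]
        rows.append(
            {
                "huc2": huc2,
                "year": int(year),
                "fertilizer_kg_km2_yr": f,
                "fixation_kg_km2_yr": x,
                "import_kg_km2_yr": a + bf * f + bx * x,
            }
        )
    census_table = pd.DataFrame(rows).sort_values(["huc2", "year"], ignore_index=True)

    return {
        "nani0": nani0,
        "fixation_rate": fixation_rate,
        "import_reg_truth": import_reg_truth,
        "deposition_hist": dep_frame,
        "nonfood": nonfood,
        "nani_observed": nani_observed,
        "census_table": census_table,
    }


def nani_share_check(nani_observed: pd.DataFrame, watersheds: pd.DataFrame) -> dict:
    """Area-weighted continental mean component shares, percent of NANI."""
    areas = watersheds.set_index("watershed_id")["area_km2"]
    w = areas / areas.sum()
    means = nani_observed.groupby("watershed_id")[
        ["fertilizer", "fixation", "deposition", "food_feed_import", "nonfood_crop_export"]
    ].mean()
    aw = means.mul(w, axis=0).sum()
    nani = aw["fertilizer"] + aw["fixation"] + aw["deposition"] + aw["food_feed_import"] - aw["nonfood_crop_export"]
    return {k: float(100.0 * aw[k] / nani) for k in aw.index}


def _future_deposition(cfg: WorldConfig, dep_hist: pd.DataFrame, rcp: str) -> pd.DataFrame:
    """RCP deposition: per-watershed historical-mean level with a decline ramp."""
    base = dep_hist.groupby("watershed_id", as_index=False)["value"].mean()
    years = np.arange(JUNCTION_YEAR, FUTURE_END + 1)
    ramp = (years - JUNCTION_YEAR) / (FUTURE_END - JUNCTION_YEAR)
    mult = 1.0 + (cfg.deposition_trends[rcp] - 1.0) * ramp
    n = len(base)
    return pd.DataFrame(
        {
            "watershed_id": np.tile(base["watershed_id"].to_numpy(), len(years)),
            "year": np.repeat(years, n),
            "value": (base["value"].to_numpy()[None, :] * mult[:, None]).ravel(),
        }
    )


def generate_world(
    cfg: WorldConfig,
    scenarios: tuple = ("SSP4-3.4",),
    future_periods: tuple = (END_CENTURY,),
) -> tuple[World, dict]:
    """Assemble a complete :class:`~tnflux.scenarios.World` plus ground truth.

    Generates watersheds, land use and crops (historical + each scenario),
    the nitrogen-budget structures, daily precipitation reduced to features
    (historical ensemble plus each paired RCP over the requested future
    periods, with extreme thresholds frozen from the historical baseline),
    and fits the import regression from the census tables.
    """
    watersheds = generate_watersheds(cfg)
    lu_hist, crops_hist = generate_landuse(cfg, "historical")
    landuse = {"historical": lu_hist}
    crops = {"historical": crops_hist}
    for ssp in scenarios:
        lu, cr = generate_landuse(cfg, ssp)
        landuse[ssp] = lu
        crops[ssp] = cr

    nani_truth = generate_nani_world(cfg, watersheds, crops_hist)
    deposition = {"historical": nani_truth["deposition_hist"]}
    rcps = sorted({pair_rcp(ssp) for ssp in scenarios})
    for rcp in rcps:
        deposition[rcp] = _future_deposition(cfg, nani_truth["deposition_hist"], rcp)

    hist_span = (min(cfg.hist_years[0], cfg.baseline_years[0]), max(cfg.hist_years[1], cfg.baseline_years[1]))
    daily_hist = generate_daily_precip(cfg, "historical", hist_span)
    thresholds = compute_thresholds(daily_hist, baseline=cfg.baseline_years)
    features = {"historical": compute_features(daily_hist, thresholds=thresholds)}
    for rcp in rcps:
        span = (min(p.start for p in future_periods), max(p.end for p in future_periods))
        daily_f = generate_daily_precip(cfg, rcp, span)
        n_m = cfg.n_models[rcp]
        thr_sub = thresholds[thresholds["model_id"].isin(_model_ids(n_m))]
        features[rcp] = compute_features(daily_f, thresholds=thr_sub)

    try:
        import_reg = fit_import_regression(nani_truth["census_table"])
    except DegenerateDesignError:
        # A drift-free history has no census-year variation to regress on;
        # use the generating rule directly.
        import_reg = nani_truth["import_reg_truth"]

    world = World(
        watersheds=watersheds,
        landuse=landuse,
        crops=crops,
        deposition=deposition,
        nonfood=nani_truth["nonfood"],
        import_reg=import_reg,
        fixation_rate=nani_truth["fixation_rate"],
        features=features,
        coefficients=cfg.coefficients,
        nani_observed=nani_truth["nani_observed"],
    )
    truth = {
        "config": cfg,
        "nani0": nani_truth["nani0"],
        "fixation_rate": nani_truth["fixation_rate"],
        "import_reg_truth": nani_truth["import_reg_truth"],
        "census_table": nani_truth["census_table"],
        "share_targets": dict(cfg.nani_share_targets),
    }
    return world, truth
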