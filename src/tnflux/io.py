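"""Table readers/writers, run configuration, and the pipeline driver.

Long-format CSV is the canonical interchange. Every table type has a schema
(required columns with types and an optional uniqueness key); readers
validate and name the offending column or key on failure. ``run_pipeline``
sequences the full analysis — synthetic world, precipitation features, NANI,
projections, period means, regional aggregation, robustness — and writes a
manifest (config hash, seed, package version) so a result directory can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, SchemaError
from .model import LU_CATEGORIES, FittedModel, ModelCoefficients
from .robustness import RegionDef, change_result
from .scenarios import (
    END_CENTURY,
    HISTORICAL,
    Period,
    ScenarioSpec,
    World,
    period_mean,
    run_projection,
)  # noqa: F401
from .synth import WorldConfig, generate_world

log = logging.getLogger("tnflux")

_LU_COLS = [f"frac_{c}" for c in LU_CATEGORIES]

#: Table schemas: required columns -> dtype kind ("s" string, "i" int,
#: "f" float, "b" bool), plus an optional duplicate-detection key.
SCHEMAS: dict[str, dict] = {
    "watersheds": {
        "columns": {"watershed_id": "s", "huc2": "s", "area_km2": "f"},
        "key": ["watershed_id"],
    },
    "landuse": {
        "columns": {"watershed_id": "s", "year": "i", **{c: "f" for c in _LU_COLS}},
        "key": ["watershed_id", "year"],
    },
    "crops": {
        "columns": {
            "watershed_id": "s",
            "year": "i",
            "crop_type": "s",
            "area_fraction": "f",
            "rate_kg_km2_yr": "f",
        },
        "key": ["watershed_id", "year", "crop_type"],
    },
    "precip": {
        "columns": {
            "watershed_id": "s",
            "model_id": "s",
            "scenario_id": "s",
            "date": "s",
            "pr_mm": "f",
        },
        "key": None,
    },
    "features": {
        "columns": {
            "watershed_id": "s",
            "model_id": "s",
            "year": "i",
            "p_annual_mm": "f",
            "p_mam_ext_mm": "f",
        },
        "key": ["watershed_id", "model_id", "year"],
    },
    "nani_components": {
        "columns": {"watershed_id": "s", "year": "i", "component": "s", "value_kg_km2_yr": "f"},
        "key": ["watershed_id", "year", "component"],
    },
    "calibration": {
        "columns": {
            "catchment_id": "s",
            "year": "i",
            "tn_flux_kg_km2_yr": "f",
            "nani_kg_km2_yr": "f",
            "p_annual_mm": "f",
            "p_mam_ext_mm": "f",
        },
        "key": ["catchment_id", "year"],
    },
    "regions": {
        "columns": {"region_id": "s", "watershed_id": "s"},
        "key": ["region_id", "watershed_id"],
    },
    "reference_totals": {
        "columns": {"huc2": "s", "total_kg": "f"},
        "key": ["huc2"],
    },
    "flux": {
        "columns": {"watershed_id": "s", "model_id": "s", "year": "i", "flux_kg_km2_yr": "f"},
        "key": ["watershed_id", "model_id", "year"],
    },
}

_KIND_CHECK = {
    "f": pd.api.types.is_numeric_dtype,
    "i": pd.api.types.is_integer_dtype,
    "s": lambda s: pd.api.types.is_string_dtype(s) or pd.api.types.is_object_dtype(s),
    "b": pd.api.types.is_bool_dtype,
}


def read_table(path, schema_id: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema."""
    if schema_id not in SCHEMAS:
        raise ConfigurationError(f"unknown schema {schema_id!r}")
    schema = SCHEMAS[schema_id]
    df = pd.read_csv(path)
    for col, kind in schema["columns"].items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
        if not _KIND_CHECK[kind](df[col]):
            raise SchemaError(f"{path}: column {col!r} has wrong type {df[col].dtype}")
    key = schema.get("key")
    if key and df.duplicated(key).any():
        dup = df[df.duplicated(key)].iloc[0]
        raise SchemaError(f"{path}: duplicate key {tuple(dup[k] for k in key)} on {key}")
    return df


def write_table(df: pd.DataFrame, path, schema_id: str | None = None) -> None:
    """Write a table as CSV (validating against the schema if given)."""
    if schema_id is not None:
        schema = SCHEMAS[schema_id]
        missing = [c for c in schema["columns"] if c not in df.columns]
        if missing:
            raise SchemaError(f"refusing to write {path}: missing column {missing[0]!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_fitted_model(model: FittedModel, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=True)


def read_coefficients(path) -> ModelCoefficients:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    c = doc["coefficients"]
    return ModelCoefficients(
        intercept=c["intercept"],
        coef_fnani=c["coef_fnani"],
        coef_pannual=c["coef_pannual"],
        coef_pext=c["coef_pext"],
        coef_lu=c["coef_lu"],
    )


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    outdir: str
    seed: int = 0
    scenarios: tuple = ("SSP4-3.4",)
    with_precip_change: bool = True
    hist_period: tuple = (HISTORICAL.start, HISTORICAL.end)
    future_period: tuple = (END_CENTURY.start, END_CENTURY.end)
    world: dict = field(default_factory=dict)  # WorldConfig overrides
    robustness: dict = field(default_factory=lambda: {"alpha": 0.05, "sig_frac": 0.5, "sign_frac": 0.8})
    coefficients_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        if "scenarios" in doc:
            doc["scenarios"] = tuple(doc["scenarios"])
        for key in ("hist_period", "future_period"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "scenarios": list(self.scenarios),
            "with_precip_change": self.with_precip_change,
            "hist_period": list(self.hist_period),
            "future_period": list(self.future_period),
            "world": dict(self.world),
            "robustness": dict(self.robustness),
            "coefficients_file": self.coefficients_file,
        }


def _regions_from_watersheds(watersheds: pd.DataFrame) -> list[RegionDef]:
    regions = [RegionDef("CONUS", tuple(watersheds["watershed_id"]))]
    for rid, col in (("MARB", "in_marb"), ("Northeast", "in_northeast")):
        if col in watersheds.columns and watersheds[col].any():
            regions.append(RegionDef(rid, tuple(watersheds.loc[watersheds[col], "watershed_id"])))
    return regions


def _regional_annual_loads(field_frame: pd.DataFrame, region: RegionDef, areas: pd.Series) -> pd.DataFrame:
    sub = field_frame[field_frame["watershed_id"].isin(region.members)].copy()
    sub["load"] = sub["flux_kg_km2_yr"] * sub["watershed_id"].map(areas)
    return sub.groupby(["model_id", "year"], observed=True)["load"].sum().unstack("year")


def run_pipeline(config: RunConfig, world: World | None = None) -> dict:
    """Execute the full analysis and write result tables plus a manifest.

    Stages: synthetic world (unless one is passed in) -> projections per
    scenario (land-management-only, and combined with the paired-RCP
    precipitation if requested) -> 30-year period means -> regional loads ->
    change summaries with ensemble robustness. Returns the change table as a
    DataFrame alongside the paths written.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hist_period = Period("historical", *config.hist_period)
    fut_period = Period("future", *config.future_period)

    if world is None:
        log.info("stage: synthesize world")
        cfg = WorldConfig(seed=config.seed, **config.world)
        world, _ = generate_world(cfg, scenarios=tuple(config.scenarios), future_periods=(fut_period,))
    if config.coefficients_file:
        world.coefficients = read_coefficients(config.coefficients_file)

    areas = world.areas
    regions = _regions_from_watersheds(world.watersheds)
    rb = config.robustness

    log.info("stage: historical baseline")
    baseline_spec = ScenarioSpec.all_historical(
        ssp=config.scenarios[0],
        nani_mode="observation" if world.nani_observed is not None else "scenario",
    )
    hist_field = run_projection(world, baseline_spec, hist_period, hist_period)

    rows = []
    flux_paths = []
    for ssp in config.scenarios:
        run_modes = [("land_only", "historical")]
        if config.with_precip_change:
            run_modes.append(("combined", "paired-rcp"))
        for label, pmode in run_modes:
            log.info("stage: projection %s %s", ssp, label)
            spec = ScenarioSpec(ssp=ssp, precip_mode=pmode)
            fut_field = run_projection(world, spec, fut_period, hist_period)
            path = outdir / f"period_mean_{ssp.replace('.', '')}_{label}.csv"
            write_table(period_mean(fut_field), path)
            flux_paths.append(str(path))
            for region in regions:
                hist_ann = _regional_annual_loads(hist_field.frame, region, areas)
                fut_ann = _regional_annual_loads(fut_field.frame, region, areas)
                models = [m for m in fut_ann.index if m in hist_ann.index]
                res = change_result(
                    region.region_id,
                    hist_ann.loc[models].to_numpy(),
                    fut_ann.loc[models].to_numpy(),
                    alpha=rb["alpha"],
                    sig_frac=rb["sig_frac"],
                    sign_frac=rb["sign_frac"],
                )
                rows.append(
                    {
                        "scenario": ssp,
                        "run": label,
                        "region": region.region_id,
                        "hist_load_kg_yr": res.hist_mean,
                        "fut_load_kg_yr": res.fut_mean,
                        "percent_change": res.percent_change,
                        "percent_change_sd": res.percent_change_sd,
                        "robust": res.robust,
                        "n_models": res.n_models,
                        "n_significant": res.n_significant,
                        "n_sign_agree": res.n_sign_agree,
                    }
                )

    changes = pd.DataFrame(rows).sort_values(["scenario", "run", "region"], ignore_index=True)
    changes_path = outdir / "changes.csv"
    write_table(changes, changes_path)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "tnflux_version": __version__,
        "outputs": [str(changes_path), *flux_paths],
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline done in %.1fs", manifest["elapsed_s"])
    return {"changes": changes, "manifest": manifest, "outdir": str(outdir)}


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())
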