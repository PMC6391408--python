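"""Empirical log-linear model of riverine total-nitrogen (TN) flux.

The model relates the natural log of annual TN flux (kg N km^-2 y^-1) at
watershed scale to four predictors:

    ln(Q_TN) = b0 + b1 * f_NANI + b2 * P_Annual + b3 * P_MAM,ext + b4 * LU_DC

where f_NANI = asinh(NANI / 2) is the transformed net anthropogenic nitrogen
input, P_Annual is annual precipitation (mm), P_MAM,ext is extreme springtime
(March-May) precipitation (mm) above a fixed baseline percentile, and LU_DC is
the percentage of the catchment classified as developed or cropland.

This module houses the model itself (evaluation, calibration by OLS on the ln
scale, and the exhaustive land-use predictor selection search).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDesignError, InvalidInputError

#: The six aggregated land-use categories (alphabetical; this order defines
#: the lexicographic tie-break in :func:`select_model`).
LU_CATEGORIES: tuple[str, ...] = (
    "cropland",
    "developed",
    "forest",
    "other",
    "pasture",
    "rangeland",
)

#: Names of the fixed (non-land-use) predictors, in design-matrix order.
FIXED_PREDICTORS: tuple[str, ...] = ("f_nani", "p_annual", "p_mam_ext")


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficients of the TN loading model.

    The defaults are the published calibration for the aggregated land-use
    categories, with the land-use term applying to the summed percent cover
    of cropland plus developed land.
    """

    intercept: float = 0.538
    coef_fnani: float = 0.438
    coef_pannual: float = 0.0012
    coef_pext: float = 0.0033
    coef_lu: float = 0.0213

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("model coefficients must all be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.intercept, self.coef_fnani, self.coef_pannual, self.coef_pext, self.coef_lu]
        )


@dataclass(frozen=True)
class PredictorRecord:
    """One watershed-year predictor tuple.

    nani : kg N km^-2 y^-1 (may be negative: net-export watersheds are legal)
    p_annual, p_mam_ext : mm y^-1, with p_annual >= p_mam_ext >= 0
    lu_dc : percent of catchment area developed or cropland, in [0, 100]
    """

    nani: float
    p_annual: float
    p_mam_ext: float
    lu_dc: float

    def __post_init__(self) -> None:
        vals = (self.nani, self.p_annual, self.p_mam_ext, self.lu_dc)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite predictor value in {vals}")
        if self.p_mam_ext < 0 or self.p_annual < self.p_mam_ext:
            raise InvalidInputError(
                f"need p_annual >= p_mam_ext >= 0, got ({self.p_annual}, {self.p_mam_ext})"
            )
        if not 0.0 <= self.lu_dc <= 100.0:
            raise InvalidInputError(f"lu_dc must lie in [0, 100], got {self.lu_dc}")


@dataclass(frozen=True)
class CalibrationDataset:
    """Catchment-year records used to fit the loading model.

    ``frame`` columns: catchment_id, year, tn_flux_kg_km2_yr,
    nani_kg_km2_yr, p_annual_mm, p_mam_ext_mm, plus one ``lu_<category>_pct``
    column per aggregated land-use category (percent of catchment area).
    """

    frame: pd.DataFrame

    REQUIRED = (
        "catchment_id",
        "year",
        "tn_flux_kg_km2_yr",
        "nani_kg_km2_yr",
        "p_annual_mm",
        "p_mam_ext_mm",
    )

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise InvalidInputError(f"calibration table missing columns {missing}")
        if (df["tn_flux_kg_km2_yr"] <= 0).any():
            raise InvalidInputError("observed TN flux must be strictly positive (ln is taken)")
        if df.duplicated(["catchment_id", "year"]).any():
            raise InvalidInputError("duplicate (catchment, year) records")
        lu = df[[c for c in df.columns if c.startswith("lu_")]]
        if not lu.empty:
            if ((lu < 0) | (lu > 100)).any().any():
                raise InvalidInputError("land-use percent columns must lie in [0, 100]")
            if (lu.sum(axis=1) > 100 + 1e-6).any():
                raise InvalidInputError("land-use percentages sum to more than 100")

    @property
    def lu_categories(self) -> tuple[str, ...]:
        return tuple(
            c[len("lu_") : -len("_pct")] for c in self.frame.columns if c.startswith("lu_")
        )

    def lu_percent(self, subset) -> np.ndarray:
        """Summed percent cover over a subset of land-use categories."""
        cols = [f"lu_{cat}_pct" for cat in sorted(subset)]
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise InvalidInputError(f"unknown land-use categories {missing}")
        return self.frame[cols].sum(axis=1).to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class FittedModel:
    """Result of an OLS calibration of the loading model.

    ``coefficients.coef_lu`` is the coefficient of the first land-use
    predictor; models with two disjoint land-use predictors carry both in
    ``lu_coefs``.
    """

    coefficients: ModelCoefficients
    lu_subsets: tuple[frozenset, ...]
    lu_coefs: tuple[float, ...]
    r_squared: float
    resid_sd: float
    std_errors: dict = field(default_factory=dict)
    bic: float = float("nan")
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InvalidInputError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.resid_sd < 0:
            raise InvalidInputError("residual SD must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                "intercept": self.coefficients.intercept,
                "coef_fnani": self.coefficients.coef_fnani,
                "coef_pannual": self.coefficients.coef_pannual,
                "coef_pext": self.coefficients.coef_pext,
                "coef_lu": self.coefficients.coef_lu,
            },
            "lu_subsets": [sorted(s) for s in self.lu_subsets],
            "lu_coefs": list(self.lu_coefs),
            "r_squared": float(self.r_squared),
            "resid_sd": float(self.resid_sd),
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "bic": float(self.bic),
            "n_obs": int(self.n_obs),
        }


def transform_nani(nani):
    """Inverse-hyperbolic-sine transform of NANI: asinh(nani / 2).

    Defined on all reals (negative NANI means net nitrogen export), odd and
    strictly increasing; behaves like ln(nani) for large inputs.
    """
    arr = np.asarray(nani, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("NANI must be finite")
    out = np.arcsinh(arr / 2.0)
    return float(out) if np.isscalar(nani) or arr.ndim == 0 else out


def predict_ln_tn(rec: PredictorRecord, coeffs: ModelCoefficients | None = None) -> float:
    """Evaluate the linear predictor: expected ln TN flux for one record."""
    coeffs = coeffs or ModelCoefficients()
    return (
        coeffs.intercept
        + coeffs.coef_fnani * transform_nani(rec.nani)
        + coeffs.coef_pannual * rec.p_annual
        + coeffs.coef_pext * rec.p_mam_ext
        + coeffs.coef_lu * rec.lu_dc
    )


def predict_tn_flux(rec: PredictorRecord, coeffs: ModelCoefficients | None = None) -> float:
    """Predicted TN flux in kg N km^-2 y^-1 (plain exponentiation, no smearing)."""
    return float(np.exp(predict_ln_tn(rec, coeffs)))


def predict_ln_tn_arrays(nani, p_annual, p_mam_ext, lu_dc, coeffs: ModelCoefficients | None = None):
    """Vectorized linear predictor over aligned arrays (used by the scenario engine)."""
    coeffs = coeffs or ModelCoefficients()
    return (
        coeffs.intercept
        + coeffs.coef_fnani * np.arcsinh(np.asarray(nani, dtype=float) / 2.0)
        + coeffs.coef_pannual * np.asarray(p_annual, dtype=float)
        + coeffs.coef_pext * np.asarray(p_mam_ext, dtype=float)
        + coeffs.coef_lu * np.asarray(lu_dc, dtype=float)
    )


def _design_matrix(dataset: CalibrationDataset, lu_subsets) -> tuple[np.ndarray, np.ndarray, list]:
    df = dataset.frame
    cols = [
        np.ones(len(df)),
        np.arcsinh(df["nani_kg_km2_yr"].to_numpy() / 2.0),
        df["p_annual_mm"].to_numpy(),
        df["p_mam_ext_mm"].to_numpy(),
    ]
    names = ["intercept", *FIXED_PREDICTORS]
    for i, subset in enumerate(lu_subsets):
        cols.append(dataset.lu_percent(subset))
        names.append(f"lu_{i}:" + "+".join(sorted(subset)))
    X = np.column_stack(cols)
    y = np.log(df["tn_flux_kg_km2_yr"].to_numpy())
    return X, y, names


def calibrate(dataset: CalibrationDataset, lu_subsets=(frozenset({"cropland", "developed"}),)) -> FittedModel:
    """Fit the loading model by OLS of ln(observed flux) on the predictors.

    ``lu_subsets`` gives the land-use predictors: each is a set of category
    names whose percent covers are summed into one column (at most two,
    disjoint).

    Raises
    ------
    DegenerateDesignError
        If the design matrix is rank deficient (e.g. a constant land-use
        column, collinear with the intercept).
    """
    lu_subsets = tuple(frozenset(s) for s in lu_subsets)
    if len(lu_subsets) > 2:
        raise InvalidInputError("at most two land-use predictors are supported")
    if len(lu_subsets) == 2 and lu_subsets[0] & lu_subsets[1]:
        raise InvalidInputError("the two land-use subsets must be disjoint")
    n_coef = 4 + len(lu_subsets)
    if len(dataset) < n_coef + 2:
        raise InvalidInputError(
            f"need at least {n_coef + 2} records to fit {n_coef} coefficients"
        )
    X, y, names = _design_matrix(dataset, lu_subsets)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            "rank-deficient design (constant or collinear predictor column)"
        )
    res = sm.OLS(y, X).fit()
    lu_coefs = tuple(float(c) for c in res.params[4:]) or (0.0,)
    coeffs = ModelCoefficients(
        intercept=float(res.params[0]),
        coef_fnani=float(res.params[1]),
        coef_pannual=float(res.params[2]),
        coef_pext=float(res.params[3]),
        coef_lu=lu_coefs[0],
    )
    return FittedModel(
        coefficients=coeffs,
        lu_subsets=lu_subsets,
        lu_coefs=tuple(float(c) for c in res.params[4:]),
        r_squared=float(res.rsquared),
        resid_sd=float(np.sqrt(res.mse_resid)),
        std_errors=dict(zip(names, (float(s) for s in res.bse))),
        bic=float(res.bic),
        n_obs=int(res.nobs),
    )


def _candidate_lu_sets(categories, max_lu_predictors: int):
    """All candidate land-use predictor structures, in deterministic order.

    Candidates: the empty structure (no land-use term), every nonempty subset
    as one summed variable, and (if allowed) every unordered pair of disjoint
    nonempty subsets as two variables.
    """
    cats = sorted(categories)
    singles = []
    for r in range(1, len(cats) + 1):
        singles.extend(frozenset(c) for c in itertools.combinations(cats, r))
    yield ()
    for s in singles:
        yield (s,)
    if max_lu_predictors >= 2:
        for a, b in itertools.combinations(singles, 2):
            if not a & b:
                yield tuple(sorted((a, b), key=lambda s: tuple(sorted(s))))


def _subset_sort_key(lu_subsets):
    """Lexicographic order on the category-index tuples of each subset."""
    order = {c: i for i, c in enumerate(LU_CATEGORIES)}
    return tuple(tuple(sorted(order.get(c, c) for c in s)) for s in lu_subsets)


def select_model(
    dataset: CalibrationDataset,
    max_lu_predictors: int = 2,
    bic_tol: float = 1e-6,
) -> FittedModel:
    """Exhaustive search over land-use predictor structures, by minimum BIC.

    Every nonempty subset of the aggregated categories forms one candidate
    summed percent-cover variable; with ``max_lu_predictors=2``, pairs of
    disjoint subsets are also considered. The fixed predictors (f_NANI,
    P_Annual, P_MAM,ext) appear in every candidate. Ties within ``bic_tol``
    are broken by fewer land-use predictors, then lexicographic subset order;
    rank-deficient candidates are skipped.
    """
    if len(dataset) == 0:
        raise InvalidInputError("empty calibration dataset")
    cats = dataset.lu_categories
    if not cats:
        raise InvalidInputError("dataset carries no land-use percent columns")
    n = len(dataset)
    base_X, y, _ = _design_matrix(dataset, ())
    candidates = []
    for lu_subsets in _candidate_lu_sets(cats, max_lu_predictors):
        if lu_subsets:
            lu_cols = np.column_stack([dataset.lu_percent(s) for s in lu_subsets])
            X = np.hstack([base_X, lu_cols])
        else:
            X = base_X
        if np.linalg.matrix_rank(X) < X.shape[1]:
            continue
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        k = X.shape[1]
        bic = n * np.log(rss / n) + k * np.log(n)
        candidates.append((bic, lu_subsets))
    if not candidates:
        raise DegenerateDesignError("no candidate model has a full-rank design")
    best_bic = min(b for b, _ in candidates)
    tied = [ls for b, ls in candidates if b - best_bic <= bic_tol]
    tied.sort(key=lambda ls: (len(ls), _subset_sort_key(ls)))
    winner = tied[0]
    return calibrate(dataset, winner) if winner else _fit_no_lu(dataset)


def _fit_no_lu(dataset: CalibrationDataset) -> FittedModel:
    """Fit with no land-use term (coef_lu reported as 0)."""
    X, y, names = _design_matrix(dataset, ())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("rank-deficient design")
    res = sm.OLS(y, X).fit()
    coeffs = ModelCoefficients(
        intercept=float(res.params[0]),
        coef_fnani=float(res.params[1]),
        coef_pannual=float(res.params[2]),
        coef_pext=float(res.params[3]),
        coef_lu=0.0,
    )
    return FittedModel(
        coefficients=coeffs,
        lu_subsets=(),
        lu_coefs=(),
        r_squared=float(res.rsquared),
        resid_sd=float(np.sqrt(res.mse_resid)),
        std_errors=dict(zip(names, (float(s) for s in res.bse))),
        bic=float(res.bic),
        n_obs=int(res.nobs),
    )
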