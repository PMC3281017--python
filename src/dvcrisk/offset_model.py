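"""Stage 1: the mandatory parametric Poisson model with log-road-length offset.

The collision count for municipality i, road type r, year t is modelled as

    count ~ Poisson(length * exp(b0 + road_r + year_t + road_r:year_t + red_i))

i.e. a log-linear Poisson model with the log of the road-type length as an
offset (coefficient fixed at one).  Dividing by length, exp(linear
predictor) is the expected number of collisions per kilometre for each
road-type x year stratum with or without red-deer presence.  These effects
are mandatory: they are estimated by maximum likelihood without any
selection or penalisation, and the fitted linear predictor plus log-length
becomes the fixed offset of the stage-2 additive model.

Treatment coding with the (residential, 2006, non-red) cell as reference;
with all five road types, both years and red-deer variation present this
gives 11 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SingularityError, ValidationError
from .synthetic import ROAD_TYPES, YEARS

REFERENCE_ROAD = "residential"
REFERENCE_YEAR = 2006


@dataclass
class ParametricFit:
    """Stage-1 maximum-likelihood fit.

    coefficients / covariance are indexed by term names; covariance is the
    inverse Fisher information.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    reference_levels: tuple = (REFERENCE_ROAD, REFERENCE_YEAR)

    @property
    def std_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.coefficients.index)

    def to_dict(self) -> dict:
        return {
            "term_order": list(self.coefficients.index),
            "coefficients": self.coefficients.to_dict(),
            "covariance": self.covariance.to_dict(),
            "log_likelihood": float(self.log_likelihood),
            "reference_levels": list(self.reference_levels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricFit":
        coef = pd.Series(d["coefficients"])
        if "term_order" in d:
            coef = coef.reindex(d["term_order"])
        cov = pd.DataFrame(d["covariance"]).loc[coef.index, coef.index]
        return cls(coef, cov, d["log_likelihood"], tuple(d["reference_levels"]))


def _design(collisions: pd.DataFrame):
    """Treatment-coded design from the levels present in the data.

    Terms for absent levels are dropped, and the reference level falls back
    to the first present one when the default reference is absent (a toy
    table with one road type and one year yields an intercept-only design).
    """
    roads_present = [rt for rt in ROAD_TYPES if (collisions["road_type"] == rt).any()]
    ref_road = REFERENCE_ROAD if REFERENCE_ROAD in roads_present else roads_present[0]
    roads = [rt for rt in roads_present if rt != ref_road]
    years_present = [y for y in YEARS if (collisions["year"] == y).any()]
    ref_year = REFERENCE_YEAR if REFERENCE_YEAR in years_present else years_present[0]
    years = [y for y in years_present if y != ref_year]
    red = collisions.get("red_deer")
    has_red = red is not None and red.any() and not red.all()

    cols = {"intercept": np.ones(len(collisions))}
    for rt in roads:
        cols[f"road[{rt}]"] = (collisions["road_type"] == rt).to_numpy(float)
    for y in years:
        cols[f"year[{y}]"] = (collisions["year"] == y).to_numpy(float)
    for rt in roads:
        for y in years:
            cols[f"road[{rt}]:year[{y}]"] = cols[f"road[{rt}]"] * cols[f"year[{y}]"]
    if has_red:
        cols["red_deer"] = collisions["red_deer"].to_numpy(float)
    return pd.DataFrame(cols, index=collisions.index)


def _check_strata(collisions: pd.DataFrame, X: pd.DataFrame):
    # every road-type x year stratum in the design must contain data
    for rt in collisions["road_type"].unique():
        for y in collisions["year"].unique():
            if not ((collisions["road_type"] == rt) & (collisions["year"] == y)).any():
                raise SingularityError(
                    f"stratum road_type={rt!r}, year={y} is empty; its coefficient is inestimable"
                )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise SingularityError("design matrix is rank deficient; a stratum coefficient is inestimable")


def validate_collisions(collisions: pd.DataFrame):
    required = {"muni_id", "road_type", "year", "count", "road_length"}
    missing = required - set(collisions.columns)
    if missing:
        raise ValidationError(f"collision table missing columns: {sorted(missing)}")
    if (collisions["count"] < 0).any():
        raise ValidationError("negative collision counts")
    if (collisions["road_length"] <= 0).any():
        raise ValidationError("collision rows must have road_length > 0")
    unknown = set(collisions["road_type"]) - set(ROAD_TYPES)
    if unknown:
        raise ValidationError(f"unknown road types: {sorted(unknown)}")


def poisson_glm(X: np.ndarray, y: np.ndarray, offset: np.ndarray):
    """Offset-Poisson GLM via IRLS; returns (beta, covariance, log-lik).

    Thin wrapper around statsmodels, shared by the stage-1 fit and used as
    the maximum-likelihood oracle in boosting convergence checks.
    """
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    res = model.fit(maxiter=100, tol=1e-10)
    return res.params, res.cov_params(), float(res.llf)


def fit_offset_glm(collisions: pd.DataFrame) -> ParametricFit:
    """Fit the mandatory stage-1 model by maximum likelihood."""
    validate_collisions(collisions)
    X = _design(collisions)
    _check_strata(collisions, X)
    y = collisions["count"].to_numpy(float)
    offset = np.log(collisions["road_length"].to_numpy(float))
    beta, cov, llf = poisson_glm(X.to_numpy(), y, offset)
    coef = pd.Series(np.asarray(beta), index=X.columns)
    covariance = pd.DataFrame(np.asarray(cov), index=X.columns, columns=X.columns)
    return ParametricFit(coef, covariance, llf)


def expected_dvc_per_km(fit: ParametricFit, road_type: str, year: int, red: bool = False) -> float:
    """Expected collisions per km per year for a stratum: exp(linear predictor)."""
    if road_type not in ROAD_TYPES:
        raise ValidationError(f"unknown road type {road_type!r}")
    if year not in YEARS:
        raise ValidationError(f"unknown year {year}")
    coef = fit.coefficients
    eta = coef["intercept"]
    if road_type != REFERENCE_ROAD:
        eta += coef.get(f"road[{road_type}]", 0.0)
        if year != REFERENCE_YEAR:
            eta += coef.get(f"road[{road_type}]:year[{year}]", 0.0)
    if year != REFERENCE_YEAR:
        eta += coef.get(f"year[{year}]", 0.0)
    if red:
        eta += coef.get("red_deer", 0.0)
    return float(np.exp(eta))


def stratum_rate_table(fit: ParametricFit) -> pd.DataFrame:
    """Expected DVCs per km for every road type x year x red-deer stratum."""
    rows = []
    for rt in ROAD_TYPES:
        for y in YEARS:
            for red in (False, True):
                rows.append(
                    {
                        "road_type": rt,
                        "year": y,
                        "red_deer": red,
                        "dvc_per_km": expected_dvc_per_km(fit, rt, y, red),
                    }
                )
    return pd.DataFrame(rows)


def stage1_offset(fit: ParametricFit, collisions: pd.DataFrame) -> np.ndarray:
    """Per-row offset for stage 2: log(length) + stage-1 linear predictor.

    exp(offset) is exactly the stage-1 fitted mean of each row.
    """
    X = _design(collisions)
    unknown = set(X.columns) - set(fit.coefficients.index)
    if unknown:
        raise ValidationError(f"levels unknown to the fit: {sorted(unknown)}")
    eta = X.to_numpy() @ fit.coefficients.reindex(X.columns).to_numpy()
    return np.log(collisions["road_length"].to_numpy(float)) + eta
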