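"""External validation of the DVC index against district harvest numbers.

The municipality-level index is averaged over game-management districts
(unweighted mean of the municipalities whose centroid lies in the
district), compared with harvest per 100 ha by Spearman's rank correlation,
and the trend is summarised by a robust LOWESS smoother.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ValidationError


def aggregate_index_by_district(index: pd.DataFrame, munis: pd.DataFrame) -> pd.Series:
    """Unweighted mean municipality index per district."""
    merged = index.merge(munis[["muni_id", "district_id"]], on="muni_id", how="left")
    if merged["district_id"].isna().any():
        raise ValidationError("municipalities without district assignment")
    empty = set(munis["district_id"]) - set(merged["district_id"])
    if empty:
        warnings.warn(f"districts without municipalities omitted: {sorted(empty)[:5]}")
    return merged.groupby("district_id", sort=True)["index"].mean().rename("mean_index")


def spearman_corr(x, y):
    """Spearman's rank correlation with midranks for ties.

    Returns (rho, p).  p is two-sided: exact by permutation for n <= 8,
    otherwise the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if len(y) != n or n < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        # exact permutation null: all orderings of y against fixed x
        rx_c = rx - rx.mean()
        sx = math.sqrt(float(rx_c @ rx_c))
        ry_c = ry - ry.mean()
        sy = math.sqrt(float(ry_c @ ry_c))
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rx_c @ ry_c[list(perm)]) / (sx * sy)
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        rho_ = min(max(rho, -1 + 1e-15), 1 - 1e-15)
        t = rho_ * math.sqrt((n - 2) / (1 - rho_ * rho_))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def lowess_fit(x, y, span: float = 2 / 3) -> pd.DataFrame:
    """Robust LOWESS trend: tricube-weighted local linear regression with
    3 bisquare robustness iterations, evaluated at the sorted unique x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 5:
        raise ValidationError("LOWESS needs at least 5 points")
    if not (0 < span <= 1):
        raise ValidationError("span must lie in (0, 1]")
    if span * n < 2:
        raise ValidationError(f"span {span} covers fewer than 2 points locally")
    fitted = _sm_lowess(y, x, frac=span, it=3, return_sorted=True)
    curve = pd.DataFrame(fitted, columns=["x", "fitted"]).groupby("x", as_index=False).mean()
    return curve


@dataclass
class ValidationResult:
    table: pd.DataFrame          # district_id, mean_index, harvest_per_100ha
    spearman_rho: float
    p_value: float
    lowess_curve: pd.DataFrame   # columns x, fitted; x strictly increasing


def validate_index(index: pd.DataFrame, munis: pd.DataFrame, harvest: pd.DataFrame,
                   span: float = 2 / 3) -> ValidationResult:
    """Full validation stage: aggregate, correlate, smooth."""
    means = aggregate_index_by_district(index, munis)
    table = means.reset_index().merge(harvest, on="district_id", how="inner")
    if table.empty:
        raise ValidationError("no districts shared between index and harvest tables")
    rho, p = spearman_corr(table["mean_index"], table["harvest_per_100ha"])
    curve = lowess_fit(table["mean_index"], table["harvest_per_100ha"], span=span)
    return ValidationResult(table=table, spearman_rho=rho, p_value=p, lowess_curve=curve)
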