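"""The DVC index: exp of the summed nonparametric model contributions.

The index is the multiplicative change in expected collisions per km for a
municipality relative to the stage-1 parametric baseline: an index of 0.5
means half, 2.0 twice the baseline expectation.  Owing to the multiplicative
structure on the exp scale it decomposes exactly into group factors
(climate x land use x browsing x space x spacetime x overdispersion); the
standard deviation of the log-factors across municipalities measures the
relative importance of each group.  Municipalities are assigned to risk
classes by one-dimensional k-means on the index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .boosting import BoostFit, predict_terms
from .errors import ConfigurationError, ValidationError

GROUP_ORDER = ("climate", "landuse", "browsing", "space", "spacetime", "overdispersion")


def _group_map(fit: BoostFit, grouping=None) -> dict:
    if grouping is None:
        grouping = {L.spec.name: L.spec.group for L in fit.learners}
    for L in fit.learners:
        if L.spec.name not in grouping:
            raise ConfigurationError(f"learner {L.spec.name!r} has no group assignment")
    return grouping


def compute_index(fit: BoostFit, munis: pd.DataFrame, year: int = 2006,
                  selected=None, include_overdispersion: bool = False,
                  include_spacetime: bool = False, grouping=None) -> pd.DataFrame:
    """Per-municipality DVC index and its multiplicative group factors.

    Only learners in ``selected`` (e.g. the stability-selection survivors;
    None = all) contribute.  Groups toggled off (spacetime, overdispersion
    by default -- the mapped index names climate, land use, browsing and
    spatial heterogeneity) are reported as factor 1, so the index always
    equals the product of the factor columns exactly.

    Overdispersion intercepts are observation-specific: with
    ``include_overdispersion`` the factor is exp of the mean training-row
    intercept of the municipality in ``year`` (1 for municipalities without
    training rows); for mapping it is off.
    """
    grouping = _group_map(fit, grouping)
    missing = [c for L in fit.learners for c in L.spec.covariates
               if (selected is None or L.spec.name in selected) and c not in munis.columns]
    if missing:
        raise ValidationError(f"municipality table lacks selected covariates: {sorted(set(missing))}")
    frame = munis.copy()
    frame["year"] = year
    terms = predict_terms(fit, frame)

    log_factors = pd.DataFrame(0.0, index=frame.index, columns=list(GROUP_ORDER))
    for name in terms.columns:
        if selected is not None and name not in selected:
            continue
        g = grouping[name]
        log_factors[g] += terms[name]
    if not include_spacetime:
        log_factors["spacetime"] = 0.0
    if include_overdispersion:
        log_factors["overdispersion"] = _muni_overdispersion(fit, frame, year)
    else:
        log_factors["overdispersion"] = 0.0

    out = pd.DataFrame({"muni_id": munis["muni_id"].to_numpy(), "year": year})
    for g in GROUP_ORDER:
        out[g] = np.exp(log_factors[g].to_numpy())
    out["index"] = np.exp(log_factors.to_numpy().sum(axis=1))
    return out


def _muni_overdispersion(fit: BoostFit, frame: pd.DataFrame, year: int) -> np.ndarray:
    od_cols = [j for j, L in enumerate(fit.learners) if L.is_random_intercept]
    if not od_cols or fit.train_meta is None:
        return np.zeros(len(frame))
    od = fit.train_contrib[:, od_cols].sum(axis=1)
    meta = fit.train_meta
    per_muni = (
        pd.DataFrame({"muni_id": meta["muni_id"].to_numpy(), "od": od})[meta["year"].to_numpy() == year]
        .groupby("muni_id")["od"].mean()
    )
    return frame["muni_id"].map(per_muni).fillna(0.0).to_numpy()


def decompose(fit: BoostFit, munis: pd.DataFrame, year: int = 2006,
              selected=None, grouping=None):
    """Group factor columns plus a variability summary per group.

    Returns ``(factors, variability)``: the per-municipality factor table
    for all groups (spacetime included, evaluated at ``year``) and the
    standard deviation of the log-factors across municipalities -- the
    group-importance measure.
    """
    grouping = _group_map(fit, grouping)
    frame = munis.copy()
    frame["year"] = year
    terms = predict_terms(fit, frame)
    log_factors = pd.DataFrame(0.0, index=frame.index, columns=list(GROUP_ORDER))
    for name in terms.columns:
        if selected is not None and name not in selected:
            continue
        log_factors[grouping[name]] += terms[name]
    factors = np.exp(log_factors)
    factors.insert(0, "muni_id", munis["muni_id"].to_numpy())
    variability = log_factors.std(axis=0, ddof=1)
    variability.name = "sd_log_factor"
    return factors, variability


def decompose_rows(fit: BoostFit) -> pd.DataFrame:
    """Per-training-row group factors, overdispersion included.

    Satisfies exp(offset) * product of factors = stage-2 fitted mean exactly.
    """
    grouping = _group_map(fit)
    log_factors = pd.DataFrame(0.0, index=np.arange(len(fit.train_index)), columns=list(GROUP_ORDER))
    for j, name in enumerate(fit.learner_names):
        log_factors[grouping[name]] += fit.train_contrib[:, j]
    return np.exp(log_factors)


@dataclass
class RiskClassification:
    labels: pd.Series        # muni_id -> class 1..k (ascending risk)
    centers: np.ndarray      # class means on the index scale, ascending
    boundaries: np.ndarray   # k-1 midpoints between adjacent class centers


def classify_risk(index: pd.DataFrame, k: int = 7, seed: int = 0, log_scale: bool = False) -> RiskClassification:
    """One-dimensional k-means risk classes on the index (20 restarts).

    Class labels are renumbered by ascending class mean, so class 1 is the
    lowest-risk class.
    """
    values = index["index"].to_numpy(float) if isinstance(index, pd.DataFrame) else np.asarray(index, float)
    ids = index["muni_id"].to_numpy() if isinstance(index, pd.DataFrame) else np.arange(len(values))
    if k < 2:
        raise ValidationError("k must be >= 2")
    if np.unique(values).size < k:
        raise ValidationError(f"k={k} exceeds the number of distinct index values")
    x = np.log(values) if log_scale else values
    km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(x[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[km.labels_], index=ids, name="risk_class")
    centers_x = np.sort(km.cluster_centers_.ravel())
    centers = np.exp(centers_x) if log_scale else centers_x
    boundaries = 0.5 * (centers[:-1] + centers[1:])
    return RiskClassification(labels=labels, centers=centers, boundaries=boundaries)
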