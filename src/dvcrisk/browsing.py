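"""Markov-random-field smoothing of browsing proportions over districts.

Sapling surveys report, per game-management district and palatability
class, how many of n examined saplings show leading-shoot browsing.  Some
district x class cells are missing (a genus absent from the district) or
rest on few trees, so the raw proportions are noisy.  We smooth them with
an intrinsic-CAR penalized binomial likelihood: with eta_d the district
log-odds, maximize

    sum_d [ y_d * eta_d - n_d * log(1 + exp(eta_d)) ]  -  (lambda/2) eta' K eta

where K is the Laplacian of the district adjacency graph, so the penalty is
the sum of squared differences of eta between neighbouring districts.  The
constant direction is unpenalized (K 1 = 0), which plays the role of the
overall intercept; districts without data borrow strength entirely from
their neighbours.  lambda is either fixed or calibrated by bisection so the
trace of the hat matrix equals a target effective df.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ValidationError
from .synthetic import BROWSING_CLASSES

_ETA_CAP = 25.0


@dataclass
class BrowsingEstimate:
    """Smoothed browsing proportions: districts x palatability classes."""

    proportions: pd.DataFrame     # index district_id, one column per class
    lambdas: dict                 # class -> smoothing parameter
    edf: dict                     # class -> effective degrees of freedom


def validate_survey(survey: pd.DataFrame):
    required = {"district_id", "palatability_class", "n_examined", "n_browsed"}
    missing = required - set(survey.columns)
    if missing:
        raise ValidationError(f"survey table missing columns: {sorted(missing)}")
    unknown = set(survey["palatability_class"]) - set(BROWSING_CLASSES)
    if unknown:
        raise ValidationError(f"unknown palatability classes: {sorted(unknown)}")
    if (survey["n_examined"] <= 0).any():
        raise ValidationError("n_examined must be positive")
    if ((survey["n_browsed"] < 0) | (survey["n_browsed"] > survey["n_examined"])).any():
        raise ValidationError("need 0 <= n_browsed <= n_examined")


def _penalized_fit(y, n, K, lam, tol=1e-8, max_iter=200):
    """Newton ascent of the ICAR-penalized binomial log-likelihood.

    y, n are per-district counts (n = 0 marks missing cells).  Returns
    (eta, edf); edf = trace((W + lam K)^-1 W) at convergence.
    """
    obs = n > 0
    pooled = np.clip(y[obs].sum() / n[obs].sum(), 1e-6, 1 - 1e-6)
    eta = np.full(len(n), logit(pooled))

    def objective(e):
        # log-lik in the eta parametrisation minus the quadratic penalty
        ll = np.sum(y[obs] * e[obs] - n[obs] * np.logaddexp(0.0, e[obs]))
        return ll - 0.5 * lam * float(e @ K @ e)

    obj = objective(eta)
    for _ in range(max_iter):
        p = expit(eta)
        w = n * p * (1 - p)
        score = (y - n * p) - lam * (K @ eta)
        H = np.diag(w) + lam * K
        if lam == 0 and not obs.all():
            raise ValidationError("lambda = 0 cannot estimate districts without data")
        H = H + 1e-12 * np.eye(len(n))
        step = np.linalg.solve(H, score)
        # step-halving keeps the penalized likelihood non-decreasing
        t = 1.0
        for _ in range(40):
            cand = np.clip(eta + t * step, -_ETA_CAP, _ETA_CAP)
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            t *= 0.5
        new_eta = np.clip(eta + t * step, -_ETA_CAP, _ETA_CAP)
        new_obj = objective(new_eta)
        done = abs(new_obj - obj) < tol
        eta, obj = new_eta, new_obj
        if done:
            break
    p = expit(eta)
    w = n * p * (1 - p)
    H = np.diag(w) + lam * K + 1e-12 * np.eye(len(n))
    edf = float(np.trace(np.linalg.solve(H, np.diag(w))))
    return eta, edf


def fit_mrf_binomial(survey: pd.DataFrame, graph: nx.Graph, lam: float = None,
                     target_df: float = None) -> BrowsingEstimate:
    """Fit the MRF smoother per palatability class.

    Exactly one of ``lam`` (fixed smoothing parameter) or ``target_df``
    should be given; when both are None, target_df defaults to
    n_districts / 4.
    """
    validate_survey(survey)
    districts = sorted(graph.nodes)
    missing_d = set(survey["district_id"]) - set(districts)
    if missing_d:
        raise ValidationError(f"survey districts not in graph: {sorted(missing_d)[:5]}")
    nd = len(districts)
    if lam is None and target_df is None:
        target_df = nd / 4
    if target_df is not None and not (1 <= target_df <= nd):
        raise ValidationError("target_df must lie in [1, n_districts]")
    K = nx.laplacian_matrix(graph, nodelist=districts).toarray().astype(float)
    pos = {d: i for i, d in enumerate(districts)}

    props, lambdas, edfs = {}, {}, {}
    for cls in BROWSING_CLASSES:
        sub = survey[survey["palatability_class"] == cls]
        if sub.empty:
            continue
        y = np.zeros(nd)
        n = np.zeros(nd)
        for _, r in sub.iterrows():
            i = pos[r["district_id"]]
            y[i] += r["n_browsed"]
            n[i] += r["n_examined"]
        _check_component_coverage(graph, districts, n, cls)
        if lam is not None:
            lam_c = float(lam)
            eta, edf = _penalized_fit(y, n, K, lam_c)
        else:
            lam_c, eta, edf = _calibrate_df(y, n, K, target_df)
        props[cls] = expit(eta)
        lambdas[cls] = lam_c
        edfs[cls] = edf
    proportions = pd.DataFrame(props, index=pd.Index(districts, name="district_id"))
    return BrowsingEstimate(proportions=proportions, lambdas=lambdas, edf=edfs)


def _check_component_coverage(graph, districts, n, cls):
    has_data = {d for d, ni in zip(districts, n) if ni > 0}
    for comp in nx.connected_components(graph):
        if not (comp & has_data):
            raise ValidationError(
                f"class {cls!r}: graph component {sorted(comp)[:3]}... has no survey data"
            )


def _calibrate_df(y, n, K, target_df):
    """Bisection on log10(lambda) for trace(hat) = target_df."""
    lo, hi = -8.0, 10.0

    def edf_at(loglam):
        lam = 10.0 ** loglam
        return _penalized_fit(y, n, K, lam)

    eta_lo, edf_lo = edf_at(lo)
    if edf_lo <= target_df:
        return 10.0 ** lo, eta_lo, edf_lo
    eta_hi, edf_hi = edf_at(hi)
    if edf_hi >= target_df:
        return 10.0 ** hi, eta_hi, edf_hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        eta, edf = edf_at(mid)
        if abs(edf - target_df) < 1e-4 or hi - lo < 1e-10:
            return 10.0 ** mid, eta, edf
        if edf > target_df:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    eta, edf = edf_at(mid)
    return 10.0 ** mid, eta, edf


def extract_at_centroids(estimate: BrowsingEstimate, munis: pd.DataFrame) -> pd.DataFrame:
    """Per-municipality browsing covariates from the smoothed district map.

    In the grid world a municipality centroid falls in its own district, so
    extraction is district lookup.  Columns follow the fixed class order.
    """
    unknown = set(munis["district_id"]) - set(estimate.proportions.index)
    if unknown:
        raise ValidationError(f"districts without browsing estimate: {sorted(unknown)[:5]}")
    out = pd.DataFrame({"muni_id": munis["muni_id"].to_numpy()})
    for cls in BROWSING_CLASSES:
        if cls not in estimate.proportions.columns:
            raise ValidationError(f"no estimate for class {cls!r}")
        out[f"browsing_{cls}"] = munis["district_id"].map(estimate.proportions[cls]).to_numpy()
    return out
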