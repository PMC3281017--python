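"""Stage 2: component-wise functional gradient boosting of the additive
Poisson model on the fixed stage-1 offset.

Starting from the linear predictor F = offset, each iteration computes the
negative Poisson gradient u_i = y_i - exp(F_i), fits every base-learner to
u by penalized least squares, selects the learner with the smallest
penalized residual sum of squares (ties broken by learner order), and
updates F by a step-length nu times its fitted values.  The aggregated
per-learner coefficient increments form the nonparametric model part.

The number of iterations (mstop) -- the main complexity parameter -- is
chosen by out-of-bootstrap risk: for each bootstrap resample the model is
refitted and the negative Poisson log-likelihood is evaluated on the rows
left out of the resample along a grid of iteration counts.  Variable
selection is by stability selection: the fit is repeated on half-samples of
the municipalities and a learner is kept when its selection frequency
exceeds a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BaseLearnerSpec, BuiltLearner, build_learners
from .errors import DivergenceError, ValidationError


def make_model_frame(collisions: pd.DataFrame, munis: pd.DataFrame) -> pd.DataFrame:
    """Merge collision rows with municipality covariates and centroids."""
    merged = collisions.merge(munis.drop(columns=["red_deer"], errors="ignore"), on="muni_id", how="left", validate="many_to_one")
    if merged["centroid_x"].isna().any():
        missing = merged.loc[merged["centroid_x"].isna(), "muni_id"].unique()
        raise ValidationError(f"municipalities missing from the table: {list(missing)[:5]}")
    return merged


@dataclass
class BoostFit:
    """The fitted stage-2 ensemble."""

    learners: list
    nu: float
    mstop: int
    selection_path: list
    coefs: list                      # aggregated coefficients per learner
    offset: np.ndarray               # per-row offset used during training
    train_linpred: np.ndarray        # F after mstop iterations
    train_contrib: np.ndarray        # (n_rows, n_learners) per-learner contributions
    train_index: np.ndarray          # positions (into the training frame) that were fitted
    train_meta: pd.DataFrame = None  # muni_id / year of the training rows, when available
    train_risk_path: np.ndarray = None   # in-sample mean negative log-lik per iteration
    centering: np.ndarray = field(default=None)  # training mean of each learner's contribution

    def __post_init__(self):
        if self.centering is None:
            self.centering = self.train_contrib.mean(axis=0) if len(self.train_index) else np.zeros(len(self.learners))

    @property
    def learner_names(self):
        return [L.spec.name for L in self.learners]

    def learner(self, name: str) -> BuiltLearner:
        for L in self.learners:
            if L.spec.name == name:
                return L
        raise ValidationError(f"no base-learner named {name!r} in fit")

    def _coef(self, name: str) -> np.ndarray:
        return self.coefs[self.learner_names.index(name)]


def _check_gradient(mu):
    if not np.all(np.isfinite(mu)):
        raise DivergenceError(
            "non-finite Poisson mean during boosting (exp overflow); use a smaller step length nu"
        )


def _poisson_risk(y, F):
    """Mean negative Poisson log-likelihood (dropping the log y! constant)."""
    return float(np.mean(np.exp(F) - y * F))


def _boost(learners, y, offset, idx, nu, mstop, oob_idx=None, grid=None,
           stop_at_distinct=None):
    """Core boosting loop on rows ``idx``.

    Returns (coefs, path, F, contrib) and, when ``oob_idx``/``grid`` are
    given, the out-of-bootstrap risk evaluated at each grid point.
    """
    idx = np.asarray(idx)
    y_in = y[idx]
    F = offset[idx].astype(float).copy()
    solvers = [L.solver(idx) for L in learners]
    coefs = [None] * len(learners)
    contrib = np.zeros((len(idx), len(learners)))
    path = []
    risk_path = []

    track_oob = oob_idx is not None
    if track_oob:
        oob_idx = np.asarray(oob_idx)
        y_out = y[oob_idx]
        F_out = offset[oob_idx].astype(float).copy()
        X_out = [None if L.is_random_intercept else L.X[oob_idx] for L in learners]
        risks = {}
        if 0 in grid:
            risks[0] = _poisson_risk(y_out, F_out)

    risk_cur = _poisson_risk(y_in, F)
    for m in range(1, mstop + 1):
        mu = np.exp(F)
        _check_gradient(mu)
        u = y_in - mu
        uu = float(u @ u)
        best, best_crit, best_coef = None, np.inf, None
        for j, s in enumerate(solvers):
            coef, crit = s.probe(u, uu)
            if crit < best_crit - 1e-12:
                best, best_crit, best_coef = j, crit, coef
        best_fit = solvers[best].fitted(best_coef)
        # safeguarded step: the count-scale gradient can overshoot the
        # log-scale predictor where the Poisson mean is large, so halve the
        # step until the in-sample risk is non-increasing
        t = 1.0
        for _ in range(30):
            risk_new = _poisson_risk(y_in, F + nu * t * best_fit)
            if np.isfinite(risk_new) and risk_new <= risk_cur + 1e-12:
                break
            t *= 0.5
        F += nu * t * best_fit
        risk_cur = _poisson_risk(y_in, F)
        risk_path.append(risk_cur)
        contrib[:, best] += nu * t * best_fit
        if coefs[best] is None:
            coefs[best] = nu * t * best_coef
        else:
            coefs[best] = coefs[best] + nu * t * best_coef
        path.append(best)
        if stop_at_distinct is not None and len(set(path)) >= stop_at_distinct:
            break
        if track_oob:
            L = learners[best]
            if not L.is_random_intercept:
                F_out += nu * t * (X_out[best] @ best_coef)
            if m in grid:
                risks[m] = _poisson_risk(y_out, F_out)

    for j, L in enumerate(learners):
        if coefs[j] is None:
            p = 0 if L.is_random_intercept else L.X.shape[1]
            coefs[j] = np.zeros(len(idx) if L.is_random_intercept else p)
    if track_oob:
        return coefs, path, F, contrib, risks
    return coefs, path, F, contrib, np.asarray(risk_path)


def fit_boost(data: pd.DataFrame, offset: np.ndarray, specs, nu: float = 0.1,
              mstop: int = 100, learners=None, subset=None) -> BoostFit:
    """Fit the boosting ensemble for a fixed number of iterations.

    ``learners`` may carry pre-built designs (reused across refits);
    ``subset`` restricts fitting to a subset of row positions.
    """
    if mstop < 0:
        raise ValidationError("mstop must be >= 0")
    if not (0 < nu <= 1):
        raise ValidationError("step length nu must lie in (0, 1]")
    if learners is None:
        learners = build_learners(specs, data)
    idx = np.arange(len(data)) if subset is None else np.asarray(subset)
    y = data["count"].to_numpy(float)
    coefs, path, F, contrib, risk_path = _boost(learners, y, np.asarray(offset, float), idx, nu, mstop)
    meta_cols = [c for c in ("muni_id", "year") if c in data.columns]
    meta = data.iloc[idx][meta_cols].reset_index(drop=True) if len(meta_cols) == 2 else None
    return BoostFit(
        learners=learners, nu=nu, mstop=mstop, selection_path=path, coefs=coefs,
        offset=np.asarray(offset, float)[idx], train_linpred=F, train_contrib=contrib,
        train_index=idx, train_meta=meta, train_risk_path=risk_path,
    )


# ---------------------------------------------------------------------------
# prediction

def predict_terms(fit: BoostFit, data: pd.DataFrame) -> pd.DataFrame:
    """Uncentered per-learner contributions for new rows (link scale).

    Random intercepts contribute 0 for rows other than the training rows;
    the 2009-only surface contributes 0 for 2006 rows (through its design).
    """
    out = {}
    for L, coef in zip(fit.learners, fit.coefs):
        if L.is_random_intercept:
            out[L.spec.name] = np.zeros(len(data))
        else:
            out[L.spec.name] = L.design_new(data) @ coef
    return pd.DataFrame(out, index=data.index)


def predict_partial(fit: BoostFit, learner_name: str, values, scale: str = "link"):
    """Centered partial contribution of one learner at the supplied values.

    ``values``: 1-d array for univariate learners, or a DataFrame carrying
    the learner's covariates (and ``year`` for the 2009-only surface).
    Values outside the training range are clamped to the boundary knots
    (with a warning).  ``scale='response'`` returns exp of the centered
    contribution (the multiplicative change in expected DVCs per km).
    """
    L = fit.learner(learner_name)
    coef = fit._coef(learner_name)
    c = fit.centering[fit.learner_names.index(learner_name)]
    if L.is_random_intercept:
        raise ValidationError("random-intercept learners have no partial function for new data")
    if isinstance(values, pd.DataFrame):
        frame = values
    else:
        frame = pd.DataFrame({L.spec.covariates[0]: np.asarray(values, float)})
    g = L.design_new(frame) @ coef - c
    return np.exp(g) if scale == "response" else g


def predict_linpred(fit: BoostFit, data: pd.DataFrame, offset: np.ndarray) -> np.ndarray:
    """offset + sum of structural learner contributions for new rows."""
    return np.asarray(offset, float) + predict_terms(fit, data).to_numpy().sum(axis=1)


# ---------------------------------------------------------------------------
# out-of-bootstrap selection of mstop

@dataclass
class OOBResult:
    grid: np.ndarray
    risk_matrix: np.ndarray          # (n_boot, len(grid)) mean OOB negative log-lik
    selected_mstop: int

    @property
    def mean_risk(self):
        return self.risk_matrix.mean(axis=0)


def select_mstop_oob(data: pd.DataFrame, offset: np.ndarray, specs, nu: float = 0.1,
                     grid=None, n_boot: int = 25, seed: int = 0, learners=None) -> OOBResult:
    """Choose mstop by minimal mean out-of-bootstrap Poisson risk.

    Each replicate resamples rows with replacement, refits the full boosting
    path (knots and ridge amounts kept from the full-data designs) and
    evaluates the mean negative Poisson log-likelihood on the rows that did
    not enter the resample, at every grid point.
    """
    if grid is None:
        grid = np.arange(0, 1501, 25)
    grid = np.asarray(sorted(set(int(g) for g in grid)))
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if learners is None:
        learners = build_learners(specs, data)
    rng = np.random.default_rng(seed)
    n = len(data)
    y = data["count"].to_numpy(float)
    offset = np.asarray(offset, float)
    rows = []
    for b in range(n_boot):
        bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), bag)
        if oob.size == 0:
            warnings.warn(f"bootstrap replicate {b}: empty out-of-bootstrap set; skipped")
            continue
        *_, risks = _boost(learners, y, offset, bag, nu, int(grid.max()), oob_idx=oob, grid=set(grid.tolist()))
        rows.append([risks[g] for g in grid])
    risk_matrix = np.asarray(rows)
    selected = int(grid[int(np.argmin(risk_matrix.mean(axis=0)))])
    return OOBResult(grid=grid, risk_matrix=risk_matrix, selected_mstop=selected)


# ---------------------------------------------------------------------------
# stability selection

@dataclass
class StabilityResult:
    selection_frequency: pd.Series   # per learner name, in [0, 1]
    n_subsamples: int
    threshold: float

    @property
    def selected(self):
        return set(self.selection_frequency.index[self.selection_frequency > self.threshold])


def stability_select(data: pd.DataFrame, offset: np.ndarray, specs, nu: float = 0.1,
                     m_iter: int = 100, n_subsamples: int = 50, threshold: float = 0.5,
                     seed: int = 0, learners=None, q: int = None) -> StabilityResult:
    """Selection frequencies over half-samples of the municipalities.

    Each replicate draws floor(n_muni/2) municipalities without replacement,
    keeps all their rows and runs boosting for up to ``m_iter`` iterations.
    With ``q`` given (recommended), a replicate stops as soon as q distinct
    base-learners have entered the path and exactly those count as selected
    -- the sparse per-replicate selection event stability selection relies
    on; with ``q=None`` every learner chosen in at least one of the m_iter
    iterations counts, which is only discriminative for small m_iter.
    """
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must lie in (0, 1]")
    if n_subsamples < 2:
        raise ValidationError("n_subsamples must be >= 2")
    if learners is None:
        learners = build_learners(specs, data)
    rng = np.random.default_rng(seed)
    munis = np.sort(data["muni_id"].unique())
    y = data["count"].to_numpy(float)
    offset = np.asarray(offset, float)
    names = [L.spec.name for L in learners]
    counts = np.zeros(len(learners))
    for _ in range(n_subsamples):
        half = rng.choice(munis, size=len(munis) // 2, replace=False)
        idx = np.flatnonzero(data["muni_id"].isin(half).to_numpy())
        if m_iter == 0 or nu == 0:
            continue
        _, path, _, _, _ = _boost(learners, y, offset, idx, nu, m_iter, stop_at_distinct=q)
        for j in set(path):
            counts[j] += 1
    freq = pd.Series(counts / n_subsamples, index=names)
    return StabilityResult(selection_frequency=freq, n_subsamples=n_subsamples, threshold=threshold)
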