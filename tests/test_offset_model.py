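"""Stage-1 offset GLM: closed forms, brute-force likelihood oracle,
score equations, and simulation-based coverage."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import dvcrisk as d
from dvcrisk.errors import SingularityError, ValidationError
from dvcrisk.offset_model import _design

from conftest import toy_collisions

SINGLE_STRATUM = [
    ("A", "residential", 2006, 3, 1.0),
    ("B", "residential", 2006, 5, 3.0),
]

SIX_ROW = [
    ("A", "residential", 2006, 3, 1.0),
    ("B", "residential", 2009, 5, 2.0),
    ("C", "secondary", 2006, 7, 1.5),
    ("D", "secondary", 2009, 11, 2.5),
    ("E", "residential", 2006, 2, 1.2),
    ("F", "secondary", 2009, 4, 0.8),
]


def brute_force_mle(collisions):
    """Independent oracle: numeric maximization of the Poisson log-likelihood
    with offset log(length), from several starting points."""
    X = _design(collisions).to_numpy()
    y = collisions["count"].to_numpy(float)
    off = np.log(collisions["road_length"].to_numpy(float))

    def nll(beta):
        eta = off + X @ beta
        return np.sum(np.exp(eta) - y * eta)

    best = None
    for start in (np.zeros(X.shape[1]), np.full(X.shape[1], 0.5), np.full(X.shape[1], -0.5)):
        res = optimize.minimize(nll, start, method="Newton-CG",
                                jac=lambda b: X.T @ (np.exp(off + X @ b) - y),
                                hess=lambda b: X.T @ (np.exp(off + X @ b)[:, None] * X),
                                options={"xtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def test_single_stratum_rate_is_count_over_length():
    coll = toy_collisions(SINGLE_STRATUM)
    fit = d.fit_offset_glm(coll)
    assert fit.coefficients.index.tolist() == ["intercept"]
    assert np.exp(fit.coefficients["intercept"]) == pytest.approx(2.0, abs=1e-10)
    assert d.expected_dvc_per_km(fit, "residential", 2006) == pytest.approx(2.0, abs=1e-10)


def test_six_row_toy_matches_brute_force_oracle():
    coll = toy_collisions(SIX_ROW)
    fit = d.fit_offset_glm(coll)
    oracle = brute_force_mle(coll)
    assert np.abs(fit.coefficients.to_numpy() - oracle).max() < 1e-6
    # score equations vanish at the MLE
    X = _design(coll).to_numpy()
    mu = np.exp(d.stage1_offset(fit, coll))
    score = X.T @ (coll["count"].to_numpy() - mu)
    assert np.abs(score).max() < 1e-6
    # stratum totals reproduced (full-interaction Poisson GLM)
    coll2 = coll.assign(mu=mu)
    for (_, _), g in coll2.groupby(["road_type", "year"]):
        assert g["mu"].sum() == pytest.approx(g["count"].sum(), abs=1e-8)


def test_offsets_match_hand_computation():
    coll = toy_collisions(SINGLE_STRATUM)
    fit = d.fit_offset_glm(coll)
    b0 = fit.coefficients["intercept"]
    off = d.stage1_offset(fit, coll)
    np.testing.assert_allclose(off, b0 + np.log([1.0, 3.0]), atol=1e-12)
    # exp(offset) is the stage-1 fitted mean
    assert np.exp(off).sum() == pytest.approx(coll["count"].sum(), abs=1e-8)


def test_rate_structure_of_constructed_fits():
    names = ["intercept", "road[secondary]", "year[2009]", "red_deer"]
    zero = d.ParametricFit(pd.Series(0.0, index=names), pd.DataFrame(np.eye(4), index=names, columns=names), 0.0)
    for rt in d.ROAD_TYPES:
        for yr in d.YEARS:
            assert d.expected_dvc_per_km(zero, rt, yr) == 1.0
    half = d.ParametricFit(pd.Series([0.0, 0.0, 0.0, np.log(0.5)], index=names),
                           pd.DataFrame(np.eye(4), index=names, columns=names), 0.0)
    assert d.expected_dvc_per_km(half, "secondary", 2006, red=True) == pytest.approx(
        0.5 * d.expected_dvc_per_km(half, "secondary", 2006, red=False))


def test_full_design_has_eleven_parameters(small_world):
    fit = d.fit_offset_glm(small_world["collisions"])
    assert len(fit.coefficients) == 11
    cov = fit.covariance.to_numpy()
    assert np.abs(cov - cov.T).max() < 1e-10
    assert np.isfinite(fit.log_likelihood)


def test_coefficient_coverage_under_true_model():
    """Each coefficient within 3 reported SE of truth in >= 95% of replicates."""
    base = d.LandscapeConfig(
        grid_rows=10, grid_cols=10, district_block=5, seed=0,
        true_effects=(), overdispersion_sd=0.0, spatial_amplitude=0.0,
    )
    munis, _ = d.generate_landscape(base)
    hits = None
    n_rep = 200
    for r in range(n_rep):
        cfg = base.with_(seed=5000 + r)
        coll, _ = d.simulate_collisions(munis, cfg)
        fit = d.fit_offset_glm(coll)
        tr = pd.Series({k: cfg.true_beta[k] for k in fit.coefficients.index})
        ok = (np.abs(fit.coefficients - tr) <= 3 * fit.std_errors)
        hits = ok.astype(int) if hits is None else hits + ok.astype(int)
    assert (hits / n_rep >= 0.95).all(), hits / n_rep


def test_validation_errors():
    with pytest.raises(ValidationError):
        d.fit_offset_glm(toy_collisions([("A", "residential", 2006, -1, 1.0)]))
    with pytest.raises(ValidationError):
        d.fit_offset_glm(pd.DataFrame({
            "muni_id": ["A"], "road_type": ["residential"], "year": [2006],
            "count": [1], "road_length": [0.0]}))
    # stratum present for one year only -> inestimable interaction
    with pytest.raises(SingularityError):
        d.fit_offset_glm(toy_collisions([
            ("A", "motorway", 2006, 1, 1.0),
            ("B", "residential", 2006, 1, 1.0),
            ("C", "residential", 2009, 1, 1.0),
        ]))
    fit = d.fit_offset_glm(toy_collisions(SINGLE_STRATUM))
    with pytest.raises(ValidationError):
        d.expected_dvc_per_km(fit, "dirt_track", 2006)
    with pytest.raises(ValidationError):
        d.expected_dvc_per_km(fit, "residential", 2012)


def test_coverage_uses_true_generator_beta():
    """Generator's stage-1 truth is recovered on a larger sample (sanity of
    the simulation-estimation loop, not a distributional test)."""
    cfg = d.LandscapeConfig(grid_rows=16, grid_cols=16, district_block=4, seed=99,
                            true_effects=(), overdispersion_sd=0.0, spatial_amplitude=0.0)
    munis, _ = d.generate_landscape(cfg)
    coll, _ = d.simulate_collisions(munis, cfg)
    fit = d.fit_offset_glm(coll)
    tr = pd.Series({k: cfg.true_beta[k] for k in fit.coefficients.index})
    assert (np.abs(fit.coefficients - tr) <= 4 * fit.std_errors).all()
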