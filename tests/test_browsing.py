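"""MRF browsing smoother: limiting cases, borrowing across the graph,
penalized-likelihood behavior, centroid extraction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import dvcrisk as d
from dvcrisk.errors import ValidationError


@pytest.fixture(scope="module")
def survey_world():
    cfg = d.LandscapeConfig(grid_rows=12, grid_cols=12, district_block=2, seed=21,
                            survey_missing_frac=0.0)
    munis, graph = d.generate_landscape(cfg)
    survey, truth = d.simulate_browsing_survey(graph, cfg)
    return cfg, munis, graph, survey, truth


def empirical(survey):
    piv_b = survey.pivot(index="district_id", columns="palatability_class", values="n_browsed")
    piv_n = survey.pivot(index="district_id", columns="palatability_class", values="n_examined")
    return piv_b / piv_n


def test_lambda_zero_reproduces_empirical_proportions(survey_world):
    *_, graph, survey, _ = survey_world
    est = d.fit_mrf_binomial(survey, graph, lam=0.0)
    emp = empirical(survey)
    # interior cells (neither 0 nor n browsed)
    for cls in est.proportions.columns:
        mask = (emp[cls] > 0) & (emp[cls] < 1)
        assert np.abs(est.proportions.loc[mask, cls] - emp.loc[mask, cls]).max() < 1e-8


def test_infinite_smoothing_collapses_to_pooled(survey_world):
    *_, graph, survey, _ = survey_world
    est = d.fit_mrf_binomial(survey, graph, lam=1e8)
    pooled = survey.groupby("palatability_class").apply(
        lambda s: s["n_browsed"].sum() / s["n_examined"].sum(), include_groups=False)
    for cls in est.proportions.columns:
        assert np.abs(est.proportions[cls] - pooled[cls]).max() < 1e-4


def test_estimates_bounded_and_missing_districts_borrowed():
    cfg = d.LandscapeConfig(grid_rows=12, grid_cols=12, district_block=2, seed=22,
                            survey_missing_frac=0.3)
    _, graph = d.generate_landscape(cfg)
    survey, _ = d.simulate_browsing_survey(graph, cfg)
    est = d.fit_mrf_binomial(survey, graph)
    assert est.proportions.shape[0] == graph.number_of_nodes()
    assert ((est.proportions > 0) & (est.proportions < 1)).all().all()
    observed = set(survey.loc[survey["palatability_class"] == "oak_fir", "district_id"])
    missing = [dd for dd in graph.nodes if dd not in observed]
    assert missing  # some district really is unobserved for this class
    assert est.proportions.loc[missing, "oak_fir"].notna().all()


def test_monotone_in_data(survey_world):
    *_, graph, survey, _ = survey_world
    lam = 5.0
    est1 = d.fit_mrf_binomial(survey, graph, lam=lam)
    bumped = survey.copy()
    target = bumped.index[bumped["palatability_class"] == "oak_fir"][0]
    dist = bumped.loc[target, "district_id"]
    bumped.loc[target, "n_browsed"] = min(
        bumped.loc[target, "n_browsed"] + 20, bumped.loc[target, "n_examined"])
    est2 = d.fit_mrf_binomial(bumped, graph, lam=lam)
    assert est2.proportions.loc[dist, "oak_fir"] >= est1.proportions.loc[dist, "oak_fir"] - 1e-10


def test_target_df_calibration(survey_world):
    *_, graph, survey, _ = survey_world
    est = d.fit_mrf_binomial(survey, graph, target_df=10.0)
    for cls, edf in est.edf.items():
        assert edf == pytest.approx(10.0, abs=0.01), cls


def test_smoothing_beats_raw_logits():
    """At transect-scale counts, MRF smoothing dominates the raw empirical
    logits in total squared error against the generator's truth."""
    cfg = d.LandscapeConfig(grid_rows=12, grid_cols=12, district_block=2)
    err_s = err_r = 0.0
    for r in range(30):
        c = cfg.with_(seed=3000 + r)
        _, graph = d.generate_landscape(c)
        survey, truth = d.simulate_browsing_survey(graph, c)
        est = d.fit_mrf_binomial(survey, graph)
        tl = truth.pivot(index="district_id", columns="palatability_class", values="true_logit")
        sm = np.log(est.proportions / (1 - est.proportions))
        nb = survey.pivot(index="district_id", columns="palatability_class", values="n_browsed")
        ne = survey.pivot(index="district_id", columns="palatability_class", values="n_examined")
        raw = np.log((nb + 0.5) / (ne - nb + 0.5))
        for cls in sm.columns:
            mask = raw[cls].notna()
            err_s += float(((sm[cls][mask] - tl[cls][mask]) ** 2).sum())
            err_r += float(((raw[cls][mask] - tl[cls][mask]) ** 2).sum())
    assert err_s < err_r


def test_survey_validation_errors(survey_world):
    *_, graph, survey, _ = survey_world
    bad = survey.copy()
    bad.loc[bad.index[0], "n_browsed"] = bad.loc[bad.index[0], "n_examined"] + 1
    with pytest.raises(ValidationError):
        d.fit_mrf_binomial(bad, graph)
    with pytest.raises(ValidationError):
        d.fit_mrf_binomial(survey, graph, target_df=0.5)
    # a disconnected component with no data for a class is an error
    g2 = nx.Graph()
    g2.add_edges_from([("D1", "D2"), ("D3", "D4")])
    sv = pd.DataFrame({
        "district_id": ["D1", "D2"],
        "palatability_class": ["oak_fir", "oak_fir"],
        "n_examined": [75, 75], "n_browsed": [10, 20],
    })
    with pytest.raises(ValidationError, match="component"):
        d.fit_mrf_binomial(sv, g2, lam=1.0)


def test_extract_at_centroids(survey_world):
    _, munis, graph, survey, _ = survey_world
    est = d.fit_mrf_binomial(survey, graph)
    cov = d.extract_at_centroids(est, munis)
    assert cov.columns.tolist() == ["muni_id"] + list(d.BROWSING_VARS)
    merged = cov.merge(munis[["muni_id", "district_id"]], on="muni_id")
    for cls in d.BROWSING_CLASSES:
        # all municipalities of a district share the district estimate
        per_d = merged.groupby("district_id")[f"browsing_{cls}"].nunique()
        assert (per_d == 1).all()
        # re-aggregation by district reproduces the estimates exactly
        back = merged.groupby("district_id")[f"browsing_{cls}"].first()
        np.testing.assert_allclose(back.sort_index(), est.proportions[cls].sort_index(), atol=0)
    with pytest.raises(ValidationError):
        other = munis.copy()
        other.loc[other.index[0], "district_id"] = "D999"
        d.extract_at_centroids(est, other)
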