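"""Generator properties: determinism, structure, spatial autocorrelation,
and agreement of simulated moments with their specified distributions."""

import numpy as np
import pandas as pd
import pytest

import dvcrisk as d
from dvcrisk.errors import ConfigurationError


def moran_i(grid_values):
    """Moran's I on a full grid with rook weights (no normalisation fuss)."""
    z = grid_values - grid_values.mean()
    num = 0.0
    w = 0
    R, C = z.shape
    for dr, dc in ((0, 1), (1, 0)):
        a = z[: R - dr, : C - dc]
        b = z[dr:, dc:]
        num += 2 * np.sum(a * b)
        w += 2 * a.size
    return (z.size / w) * num / np.sum(z * z)


def test_generator_is_deterministic():
    cfg = d.LandscapeConfig(grid_rows=8, grid_cols=8, district_block=4, seed=7)
    out1 = d.generate_landscape(cfg)
    out2 = d.generate_landscape(cfg)
    pd.testing.assert_frame_equal(out1[0], out2[0])
    assert sorted(out1[1].edges) == sorted(out2[1].edges)
    c1, t1 = d.simulate_collisions(out1[0], cfg)
    c2, t2 = d.simulate_collisions(out2[0], cfg)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(t1, t2)
    s1, _ = d.simulate_browsing_survey(out1[1], cfg)
    s2, _ = d.simulate_browsing_survey(out2[1], cfg)
    pd.testing.assert_frame_equal(s1, s2)
    idx = d.true_dvc_index(out1[0], cfg)
    h1 = d.simulate_harvest(out1[0], idx, cfg)
    h2 = d.simulate_harvest(out2[0], idx, cfg)
    pd.testing.assert_frame_equal(h1, h2)


def test_minimal_grid_single_district():
    cfg = d.LandscapeConfig(grid_rows=2, grid_cols=2, district_block=2, seed=1)
    munis, graph = d.generate_landscape(cfg)
    assert len(munis) == 4
    assert munis["district_id"].nunique() == 1
    assert graph.number_of_nodes() == 1 and graph.number_of_edges() == 0


@pytest.mark.parametrize("bad", [
    dict(grid_rows=1),
    dict(district_block=3),          # does not divide 8
    dict(p_no_road=1.2),
    dict(true_effects=(("nope", "sin", 1.0),)),
    dict(true_effects=(("bio1", "wiggle", 1.0),)),
])
def test_invalid_config_rejected(bad):
    kwargs = {"grid_rows": 8, "grid_cols": 8, "district_block": 4, **bad}
    with pytest.raises(ConfigurationError):
        d.LandscapeConfig(**kwargs)


def test_covariates_spatially_autocorrelated():
    cfg = d.LandscapeConfig(grid_rows=16, grid_cols=16, district_block=4, seed=3)
    munis, _ = d.generate_landscape(cfg)
    for name in d.COVARIATES[:6] + d.BROWSING_VARS[:1]:
        grid = munis[name].to_numpy().reshape(16, 16)
        assert moran_i(grid) > 0, name


def test_collision_table_structure(small_world):
    munis, coll = small_world["munis"], small_world["collisions"]
    assert set(coll["road_type"]) <= set(d.ROAD_TYPES)
    assert len(coll) <= 5 * 2 * len(munis)
    assert (coll["count"] >= 0).all()
    assert (coll["road_length"] > 0).all()
    # every row's (muni, road type) has positive length in the landscape
    lengths = munis.set_index("muni_id")
    for rt in d.ROAD_TYPES:
        sub = coll[coll["road_type"] == rt]
        assert (lengths.loc[sub["muni_id"], f"length_{rt}"].to_numpy() > 0).all()
    # zero-length pairs are omitted entirely
    zero_pairs = [
        (m, rt) for rt in d.ROAD_TYPES
        for m in munis.loc[munis[f"length_{rt}"] == 0, "muni_id"]
    ]
    emitted = set(zip(coll["muni_id"], coll["road_type"]))
    assert not (set(zero_pairs) & emitted)


def test_truth_components_sum_to_eta(small_world):
    truth = small_world["truth"]
    parts = [c for c in truth.columns if c.startswith("f_")] + [
        "stage1", "spatial", "spacetime", "overdispersion"]
    total = truth[parts].sum(axis=1)
    assert np.abs(total - truth["eta"]).max() < 1e-10


def test_poisson_mean_matches_construction():
    """With all effects off, empirical count totals match length*exp(eta)."""
    cfg = d.LandscapeConfig(
        grid_rows=32, grid_cols=32, district_block=4, seed=13,
        true_effects=(), overdispersion_sd=0.0, spatial_amplitude=0.0,
        p_no_road=0.0,
    )
    munis, _ = d.generate_landscape(cfg)
    coll, truth = d.simulate_collisions(munis, cfg)
    assert len(coll) == 32 * 32 * 5 * 2
    mu = coll["road_length"].to_numpy() * np.exp(truth["eta"].to_numpy())
    z = (coll["count"].sum() - mu.sum()) / np.sqrt(mu.sum())
    assert abs(z) < 3


def test_browsing_survey_null_proportion_half():
    cfg = d.LandscapeConfig(
        grid_rows=16, grid_cols=16, district_block=2, seed=5,
        browsing_params={c: (0.0, 0.0) for c in d.BROWSING_CLASSES},
        survey_missing_frac=0.0,
    )
    _, graph = d.generate_landscape(cfg)
    survey, _ = d.simulate_browsing_survey(graph, cfg)
    n = survey["n_examined"].sum()
    p_hat = survey["n_browsed"].sum() / n
    assert abs(p_hat - 0.5) < 3 * np.sqrt(0.25 / n)


def test_browsing_survey_missingness_and_classes(small_world):
    cfg = small_world["config"].with_(survey_missing_frac=0.0)
    survey, _ = d.simulate_browsing_survey(small_world["graph"], cfg)
    assert set(survey["palatability_class"]) == set(d.BROWSING_CLASSES)
    assert ((survey["n_browsed"] >= 0) & (survey["n_browsed"] <= survey["n_examined"])).all()
    # drop fraction 1 removes every cell
    cfg_all = cfg.with_(survey_missing_frac=1.0)
    survey2, _ = d.simulate_browsing_survey(small_world["graph"], cfg_all)
    assert survey2.empty


def test_harvest_monotone_and_noise_limits(small_world):
    munis = small_world["munis"]
    cfg0 = small_world["config"].with_(harvest_noise_sd=0.0)
    idx = d.true_dvc_index(munis, cfg0)
    h = d.simulate_harvest(munis, idx, cfg0)
    dist = pd.DataFrame({"district_id": munis["district_id"], "idx": idx}).groupby("district_id")["idx"].mean()
    merged = h.merge(dist.rename("mean_idx"), on="district_id")
    rho, _ = d.spearman_corr(merged["harvest_per_100ha"], merged["mean_idx"])
    assert rho == pytest.approx(1.0)
    # default noise: positive association across a larger world
    cfg = d.LandscapeConfig(grid_rows=20, grid_cols=20, district_block=2, seed=17)
    munis2, _ = d.generate_landscape(cfg)
    idx2 = d.true_dvc_index(munis2, cfg)
    h2 = d.simulate_harvest(munis2, idx2, cfg)
    dist2 = pd.DataFrame({"district_id": munis2["district_id"], "idx": idx2}).groupby("district_id")["idx"].mean()
    m2 = h2.merge(dist2.rename("mean_idx"), on="district_id")
    rho2, p2 = d.spearman_corr(m2["harvest_per_100ha"], m2["mean_idx"])
    assert rho2 > 0 and p2 < 0.05
    # enormous noise: correlation centred on zero over replicates
    rhos = []
    for s in range(20):
        cfgn = cfg.with_(seed=100 + s, harvest_noise_sd=1e6)
        hn = d.simulate_harvest(munis2, idx2, cfgn)
        mn = hn.merge(dist2.rename("mean_idx"), on="district_id")
        rhos.append(d.spearman_corr(mn["harvest_per_100ha"], mn["mean_idx"])[0])
    assert abs(np.mean(rhos)) < 0.2


def test_true_partial_zero_for_noise_covariates(small_world):
    cfg = small_world["config"]
    x = np.linspace(-2, 2, 50)
    assert np.all(d.true_partial(cfg, "bio6", x) == 0)
    assert np.any(d.true_partial(cfg, "bio1", x) != 0)
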