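"""Shared fixtures: small synthetic worlds and fitted models.

Everything is generated programmatically; the expensive fits are
session-scoped so the identity and prediction tests can share them.
"""

import numpy as np
import pytest

import dvcrisk as d


@pytest.fixture(scope="session")
def small_world():
    """An 8x8 world with the default sparse truth (fast to fit)."""
    cfg = d.LandscapeConfig(grid_rows=8, grid_cols=8, district_block=2, seed=31)
    munis, graph = d.generate_landscape(cfg)
    collisions, truth = d.simulate_collisions(munis, cfg)
    return {"config": cfg, "munis": munis, "graph": graph,
            "collisions": collisions, "truth": truth}


@pytest.fixture(scope="session")
def small_fit(small_world):
    """Stage-1 + stage-2 fit on the small world, full learner battery
    including the per-row overdispersion intercepts."""
    w = small_world
    pfit = d.fit_offset_glm(w["collisions"])
    offset = d.stage1_offset(pfit, w["collisions"])
    data = d.make_model_frame(w["collisions"], w["munis"])
    specs = d.default_learner_specs(
        climate=d.CLIMATE_VARS, landuse=d.LANDUSE_VARS, browsing=d.BROWSING_VARS,
        random_intercept=True,
    )
    fit = d.fit_boost(data, offset, specs, nu=0.1, mstop=120)
    return {"pfit": pfit, "offset": offset, "data": data, "fit": fit, **w}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_collisions(rows):
    """Build a collision table from (muni, road_type, year, count, length[, red])."""
    import pandas as pd

    recs = []
    for r in rows:
        rec = {"muni_id": r[0], "road_type": r[1], "year": r[2],
               "count": r[3], "road_length": r[4],
               "red_deer": r[5] if len(r) > 5 else False}
        recs.append(rec)
    return pd.DataFrame(recs)
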