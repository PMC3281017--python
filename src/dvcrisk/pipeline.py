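"""End-to-end orchestration of the two-stage analysis.

simulate (optional) -> stage-1 offset GLM -> browsing smoothing ->
out-of-bootstrap mstop selection -> final boosting fit -> stability
selection -> DVC index + risk classes -> harvest validation.  Every stage
is logged; the run report carries the config hash and seed so identical
configurations reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .basis import default_learner_specs
from .boosting import fit_boost, make_model_frame, select_mstop_oob, stability_select
from .browsing import extract_at_centroids, fit_mrf_binomial
from .index import classify_risk, compute_index, decompose
from .offset_model import fit_offset_glm, stage1_offset, stratum_rate_table
from .synthetic import (
    BROWSING_VARS, CLIMATE_VARS, LANDUSE_VARS, LandscapeConfig,
    generate_landscape, simulate_browsing_survey, simulate_collisions,
    simulate_harvest, true_dvc_index,
)

log = logging.getLogger("dvcrisk")


@dataclass
class PipelineConfig:
    """Stage parameters of the full pipeline."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    seed: int = 1
    nu: float = 0.1
    mstop_grid: tuple = tuple(range(0, 1501, 25))
    n_boot: int = 25
    n_subsamples: int = 50
    threshold: float = 0.5
    stability_q: int = 14
    target_df: float = 4.0
    browsing_target_df: float = None   # default n_districts / 4
    k_classes: int = 7
    span: float = 2 / 3
    use_smoothed_browsing: bool = True
    index_year: int = 2006

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landscape"]["true_effects"] = [list(e) for e in self.landscape.true_effects]
        d["mstop_grid"] = list(self.mstop_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        land = d.pop("landscape", {})
        if isinstance(land, dict):
            land = dict(land)
            if "true_effects" in land:
                land["true_effects"] = tuple(tuple(e) for e in land["true_effects"])
            land = LandscapeConfig(**land)
        if "mstop_grid" in d:
            d["mstop_grid"] = tuple(d["mstop_grid"])
        return cls(landscape=land, **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run every stage on a freshly simulated world; return the run report.

    When ``outdir`` is given, all tabular artifacts and the report are
    written there as CSV/JSON (deterministic payloads: re-running with the
    same config yields byte-identical files).
    """
    rng_master = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_master.spawn(3)]
    land = config.landscape

    log.info("simulate: grid %dx%d, seed %d", land.grid_rows, land.grid_cols, land.seed)
    munis, graph = generate_landscape(land)
    collisions, truth = simulate_collisions(munis, land)
    survey, survey_truth = simulate_browsing_survey(graph, land)
    idx_truth = true_dvc_index(munis, land, year=config.index_year)
    harvest = simulate_harvest(munis, idx_truth, land)
    log.info("simulate: %d municipalities, %d collision rows, %d survey cells",
             len(munis), len(collisions), len(survey))

    log.info("stage 1: offset Poisson GLM")
    pfit = fit_offset_glm(collisions)
    offset = stage1_offset(pfit, collisions)

    log.info("browsing: MRF smoothing over %d districts", graph.number_of_nodes())
    est = fit_mrf_binomial(survey, graph, target_df=config.browsing_target_df)
    if config.use_smoothed_browsing:
        smoothed = extract_at_centroids(est, munis)
        munis = munis.drop(columns=list(BROWSING_VARS)).merge(smoothed, on="muni_id")

    data = make_model_frame(collisions, munis)
    specs = default_learner_specs(
        climate=CLIMATE_VARS, landuse=LANDUSE_VARS, browsing=BROWSING_VARS,
        target_df=config.target_df,
    )

    log.info("stage 2: OOB selection of mstop (%d bootstraps)", config.n_boot)
    oob = select_mstop_oob(data, offset, specs, nu=config.nu, grid=config.mstop_grid,
                           n_boot=config.n_boot, seed=stage_seeds[0])
    log.info("stage 2: selected mstop = %d", oob.selected_mstop)

    fit = fit_boost(data, offset, specs, nu=config.nu, mstop=oob.selected_mstop)

    log.info("stability selection: %d half-samples", config.n_subsamples)
    stab = stability_select(data, offset, specs, nu=config.nu,
                            m_iter=max(oob.selected_mstop, 200),
                            n_subsamples=config.n_subsamples,
                            threshold=config.threshold, seed=stage_seeds[1],
                            q=config.stability_q)
    selected = sorted(stab.selected)
    log.info("selected learners: %s", selected)

    index = compute_index(fit, munis, year=config.index_year, selected=selected)
    classes = classify_risk(index, k=config.k_classes, seed=stage_seeds[2])
    index = index.merge(classes.labels.rename("risk_class"), left_on="muni_id", right_index=True)
    _, variability = decompose(fit, munis, year=config.index_year, selected=selected)

    from .validation import validate_index

    val = validate_index(index, munis, harvest, span=config.span)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_municipalities": int(len(munis)),
        "n_rows": int(len(collisions)),
        "stage1_coefficients": {k: float(v) for k, v in pfit.coefficients.items()},
        "selected_mstop": int(oob.selected_mstop),
        "oob_risk_at_0": float(oob.mean_risk[list(oob.grid).index(0)]) if 0 in oob.grid else None,
        "oob_risk_at_selected": float(oob.mean_risk.min()),
        "selection_frequencies": {k: float(v) for k, v in stab.selection_frequency.items()},
        "selected_learners": selected,
        "group_log_sd": {k: float(v) for k, v in variability.items()},
        "index_summary": {
            "min": float(index["index"].min()),
            "median": float(index["index"].median()),
            "max": float(index["index"].max()),
        },
        "index_product_check": float(
            np.max(np.abs(index[list(decompose_cols())].prod(axis=1) - index["index"]))
        ),
        "spearman_rho": float(val.spearman_rho),
        "p_value": float(val.p_value),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_munis(munis, outdir / "municipalities.csv")
        dio.write_collisions(collisions, outdir / "collisions.csv")
        dio.write_survey(survey, outdir / "browsing_survey.csv")
        dio.write_harvest(harvest, outdir / "harvest.csv")
        dio.write_graph(graph, outdir / "district_edges.csv")
        dio.save_parametric_fit(pfit, outdir / "stage1_fit.json")
        stratum_rate_table(pfit).to_csv(outdir / "stage1_rates.csv", index=False)
        pd.DataFrame({"mstop": oob.grid, "mean_oob_risk": oob.mean_risk}).to_csv(
            outdir / "oob_risk.csv", index=False)
        stab.selection_frequency.rename("frequency").to_csv(outdir / "stability_frequencies.csv")
        dio.save_boost_fit(fit, outdir / "boost_fit.json")
        index.to_csv(outdir / "dvc_index.csv", index=False)
        est.proportions.to_csv(outdir / "browsing_smoothed.csv")
        val.table.to_csv(outdir / "validation_table.csv", index=False)
        val.lowess_curve.to_csv(outdir / "lowess_curve.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def decompose_cols():
    from .index import GROUP_ORDER

    return list(GROUP_ORDER)
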