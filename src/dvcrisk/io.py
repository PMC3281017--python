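"""CSV / JSON / YAML interchange with schema validation.

All tabular artifacts are flat CSV files with documented headers; the
district adjacency graph is a two-column edge list; fitted models and run
reports are JSON.  Readers validate schema and value ranges and report the
offending file and rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .basis import BaseLearnerSpec, BuiltLearner
from .boosting import BoostFit
from .errors import ValidationError
from .offset_model import ParametricFit, validate_collisions
from .synthetic import BROWSING_VARS, COVARIATES, ROAD_TYPES

MUNI_BASE_COLS = ["muni_id", "centroid_x", "centroid_y", "district_id", "red_deer"]
MUNI_COLS = MUNI_BASE_COLS + [f"length_{rt}" for rt in ROAD_TYPES] + list(COVARIATES)


def write_munis(munis: pd.DataFrame, path):
    munis.to_csv(path, index=False)


def read_munis(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MUNI_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing municipality columns: {sorted(missing)}")
    if df["muni_id"].duplicated().any():
        dup = df.loc[df["muni_id"].duplicated(), "muni_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate muni_id {dup!r}")
    for rt in ROAD_TYPES:
        if (df[f"length_{rt}"] < 0).any():
            raise ValidationError(f"{path}: negative road length for {rt}")
    for col in BROWSING_VARS:
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValidationError(f"{path}: browsing proportion outside [0, 1] in {col}")
    if df.duplicated(subset=["centroid_x", "centroid_y"]).any():
        raise ValidationError(f"{path}: centroids are not unique")
    df["red_deer"] = df["red_deer"].astype(bool)
    return df


def write_collisions(collisions: pd.DataFrame, path):
    collisions.to_csv(path, index=False)


def read_collisions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    try:
        validate_collisions(df)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e
    df["red_deer"] = df["red_deer"].astype(bool) if "red_deer" in df.columns else False
    return df


def write_survey(survey: pd.DataFrame, path):
    survey.to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    from .browsing import validate_survey

    df = pd.read_csv(path)
    try:
        validate_survey(df)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e
    return df


def write_harvest(harvest: pd.DataFrame, path):
    harvest.to_csv(path, index=False)


def read_harvest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"district_id", "harvest_per_100ha"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing harvest columns: {sorted(missing)}")
    if (df["harvest_per_100ha"] < 0).any():
        raise ValidationError(f"{path}: negative harvest")
    return df


def write_graph(graph: nx.Graph, path):
    pd.DataFrame(sorted(graph.edges), columns=["district_a", "district_b"]).to_csv(path, index=False)


def read_graph(path, nodes=None) -> nx.Graph:
    df = pd.read_csv(path)
    missing = {"district_a", "district_b"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing edge-list columns: {sorted(missing)}")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(df.itertuples(index=False, name=None))
    if any(a == b for a, b in g.edges):
        raise ValidationError(f"{path}: self-loop in district graph")
    return g


# ---------------------------------------------------------------------------
# model serialization

def save_parametric_fit(fit: ParametricFit, path):
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1, sort_keys=True))


def load_parametric_fit(path) -> ParametricFit:
    return ParametricFit.from_dict(json.loads(Path(path).read_text()))


def save_boost_fit(fit: BoostFit, path):
    """Serialize the ensemble for later prediction.

    Stores learner specs, knots, ridge amounts, aggregated coefficients and
    centering constants.  Training-row quantities (linear predictor,
    per-row contributions, random-intercept values) are not stored; a
    loaded fit predicts structural terms only.
    """
    learners = []
    for L, coef, c in zip(fit.learners, fit.coefs, fit.centering):
        spec = L.spec
        entry = {
            "spec": {
                "name": spec.name, "kind": spec.kind, "covariates": list(spec.covariates),
                "n_knots": spec.n_knots, "spline_degree": spec.spline_degree,
                "penalty_order": spec.penalty_order, "target_df": spec.target_df,
                "group": spec.group,
            },
            "lam": None if L.lam is None else float(L.lam),
            "centering": float(c),
            "coef": [] if L.is_random_intercept else np.asarray(coef).tolist(),
        }
        if L._knots is not None:
            if isinstance(L._knots, tuple):
                entry["knots"] = [k.tolist() for k in L._knots]
            else:
                entry["knots"] = L._knots.tolist()
        learners.append(entry)
    payload = {"nu": fit.nu, "mstop": fit.mstop, "selection_path": list(map(int, fit.selection_path)),
               "learners": learners}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_boost_fit(path) -> BoostFit:
    payload = json.loads(Path(path).read_text())
    learners, coefs = [], []
    for entry in payload["learners"]:
        spec = BaseLearnerSpec(**{**entry["spec"], "covariates": tuple(entry["spec"]["covariates"])})
        L = BuiltLearner.__new__(BuiltLearner)
        L.spec = spec
        L.monotone = spec.kind == "mono_pspline"
        L.is_random_intercept = spec.kind == "random_intercept"
        L.lam = entry["lam"]
        L.X = None
        L.K = None
        knots = entry.get("knots")
        if knots is None:
            L._knots = None
        elif knots and isinstance(knots[0], list):
            L._knots = tuple(np.asarray(k) for k in knots)
        else:
            L._knots = np.asarray(knots)
        learners.append(L)
        coefs.append(np.asarray(entry["coef"], float))
    n_l = len(learners)
    return BoostFit(
        learners=learners, nu=payload["nu"], mstop=payload["mstop"],
        selection_path=payload["selection_path"], coefs=coefs,
        offset=np.zeros(0), train_linpred=np.zeros(0),
        train_contrib=np.zeros((0, n_l)), train_index=np.zeros(0, int),
        centering=np.asarray([e["centering"] for e in payload["learners"]]),
    )


# ---------------------------------------------------------------------------
# configs

def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
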