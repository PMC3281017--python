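"""Synthetic municipality landscapes with known ground truth.

The generator emulates the data structures of a state-wide deer-vehicle
collision (DVC) study: a grid of municipalities (each with road lengths for
five road categories and a vector of climate / land-use / browsing
covariates), square blocks of municipalities forming game-management
districts, collision counts for two survey years, a sapling browsing survey
per district, and district-level harvest numbers.  Every stochastic output
carries its ground truth alongside so that recovery of effects, indices and
correlations can be tested without any external data.

Municipalities are grid cells; centroids are cell centres; districts are
``district_block`` x ``district_block`` blocks of cells with rook adjacency.
Covariates are spatially autocorrelated Gaussian surfaces (smoothed white
noise) plus independent noise.  Collision counts are Poisson draws from a
log-linear model: a parametric road-type x year x red-deer predictor with
log road length as offset, plus sparse smooth covariate effects, a smooth
spatial surface, an optional 2009-only spatio-temporal surface, and
lognormal overdispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .errors import ConfigurationError

ROAD_TYPES = ("motorway", "primary", "secondary", "tertiary", "residential")

CLIMATE_VARS = (
    "bio1",   # annual mean temperature
    "bio4",   # temperature seasonality
    "bio6",   # min temperature of coldest month
    "bio7",   # temperature annual range
    "bio10",  # mean temperature of warmest quarter
    "bio11",  # mean temperature of coldest quarter
    "bio12",  # annual precipitation
    "bio18",  # precipitation of warmest quarter
    "bio19",  # precipitation of coldest quarter
)

LANDUSE_VARS = (
    "meadows",
    "swamps",
    "industry",
    "urban",
    "complex_habitats",
    "conifer_forest",
    "mixed_forest",
    "broadleaf_forest",
    "arable",
    "forest_edge_length",
)

BROWSING_CLASSES = ("spruce_pine", "oak_fir", "ash_maple_elm_linden", "beech_other")
BROWSING_VARS = tuple(f"browsing_{c}" for c in BROWSING_CLASSES)

COVARIATES = CLIMATE_VARS + LANDUSE_VARS + BROWSING_VARS

YEARS = (2006, 2009)

# Per-municipality road-length lognormal parameters (log-km).  Means follow
# the ordering of the printed Bavarian per-municipality averages
# (residential >> tertiary > secondary > primary > motorway).
DEFAULT_ROAD_LENGTH_PARAMS = {
    "motorway": (1.73, 0.5),
    "primary": (1.79, 0.5),
    "secondary": (1.98, 0.5),
    "tertiary": (2.13, 0.5),
    "residential": (3.58, 0.5),
}

# Probability that a municipality lacks a road type; complements of the
# Bavarian presence fractions (525, 1048, 1724, 1977, 2181 of 2223).
DEFAULT_P_NO_ROAD = {
    "motorway": 0.764,
    "primary": 0.529,
    "secondary": 0.224,
    "tertiary": 0.111,
    "residential": 0.019,
}

# Stage-1 truth: treatment coding with residential x 2006 x non-red baseline.
# Red-deer factor 0.76 and a global ~15% 2009 increase; motorways strongly
# below baseline (fencing).
DEFAULT_TRUE_BETA = {
    "intercept": math.log(0.15),
    "road[motorway]": -1.6,
    "road[primary]": 0.6,
    "road[secondary]": 1.0,
    "road[tertiary]": 0.8,
    "year[2009]": math.log(1.15),
    "road[motorway]:year[2009]": -0.15,
    "road[primary]:year[2009]": 0.0,
    "road[secondary]:year[2009]": 0.0,
    "road[tertiary]:year[2009]": 0.0,
    "red_deer": math.log(0.76),
}

# Sparse truth: 3 of 9 climate, 2 of 10 land-use and 1 of 4 browsing effects
# are nonzero; everything else is noise.  Amplitude ordering climate >
# land use > browsing mirrors the relative group importance the model is
# meant to recover (browsing tops out near a +/-35% multiplicative change).
DEFAULT_TRUE_EFFECTS = (
    ("bio1", "sin", 0.5),
    ("bio12", "quadratic", 0.45),
    ("bio4", "linear", -0.4),
    ("forest_edge_length", "quadratic", 0.35),
    ("urban", "linear", -0.35),
    ("browsing_oak_fir", "increasing", 0.3),
)

# Per palatability class: (baseline logit of browsing proportion, amplitude
# of the smooth spatial logit field).
DEFAULT_BROWSING_PARAMS = {
    "spruce_pine": (logit(0.10), 0.5),
    "oak_fir": (logit(0.30), 0.6),
    "ash_maple_elm_linden": (logit(0.40), 0.6),
    "beech_other": (logit(0.25), 0.5),
}


@dataclass(frozen=True)
class LandscapeConfig:
    """All knobs of the synthetic world.

    Defaults describe the study conditions the generator is meant to
    emulate; see the shape functions in :data:`SHAPES` for the meaning of
    the ``true_effects`` tags.
    """

    grid_rows: int = 20
    grid_cols: int = 20
    district_block: int = 4
    seed: int = 20060116
    road_length_params: dict = field(default_factory=lambda: dict(DEFAULT_ROAD_LENGTH_PARAMS))
    p_no_road: dict = field(default_factory=lambda: dict(DEFAULT_P_NO_ROAD))
    covariate_spatial_range: float = 2.0
    covariate_noise_frac: float = 0.5
    overdispersion_sd: float = 0.2
    true_effects: tuple = DEFAULT_TRUE_EFFECTS
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    spatial_amplitude: float = 0.35
    spatial_range: float = 4.0
    spacetime_amplitude: float = 0.0
    browsing_params: dict = field(default_factory=lambda: dict(DEFAULT_BROWSING_PARAMS))
    saplings_per_district: int = 75  # one transect of 75 saplings per survey point
    survey_missing_frac: float = 0.1
    red_deer_frac: float = 0.15
    harvest_max: float = 10.0  # plateau: up to ~10 roe deer per 100 ha
    harvest_halfsat: float = 0.75
    harvest_noise_sd: float = 0.8

    def __post_init__(self):
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ConfigurationError("grid dimensions must be >= 2")
        if self.district_block < 1:
            raise ConfigurationError("district_block must be positive")
        if self.grid_rows % self.district_block or self.grid_cols % self.district_block:
            raise ConfigurationError(
                f"district_block={self.district_block} must divide grid dims "
                f"({self.grid_rows}x{self.grid_cols})"
            )
        p = self._p_no_road_map()
        if any(not (0 <= v < 1) for v in p.values()):
            raise ConfigurationError("p_no_road must lie in [0, 1)")
        if self.overdispersion_sd < 0:
            raise ConfigurationError("overdispersion_sd must be >= 0")
        for name, _, _ in self.true_effects:
            if name not in COVARIATES:
                raise ConfigurationError(f"unknown covariate in true_effects: {name!r}")
        for _, tag, _ in self.true_effects:
            if tag not in SHAPES:
                raise ConfigurationError(f"unknown effect shape tag: {tag!r}")

    def _p_no_road_map(self) -> dict:
        if isinstance(self.p_no_road, dict):
            return dict(self.p_no_road)
        return {rt: float(self.p_no_road) for rt in ROAD_TYPES}

    def with_(self, **kwargs) -> "LandscapeConfig":
        """Return a copy with fields replaced."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# effect shape functions (ground-truth partial effects on the log scale)

def _std_browsing(p):
    # browsing covariates live on [0, 1]; centre/scale to a comparable range
    return (np.asarray(p, dtype=float) - 0.25) / 0.12


SHAPES = {
    "sin": lambda z, a: a * np.sin(2.0 * np.pi * z / 5.0),
    "quadratic": lambda z, a: a * (z * z - 1.0) / 3.0,
    "linear": lambda z, a: a * z / 2.0,
    "increasing": lambda z, a: a * np.tanh(z),
}


def true_partial(config: LandscapeConfig, covariate: str, values) -> np.ndarray:
    """Evaluate the ground-truth partial effect of ``covariate`` (log scale).

    Covariates absent from ``config.true_effects`` are pure noise and return
    zeros.  Browsing proportions are internally standardised before the
    shape function is applied.
    """
    values = np.asarray(values, dtype=float)
    for name, tag, amp in config.true_effects:
        if name == covariate:
            z = _std_browsing(values) if name in BROWSING_VARS else values
            return SHAPES[tag](z, amp)
    return np.zeros_like(values)


# ---------------------------------------------------------------------------
# random-stream management: one global seed, named independent substreams

_STREAMS = (
    "covariates", "roads", "browsing_fields", "spatial", "spacetime",
    "overdispersion", "counts", "survey", "harvest",
)


def _rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _browsing_logit_grids(config) -> dict:
    """True municipality-level browsing logits per class, on the grid.

    Smooth class field plus independent local variation; the district-level
    survey truth is the block mean of these logits, so covariates and
    survey share one ground truth.
    """
    rng = _rngs(config.seed)["browsing_fields"]
    w = config.covariate_noise_frac
    out = {}
    for cls in BROWSING_CLASSES:
        mu0, amp = config.browsing_params[cls]
        f = _smooth_field(rng, config.grid_rows, config.grid_cols, config.covariate_spatial_range)
        eps = rng.standard_normal((config.grid_rows, config.grid_cols))
        out[cls] = mu0 + amp * (math.sqrt(1 - w * w) * f + w * eps)
    return out


def _smooth_field(rng, rows, cols, corr_range):
    """Standardised smooth Gaussian surface on the grid (unit variance)."""
    z = rng.standard_normal((rows, cols))
    f = gaussian_filter(z, sigma=corr_range, mode="reflect")
    sd = f.std()
    if sd < 1e-12:
        return np.zeros_like(f)
    return (f - f.mean()) / sd


# ---------------------------------------------------------------------------
# landscape

def generate_landscape(config: LandscapeConfig):
    """Generate the municipality table and district adjacency graph.

    Returns ``(munis, graph)`` where ``munis`` is a DataFrame with one row
    per municipality (centroid, district, red-deer flag, five road lengths,
    23 covariates) and ``graph`` is a networkx Graph over district ids with
    rook adjacency of the square district blocks.
    """
    rngs = _rngs(config.seed)
    R, C = config.grid_rows, config.grid_cols
    n = R * C
    rows_idx, cols_idx = np.divmod(np.arange(n), C)

    nb_rows = R // config.district_block
    nb_cols = C // config.district_block
    drow = rows_idx // config.district_block
    dcol = cols_idx // config.district_block
    district_id = np.char.add(
        np.char.add("D", np.char.zfill((drow * nb_cols + dcol).astype(str), 3)), ""
    )

    munis = pd.DataFrame(
        {
            "muni_id": [f"M{i:04d}" for i in range(n)],
            "centroid_x": cols_idx + 0.5,
            "centroid_y": rows_idx + 0.5,
            "district_id": district_id,
        }
    )

    # red-deer districts: one contiguous block in the lower-left corner of
    # the district lattice covering ~red_deer_frac of districts
    k = max(1, int(round(math.sqrt(config.red_deer_frac) * min(nb_rows, nb_cols))))
    munis["red_deer"] = (drow < k) & (dcol < k)

    rng_roads = rngs["roads"]
    p_no = config._p_no_road_map()
    for rt in ROAD_TYPES:
        mu, sd = config.road_length_params[rt]
        lengths = np.exp(rng_roads.normal(mu, sd, size=n))
        absent = rng_roads.random(n) < p_no[rt]
        lengths[absent] = 0.0
        munis[f"length_{rt}"] = lengths

    # climate and land-use covariates: smooth field + independent noise,
    # standardised to ~unit variance
    rng_cov = rngs["covariates"]
    w = config.covariate_noise_frac
    for name in CLIMATE_VARS + LANDUSE_VARS:
        f = _smooth_field(rng_cov, R, C, config.covariate_spatial_range)
        eps = rng_cov.standard_normal((R, C))
        surf = math.sqrt(1 - w * w) * f + w * eps
        munis[name] = surf[rows_idx, cols_idx]

    # browsing proportions: logistic of class baseline + smooth logit field
    # + local (municipality-level) variation
    logits = _browsing_logit_grids(config)
    for cls in BROWSING_CLASSES:
        munis[f"browsing_{cls}"] = expit(logits[cls][rows_idx, cols_idx])

    graph = nx.Graph()
    dids = sorted(set(district_id))
    graph.add_nodes_from(dids)
    for br in range(nb_rows):
        for bc in range(nb_cols):
            d = f"D{br * nb_cols + bc:03d}"
            if bc + 1 < nb_cols:
                graph.add_edge(d, f"D{br * nb_cols + bc + 1:03d}")
            if br + 1 < nb_rows:
                graph.add_edge(d, f"D{(br + 1) * nb_cols + bc:03d}")
    return munis, graph


# ---------------------------------------------------------------------------
# collisions

def _stage1_linpred(config, road_type, year, red):
    b = config.true_beta
    eta = b["intercept"] + (b["red_deer"] if red else 0.0)
    if road_type != "residential":
        eta += b[f"road[{road_type}]"]
        if year == 2009:
            eta += b.get(f"road[{road_type}]:year[2009]", 0.0)
    if year == 2009:
        eta += b["year[2009]"]
    return eta


def _spatial_surfaces(config):
    rngs = _rngs(config.seed)
    R, C = config.grid_rows, config.grid_cols
    f_sp = config.spatial_amplitude * _smooth_field(rngs["spatial"], R, C, config.spatial_range)
    f_st = config.spacetime_amplitude * _smooth_field(rngs["spacetime"], R, C, config.spatial_range)
    return f_sp, f_st


def true_dvc_index(munis: pd.DataFrame, config: LandscapeConfig, year: int = 2006) -> pd.Series:
    """Ground-truth DVC index per municipality.

    exp of the summed true covariate partials plus the spatial surface (plus
    the spatio-temporal surface for 2009); the multiplicative change in
    expected collisions per km relative to the parametric baseline.
    """
    f_sp, f_st = _spatial_surfaces(config)
    ix = munis["centroid_y"].to_numpy().astype(int)
    jx = munis["centroid_x"].to_numpy().astype(int)
    eta = f_sp[ix, jx].copy()
    if year == 2009:
        eta += f_st[ix, jx]
    for name, _, _ in config.true_effects:
        eta += true_partial(config, name, munis[name].to_numpy())
    return pd.Series(np.exp(eta), index=munis.index, name="true_index")


def simulate_collisions(munis: pd.DataFrame, config: LandscapeConfig):
    """Draw Poisson collision counts for every municipality x road type x year.

    Municipality-road-type pairs with zero road length are omitted.  Returns
    ``(collisions, truth)``: the long-format count table and a row-aligned
    truth table with the total log-linear predictor ``eta`` and its additive
    components (stage-1 part, each covariate partial, spatial and
    spatio-temporal surfaces, overdispersion intercept).
    """
    for name, _, _ in config.true_effects:
        if name not in munis.columns:
            raise ConfigurationError(f"true effect covariate {name!r} missing from table")
    rngs = _rngs(config.seed)
    f_sp, f_st = _spatial_surfaces(config)
    ix = munis["centroid_y"].to_numpy().astype(int)
    jx = munis["centroid_x"].to_numpy().astype(int)

    partials = {
        name: true_partial(config, name, munis[name].to_numpy())
        for name, _, _ in config.true_effects
    }
    sp = f_sp[ix, jx]
    st = f_st[ix, jx]
    env = sum(partials.values()) if partials else np.zeros(len(munis))

    rec_c, rec_t = [], []
    rng_od = rngs["overdispersion"]
    rng_counts = rngs["counts"]
    red = munis["red_deer"].to_numpy()
    for year in YEARS:
        for rt in ROAD_TYPES:
            lengths = munis[f"length_{rt}"].to_numpy()
            present = lengths > 0
            if not present.any():
                continue
            base = np.array(
                [_stage1_linpred(config, rt, year, r) for r in red[present]]
            )
            od = (
                rng_od.normal(0.0, config.overdispersion_sd, size=present.sum())
                if config.overdispersion_sd > 0
                else np.zeros(present.sum())
            )
            eta = base + env[present] + sp[present] + (st[present] if year == 2009 else 0.0) + od
            mu = lengths[present] * np.exp(eta)
            counts = rng_counts.poisson(mu)
            sub = munis.loc[present, "muni_id"].to_numpy()
            rec_c.append(
                pd.DataFrame(
                    {
                        "muni_id": sub,
                        "road_type": rt,
                        "year": year,
                        "count": counts,
                        "road_length": lengths[present],
                        "red_deer": red[present],
                    }
                )
            )
            t = pd.DataFrame({"muni_id": sub, "road_type": rt, "year": year})
            t["eta"] = eta
            t["stage1"] = base
            for name in COVARIATES:
                if name in partials:
                    t[f"f_{name}"] = partials[name][present]
            t["spatial"] = sp[present]
            t["spacetime"] = st[present] if year == 2009 else 0.0
            t["overdispersion"] = od
            rec_t.append(t)

    collisions = pd.concat(rec_c, ignore_index=True)
    truth = pd.concat(rec_t, ignore_index=True)
    return collisions, truth


# ---------------------------------------------------------------------------
# browsing survey

def simulate_browsing_survey(graph: nx.Graph, config: LandscapeConfig):
    """Binomial sapling survey per district x palatability class.

    ``n_browsed ~ Binomial(n_examined, logistic(class baseline + smooth
    district-level logit field))``.  A ``survey_missing_frac`` fraction of
    district x class cells is dropped to emulate absent genera.  Returns
    ``(survey, truth)`` with the true logits per district x class.
    """
    rng = _rngs(config.seed)["survey"]
    districts = sorted(graph.nodes)
    nb_cols = config.grid_cols // config.district_block
    logits = _browsing_logit_grids(config)
    rows_s, rows_t = [], []
    for cls in BROWSING_CLASSES:
        logit_field = logits[cls]
        for d in districts:
            idx = int(d[1:])
            br, bc = divmod(idx, nb_cols)
            blk = logit_field[
                br * config.district_block:(br + 1) * config.district_block,
                bc * config.district_block:(bc + 1) * config.district_block,
            ]
            eta = float(blk.mean())
            rows_t.append({"district_id": d, "palatability_class": cls, "true_logit": eta})
            if rng.random() < config.survey_missing_frac:
                continue
            n_ex = config.saplings_per_district
            n_br = int(rng.binomial(n_ex, expit(eta)))
            rows_s.append(
                {
                    "district_id": d,
                    "palatability_class": cls,
                    "n_examined": n_ex,
                    "n_browsed": n_br,
                }
            )
    survey = pd.DataFrame(rows_s, columns=["district_id", "palatability_class", "n_examined", "n_browsed"])
    truth = pd.DataFrame(rows_t)
    return survey, truth


# ---------------------------------------------------------------------------
# harvest

def recovery_study_config(seed: int = 20060116) -> LandscapeConfig:
    """World for the controlled function-recovery study.

    One sine, one quadratic and one monotone effect with amplitudes the
    boosting fit is powered to resolve at the out-of-bootstrap stopping
    iteration, under pure Poisson sampling: the overdispersion and nuisance
    spatial-surface channels are off, so the measured error reflects
    estimation of the covariate functions alone (those channels are
    exercised by their own tests).
    """
    return LandscapeConfig(
        seed=seed,
        true_effects=(
            ("bio1", "sin", 0.8),
            ("forest_edge_length", "quadratic", 0.6),
            ("browsing_oak_fir", "increasing", 0.5),
        ),
        overdispersion_sd=0.0,
        spatial_amplitude=0.0,
    )


def simulate_harvest(munis: pd.DataFrame, index_truth: pd.Series, config: LandscapeConfig) -> pd.DataFrame:
    """District harvest numbers driven by the true DVC index.

    District harvest per 100 ha is a monotone saturating (Michaelis-Menten)
    transform of the district-mean true index plus Gaussian noise, so the
    relation is near-linear for small indices and plateaus at high ones.
    """
    if (np.asarray(index_truth) <= 0).any():
        raise ConfigurationError("index_truth must be positive")
    rng = _rngs(config.seed)["harvest"]
    df = pd.DataFrame({"district_id": munis["district_id"].to_numpy(), "idx": np.asarray(index_truth)})
    dist = df.groupby("district_id", sort=True)["idx"].mean()
    mean_h = config.harvest_max * dist / (dist + config.harvest_halfsat)
    noise = rng.normal(0.0, config.harvest_noise_sd, size=len(dist))
    harvest = np.maximum(mean_h.to_numpy() + noise, 0.0)
    return pd.DataFrame({"district_id": dist.index, "harvest_per_100ha": harvest})
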