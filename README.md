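# dvcrisk

Model-based risk assessment for deer–vehicle collisions (DVCs) at the
municipality scale.

Collisions between vehicles and roe deer are frequent enough that,
recorded per municipality and road type, they carry usable information
about local deer density — information that is otherwise expensive to
obtain at landscape scale.  `dvcrisk` implements a two-stage Poisson
regression pipeline that turns collision counts into a relative,
map-ready risk index, for wildlife managers, road-safety planners and
quantitative ecologists who want to apply or study the method on their own
data or on fully synthetic replicas.

## The model

**Stage 1 — mandatory parametric baseline.**  The count of collisions for
municipality *i*, road type *r* and year *t* follows

```
count_irt ~ Poisson( L_ir · exp(β₀ + β_r + β_t + β_rt + β_red · red_i) )
```

with the log road length `log L_ir` as offset, so `exp(linear predictor)`
is the expected number of DVCs per km for each road-type × year stratum,
with or without red-deer district membership.  These effects are
estimated by maximum likelihood without selection or penalisation.

**Stage 2 — boosted additive deviations.**  Deviations from the stage-1
baseline are modelled by a Poisson additive model with the whole stage-1
predictor as offset:

```
log μ = offset + Σⱼ f_j(x_ij) + f_spat(s_i) + f_st(s_i)·1[t=2009] + b_i
```

where the `f_j` are penalized-spline partial effects of 9 climate, 10
land-use and 4 browsing-intensity covariates (the browsing effects
constrained to be nondecreasing), `f_spat` a bivariate spline surface over
municipality centroids, `f_st` a 2009-only surface, and `b_i` optional
observation-level overdispersion intercepts.  The ensemble is fitted by
component-wise functional gradient boosting: each iteration fits every
base-learner to the current negative gradient by penalized least squares
(all learners calibrated to the same effective degrees of freedom) and
updates only the best one.  The number of iterations is chosen by
out-of-bootstrap risk; relevant terms are identified by stability
selection over municipality half-samples.

**DVC index.**  `exp(Σ selected nonparametric contributions)` is the DVC
index: the multiplicative change in expected DVCs per km relative to the
stage-1 baseline (0.5 = half, 2.0 = twice).  It factorises exactly into
climate × land-use × browsing × spatial components, is classified into
k-means risk classes for mapping, and is validated externally against
district harvest numbers via a LOWESS trend and Spearman's rank
correlation.

Browsing covariates come from a sapling survey smoothed over the
game-management-district adjacency graph with an intrinsic-CAR (Markov
random field) penalized binomial model.

A synthetic-data generator (`LandscapeConfig`, `generate_landscape`,
`simulate_collisions`, `simulate_browsing_survey`, `simulate_harvest`)
produces grid-world replicas of all inputs with known ground truth, so
every stage is testable end to end without external data.

## Worked example

```python
import dvcrisk as d

cfg = d.PipelineConfig(
    landscape=d.LandscapeConfig(grid_rows=12, grid_cols=12, district_block=2, seed=23),
    seed=3, mstop_grid=tuple(range(0, 301, 25)), n_boot=10, n_subsamples=25,
)
report = d.run_pipeline(cfg)
```

prints (see `examples/dvc_index_and_validation.py`):

```
selected mstop: 150
DVC index across municipalities: min 0.40, median 0.98, max 2.41
relative group importance (sd of log factors):
  climate    0.418
  landuse    0.207
  browsing   0.053
  space      0.000
index = product of group factors, max |error| = 4.4e-16
harvest validation: Spearman rho = 0.801 (p = 4.61e-09) across districts
```

The index summary says collision risk varies about six-fold across
municipalities relative to the parametric baseline; climate covariates
drive most of that variation, land use less, browsing least; and the
district-mean index ranks districts almost as the harvest numbers do —
supporting its use as a relative deer-density surrogate.  Each
`examples/*.py` script demonstrates one capability (simulation, stage-1
baseline, boosting, browsing smoothing, index + validation) and prints
what the numbers mean.

A thin CLI wraps the same functions:

```
dvcrisk simulate --out world/
dvcrisk fit-offset --collisions world/collisions.csv --out stage1.json
dvcrisk run --config pipeline.yaml --out results/
```

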