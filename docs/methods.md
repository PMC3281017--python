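# Methods

## Model and two-step estimation

The response is the number of deer–vehicle collisions (DVCs) per
municipality × road type × year.  Counts are modelled as Poisson
throughout; road length enters as an offset so that rates are per km.

Estimation is deliberately split in two steps.  The parametric part
(intercept, road-type and year main effects and interactions, red-deer
district indicator — 11 parameters under treatment coding with the
residential × 2006 × non-red cell as reference) is scientifically
mandatory and is fitted first, alone, by maximum likelihood (statsmodels
IRLS; covariance = inverse Fisher information).  Fitting the flexible
terms simultaneously with the parametric ones would let goodness-of-fit
comparisons favour the more flexible components and bias variable
selection, so the second step treats the entire stage-1 linear predictor
(including `log` length) as a fixed offset and models only deviations
from it.

Municipality–road-type pairs with zero length are excluded rather than
given a `-inf` offset; a road type observed in only one year makes its
interaction inestimable and raises an error naming the stratum.

## Stage 2: component-wise boosting

Base-learners:

| kind             | design                                   | penalty                          |
|------------------|------------------------------------------|----------------------------------|
| `pspline`        | cubic B-splines, 20 interior knots       | 2nd-order difference             |
| `mono_pspline`   | same, coefficients nondecreasing         | 2nd-order difference             |
| `spatial`        | tensor product over centroids, 8×8 interior knots | Kronecker sum of 1st-order differences |
| `spatiotemporal` | as spatial, rows zeroed unless year 2009 | as spatial                       |
| `random_intercept` | identity (one coefficient per row)     | ridge                            |
| `linear`         | `[1, x]`                                  | none                             |

Every penalized learner's ridge amount is calibrated so the trace of its
smoother hat matrix equals a common `target_df` (default 4), found by
bisection on the generalized-eigenvalue representation of the trace
(tolerance 1e-6); for the ridge-on-identity intercepts the closed form is
λ = n/df − 1.  Equal complexity keeps the per-iteration selection among
learners fair.  The bivariate surfaces use first-order difference
marginals because the Kronecker-sum penalty with second-order marginals
has a four-dimensional null space, which would make df = 4 unreachable at
any finite λ.

The fitting loop is functional gradient descent on the Poisson
log-likelihood: with linear predictor `F` (initialised at the offset),
each iteration computes the negative gradient `u = y − exp(F)`, fits
every base-learner to `u` by penalized least squares, selects the learner
with the smallest *penalized* residual sum of squares (ties go to the
earlier learner), and advances `F` by ν (default 0.1) times its fitted
values.  Two numerical safeguards matter in count data:

* **Step halving.**  The gradient lives on the count scale while `F`
  lives on the log scale; where the mean is large a df-4 fit can propose
  steps of several log-units, which makes the risk oscillate.  After
  selection, the step is halved until the in-sample risk is
  non-increasing.  This guarantees a monotone training-risk path without
  affecting which learner is chosen.
* **Exact monotone fits.**  Monotone learners solve the constrained
  penalized least-squares problem exactly: coefficients are
  reparametrised as a free level plus nonnegative increments and the
  problem becomes a small nonnegative least-squares system in the
  Cholesky metric of the penalized normal matrix.  Projecting the
  unconstrained solution onto monotone sequences instead (a seemingly
  harmless shortcut) collapses to a near-constant fit whenever correlated
  covariates tilt the working residual the other way, silently removing
  the learner from competition.  Nondecreasing B-spline coefficients
  guarantee a nondecreasing fitted function, and sums of nondecreasing
  functions stay nondecreasing, so the aggregated partial effect
  inherits the constraint.

The observation-level intercepts absorb extra-Poisson variation and can
be read as multiplicative overdispersion factors.  They are implemented
and tested but not part of the default battery: at the common df their
penalized RSS undercuts every structural learner once overdispersion
dominates the count-scale residual (in experiments they took >90% of
selections while the environmental terms froze), and since they
contribute nothing to new rows the out-of-bootstrap criterion cannot
regularise them.  Enable `random_intercept=True` in
`default_learner_specs` when the per-row factors are themselves of
interest.

**mstop by out-of-bootstrap risk.**  For each of `n_boot` (default 25)
bootstrap resamples of the rows, the path is refitted (knots and ridge
amounts kept from the full-data designs) and the mean negative Poisson
log-likelihood on the rows outside the resample is recorded along the
iteration grid (default 0, 25, …, 1500); the grid point minimising the
mean out-of-bootstrap risk is selected.

**Stability selection.**  The fit is repeated on 50 half-samples of the
municipalities (all rows of ⌊n/2⌋ municipalities drawn without
replacement).  A replicate "selects" the first q = 14 distinct
base-learners that enter its path (`m_iter` caps the path length);
learners whose selection frequency exceeds the threshold (default 0.5)
form the reported model.  The selection event must be sparse for the
frequencies to discriminate — marking everything chosen in a full-length
path labels nearly every learner in nearly every replicate.  q trades
power for specificity: it should comfortably exceed the number of terms
expected to be real (here 6 covariate signals plus the two surfaces).

## DVC index

The index for a municipality is `exp(Σ contributions of the selected
learners)` evaluated at its covariates and centroid: the multiplicative
change in expected DVCs per km relative to the stage-1 baseline.
Contributions are aggregated uncentered, so a never-selected learner
contributes exactly 1 and `exp(offset) × Π group factors` reproduces the
training fitted means to machine precision; centering constants are
stored separately and subtracted only in `predict_partial` for display.
Group factors (climate, land use, browsing, space, spacetime,
overdispersion) multiply exactly to the index; groups excluded from a
particular index variant (by default the 2009-only surface and the
overdispersion term, which is observation-specific and zero out of
sample) are reported as factor 1 so the identity always holds.  The
standard deviation of the log-factors across municipalities summarises
relative group importance.  Risk classes come from one-dimensional
k-means on the index (k = 7, 20 restarts, labels renumbered by ascending
class mean); k-means is run on the raw index scale so class boundaries
read directly as index values (a log-scale option exists).

## Browsing smoother

Sapling surveys give, per game-management district and palatability class
(spruce/pine, oak/fir, ash/maple/elm/linden, beech/other), the number of
examined and browsed saplings; cells are missing where a genus is absent.
Writing η_d for the district log-odds, the smoother maximises the
binomial log-likelihood minus (λ/2)·ηᵀKη with K the Laplacian of the
district adjacency graph — an intrinsic-CAR penalty on differences
between neighbours whose null space (constants) plays the role of the
intercept.  Estimation is penalized Newton with step halving (objective
ascent guaranteed, convergence 1e-8, log-odds capped at ±25 so that
boundary cells stay finite).  λ is fixed or calibrated by bisection so
the hat-matrix trace matches a target effective df (default
n_districts/4).  Districts with no data for a class inherit estimates
entirely from their neighbours; λ = 0 with missing cells is an error, as
is a disconnected component with no data.  Municipality covariates are
the smoothed value of the district containing the centroid — in the grid
world centroid containment coincides with district membership, which
collapses the real-data point-in-polygon subtlety.

## Validation stage

The municipality index is averaged per district (unweighted mean),
matched with harvest per 100 ha, and summarised by Spearman's rank
correlation (midranks; exact permutation p for n ≤ 8, t approximation
with n − 2 df otherwise) and a LOWESS trend (statsmodels: tricube-weighted
local linear regression, 3 bisquare robustness iterations, span 2/3,
evaluated at the sorted unique district means).

## Synthetic world

Municipalities are cells of an R×C grid (default 20×20); districts are
square blocks (default 4×4, i.e. 25 districts) with rook adjacency;
centroids are cell centres.  One master seed drives named independent
substreams (covariates, roads, browsing, spatial surfaces,
overdispersion, counts, survey, harvest), so any output is reproducible
in isolation.

* **Roads.**  Lengths are lognormal per type with means ordered
  residential ≫ tertiary > secondary > primary > motorway, and per-type
  absence probabilities (motorway 0.76 … residential 0.02) matching the
  relative frequencies of a large Central-European road network; absent
  pairs are dropped, giving ≈ 6.7 rows per municipality over two years.
* **Stage-1 truth.**  Baseline 0.15 DVC/km on residential streets,
  strong negative motorway contrast (fencing), +15% global 2009 effect,
  red-deer factor 0.76 for one contiguous block of districts (~15% of
  the area).
* **Covariates.**  Nine climate and ten land-use variables are smoothed
  Gaussian white-noise surfaces (σ = 2 cells) mixed with 50%
  municipality-level noise, standardised.  The noise share matters: with
  purely smooth fields the ~40 effective spatial degrees of freedom make
  distinct covariates mutually confounded and no method can attribute
  effects reliably.  Browsing covariates are logistic transforms of
  class-specific logit fields (baselines 10–40% browsed, smooth
  amplitude ≈ 0.5–0.6) with the same local-noise share; the district
  survey truth is defined as the block-mean logit of the same fields, so
  covariates and survey share one ground truth.
* **Effects.**  The default truth is sparse — 3 of 9 climate, 2 of 10
  land-use, 1 of 4 browsing effects nonzero — with log-scale amplitudes
  0.5/0.45/0.4 (climate), 0.35 (land use) and 0.3 (browsing, saturating
  and nondecreasing), plus a smooth spatial surface (amplitude 0.35,
  σ = 4) and lognormal overdispersion (sd 0.2).  The 2009-only surface
  is zero by default: the year effect is purely global.  The ordering
  climate > land use > browsing (the latter topping out near ±35%,
  i.e. up to roughly +50% risk from low to high browsing) is the group
  hierarchy the index decomposition is expected to recover.
* **Survey and harvest.**  75 saplings per district × class cell (one
  transect), 10% of cells dropped; district harvest per 100 ha is a
  saturating (Michaelis–Menten, plateau 10 animals, half-saturation at
  index 0.75) transform of the district-mean true index plus Gaussian
  noise (sd 0.8), so the index–harvest relation is near-linear for small
  indices and flat beyond ≈ 1.5.

What the generator does *not* emulate: real polygon geometry and road
topology, measurement error in collision geocoding, temporal correlation
beyond the shared covariates, hunting-effort variation in harvests, and
any calibration of covariate distributions to a real region.  Passing
tests therefore demonstrate correctness and statistical behaviour of the
*method* under controlled conditions, not predictive validity on any
particular landscape.

## Study designs used in tests and the acceptance script

* **Main analysis** (sparse-truth default world, 20×20, ≈ 2700 rows):
  OOB selection over {0, 25, …, 1500} with 25 bootstraps; stability
  selection with 50 half-samples, q = 14, threshold 0.5; index from the
  stability-selected learners; 100 harvest redraws for the validation
  power check (the fitted index is held fixed — the replicate-level
  randomness of that property is harvest noise).
* **Function recovery** (`recovery_study_config`): sine / quadratic /
  monotone truths with amplitudes 0.8 / 0.6 / 0.5 and the
  overdispersion and nuisance spatial channels off, measured at the
  OOB-selected mstop against the generator truth, RMSE evaluated at the
  observed covariate values (a uniform grid would let empty tails
  dominate).  The study isolates function estimation; spatial-surface
  absorption and overdispersion handling are exercised by their own
  tests.  Amplitudes are sized so the estimation-error budget at the
  OOB stop sits well below the 15%-of-amplitude bar; with weaker
  effects the measure is dominated by chance aliasing between smooth
  covariate fields and the spatial surface, an additive bias that no
  amount of data at this world size removes.
* **Smoother dominance**: 100 survey replicates on a 12×12/2 world
  (36 districts), total squared logit error of the smoothed versus raw
  (continuity-corrected) district proportions against the true field.
* **Smaller worlds** (6×6 to 12×12) are used where the property being
  checked does not depend on scale — closed forms, identities, limits,
  determinism — to keep the default test run around a quarter of an
  hour on one CPU.

## Known limitations

* Boosting with equal-df learners estimates partial effects with
  shrinkage bias at the OOB stop; slowly-converging terms (tail-heavy
  shapes, narrow-range covariates) retain visible bias.
* Selection among correlated smooth covariates splits credit; a
  duplicated covariate halves frequencies (documented behavior, tested).
* The stage-1 red-deer coefficient absorbs whatever environmental
  difference the red-deer block happens to have, since stage 1 ignores
  the environment by design; its recovery is unbiased only on average
  over landscapes.
* The MRF smoother's default df (n_districts/4) is a fixed calibration,
  not data-driven; per-class REML-type tuning would adapt better when
  classes differ strongly in spatial range.
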