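# Methods

`esens` implements an end-to-end workflow for building and evaluating
*unweighted ensembles* of ecosystem-service (ES) model outputs: harmonizing
heterogeneous rasters onto one grid, normalizing them, combining them into a
per-cell committee statistic with an uncertainty layer, scoring predictors
against validation observations, and testing spatial drivers of accuracy.
Because the real global model stacks and validation datasets are external and
large, the package ships a first-class synthetic-data generator that
reproduces the *statistical structure* the analysis assumes, so every stage
can be exercised and its properties demonstrated without downloads.

## The model of model error

Each synthetic model output is a distorted copy of a latent "true service"
surface `T` (a Gaussian-smoothed white-noise field, min–max scaled to [0, 1],
smoothing width `correlation_length` in cells; a width of 1 means i.i.d.
cells):

    M_k = g_k · T + w_own,k · B_k + w_shared · S + ε_k,

where `B_k` is a smooth bias surface specific to model k ("idiosyncratic"
bias from that model's construction), `S` a smooth bias surface shared by
all models (shared assumptions), and `ε_k` Gaussian noise with standard
deviation `noise_sd` (optionally spatially clustered, and optionally scaled
per cell by a coupling or "difficulty" field). A `coverage_fraction` below 1
removes cells at random to emulate partial spatial coverage; removed cells
are no-data. Throughout the package, **true zeros are data** and enter every
statistic, while no-data cells are always ignored.

This decomposition is what makes the committee ensemble informative: the
median across models cancels idiosyncratic terms (the *portfolio effect*)
but cannot cancel the shared term, so the ensemble's advantage shrinks to
zero as `w_shared` dominates — a behaviour the acceptance studies verify.

## Grid harmonization

All layers are brought to one cell-centre-registered geographic grid
(row 0 north, half-open cell extents). Coarsening takes the block mean with
no-data ignored (a coarse cell is no-data only if all members are);
refinement interpolates bilinearly between the four nearest coarse centres,
clamping to nearest-centre extrapolation at edges. A refined cell is no-data
if any centre with positive weight is no-data — no values are invented at
data edges. Alignment shifts layers by whole cells onto the target grid;
reprojection between CRSs is out of scope (all synthetic data share one
geographic CRS). Land-use masking (used to derive fuelwood/forage proxies
from carbon layers) sets cells outside the kept classes to no-data.

Rasters are serialized as ESRI ASCII grids (plain text, `%.17g`, so disk
round trips are bit-exact and pipeline reruns reproduce identical
checksums), with provenance in a JSON sidecar; validation units are GeoJSON.

## Normalization: double-sided Winsorising

Model outputs arrive in arbitrary native units. Each layer is normalized by
fitting the 2.5th and 97.5th percentiles of its data cells (linear
interpolation between order statistics), mapping them to 0 and 1, clamping
beyond, and rescaling linearly in between. On continuous data about 2.5% of
values map to exactly 0 and 2.5% to exactly 1. The same protocol is applied
to every observation/prediction vector before scoring, which makes the
accuracy statistic unit-free. Degenerate inputs (all values identical)
raise an error rather than guessing a scale.

## Ensembles and uncertainty

The ensemble is the per-cell median (default) or mean over the contributing
models' normalized values; even-count medians average the two central
values. Per-cell spread is the standard error of the mean,
`SEM(x) = σ(x)/√n(x)`, with `σ` the sample standard deviation (n − 1
denominator) and `n(x)` the number of models with data at x. SEM is
undefined (no-data) where fewer than two models contribute, rather than 0.
Ensemble values are then min–max rescaled to span the full [0, 1] range; the
SEM layer is deliberately left on its original scale. A per-model weight
vector can be plugged into the mean statistic as the extension point for
externally derived weighting schemes; the weighting algorithms themselves
are out of scope.

For accumulated-flow services, per-polygon sums (or the maximum, taken as
the flow out of a catchment's pour point) replace per-cell values. Zonal
membership is by cell centre, which makes sums exactly conservative over
any partition of the grid.

## Accuracy: the inverse of deviance

A predictor Y is scored against observations X (both Winsorised to [0, 1],
each on its own percentile cuts) with

    D = 1 − (1/n) · Σ_x |X(x) − Y(x)|,

i.e. one minus the mean absolute error; per-point accuracy is
`1 − |X(x) − Y(x)|`. Spearman's ρ is reported alongside as a rank-based
alternative. Predictions are extracted per unit as the polygon sum, the
containing cell's value (points), or the maximum within a radius of the
unit's reference location — without leaving the unit's own polygon when it
has one (the flow-routing correction for gauged catchments).

Predictors are compared by resampling units (default: subsampling without
replacement, 10% of units or a fixed count per run; with-replacement is
available behind a flag), scoring **every predictor on the identical
resample**, and testing per-run accuracy differences with paired t tests
under a Hochberg step-up correction. Note the per-run accuracies are not
independent across runs (resamples overlap); the procedure is deliberately
reported as-is, as a descriptive comparison device, not as an exact test.
The headline "improvement" number is the ensemble's overall D minus the
median of the models' overall D — the expected gain over picking a model at
random with no a priori information — expressed in percentage points.

Cross-service proxies score one service's ensemble against another
service's validation units; the *bundle* is the unweighted per-cell mean of
the member ensembles' normalized values (no-data ignored), rescaled to the
full range, then scored like any predictor.

## Drivers of accuracy

Whether accuracy varies with country-level development/equality metrics is
tested with a sequential (type-I) sum-of-squares linear model,

    D(x) ~ β0 + β1·Auto(x) + β2·Metric(x) + ε,

with the spatial-autocorrelation covariate entered first. `Auto(x)` is the
inverse-distance-weighted mean of D at all *other* points within a maximum
effect range of 5° (Euclidean distances in degrees between unit centroids;
coincident points dominate; points with no neighbour in range fall back to
the global mean). The exact functional form of such a covariate is a
genuine design choice; IDW was chosen as the simplest distance-decaying
summary and the implementation accepts a precomputed vector, so other
kernels can be substituted.

Metrics are transformed toward normality before testing: GDP per capita by
log10, proportion-like metrics (Gini, %-researchers, %-GDP-to-R&D) by
arcsine square root after scaling into [0, 1], and HDI untransformed. The
directional hypothesis — accuracy *increases* with development — is tested
one-sided (`p_one = p_two/2` when the slope is positive, `1 − p_two/2`
otherwise), and reported F values carry the slope's sign.

A two-factor interaction model adds income equality and its product with
GDP, using type-I SS between the Auto covariate and the factors and
type-III (partial) SS among the factors and interaction. The per-service
battery is five single-metric models plus the three interaction-model terms
— eight tests — corrected together by Hochberg's step-up rule with family
size m = 8 (the generalized rule `p_(k) ≤ α/(m − k + 1)` supports families
larger than the number of p values supplied).

To standardize degrees of freedom across services of very different unit
counts, any driver test can be run through a convergence bootstrap:
repeatedly subsample a standard 178 units without replacement, accumulate
the running mean of each factor's SS, and stop once *every* factor's
running mean has changed by at most 0.05% for 25 consecutive iterations
(the stricter per-factor reading of the stopping rule); F values are then
recomputed from the converged mean SS at the standardized degrees of
freedom. A hard iteration cap flags non-convergence on the result instead
of looping forever. When the data size equals the subsample size the
procedure provably reduces to the single fit.

## Synthetic validation data and countries

Validation units are points (the containing cell's truth value), polygons,
or catchments (truth summed over the unit's cells; catchments designate
their maximum-truth cell as the pour point). Observation noise is additive
Gaussian on the native scale, before normalization. Countries are a
k-means tiling of cell coordinates (contiguous, irregular, reproducible
regions) carrying five development metrics drawn from plausible
distributions (log-normal GDP per capita and researchers-per-million,
truncated-normal HDI, uniform Gini and R&D share). The Gaussian observation
noise and these metric distributions are modelling conveniences, not
inferences about the real datasets.

Setting `accuracy_coupling ≠ 0` scales each model's noise per cell by
`clip(1 + coupling · z, 0.05, ∞)`, where z is the standardized coupled
metric of the country containing the cell — so accuracy genuinely depends
on the metric, with sign and strength under experimental control;
`coupling = 0` yields a null world in which metrics are independent of
accuracy. A clipped linear multiplier was chosen over an exponential one
because it induces an approximately linear metric–accuracy relationship,
which is the alternative the one-sided driver test is designed to detect.

## Reference studies and their problem sizes

The studies in `esens.experiments` fix the package's reference conditions
(all seeds fan out from one base seed):

* **Portfolio effect** — 64×64 worlds, 9 models with idiosyncratic bias
  fields (weight 0.3, gains 0.85–1.15) and noise sd 0.15, scored at 150
  point units over 200 world seeds; the shared-bias variant zeroes all
  idiosyncratic terms and sets a common bias surface (weight 0.5).
* **SEM as accuracy proxy** — 48×48 worlds whose noise is heterogeneous on
  two axes: per-model sd 0.1–0.4 and a smooth per-cell "difficulty" field
  (amplitude 0.1–3.0) shared by all models; 400 point units, 100 seeds.
* **Driver calibration and power** — 32×32 worlds tiled into 178 countries,
  5 noise-only models (sd 0.3). Accuracy is evaluated at the *plot* scale
  (3 sampled plot cells per country, observations and predictions averaged
  over them and Winsorised) so unit sizes are equal and the per-unit error
  is governed by local model noise. The null study (coupling 0) uses 500
  worlds; its family-wise rejection rate is ≈5% in truth, so a 500-world
  estimate carries a Monte Carlo standard error of about 1 percentage
  point. The power study uses coupling −0.9 on HDI, which induces a
  realized metric–accuracy correlation of ≈0.45 at n = 178, over 200
  worlds.

These sizes keep the full suite and the reproduction script inside a few
minutes on one CPU while leaving comfortable statistical margins.

## Known limitations

* The synthetic worlds are stationary Gaussian constructions; real model
  error is non-Gaussian, non-stationary, and correlated with land cover,
  so passing studies demonstrate the *machinery and its statistical
  behaviour*, not real-world ensemble accuracy.
* No reprojection or datum handling; all grids share one geographic CRS.
* Catchments are polygon approximations with a designated pour-point cell;
  true flow routing and DEM-based delineation are out of scope.
* Weighted-ensemble algorithms (PCA, correlation-coefficient,
  regression-to-the-median, leave-one-out log-likelihood) are not
  implemented; only the per-model weight hook exists.
* The bootstrap comparison's paired t tests inherit the dependence of
  overlapping resamples, as described above.
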