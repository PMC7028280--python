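# Methods

## Model

Annual-average concentrations are modelled on the square-root scale, where
their distribution across a national monitoring network is close to Gaussian.
For sqrt-scale observations $y$ at sites $s_1,\dots,s_n$ the model is
universal kriging:

$$ y = X\beta + \eta, \qquad \eta \sim \mathcal N(0, \Sigma), $$

with mean design $X = [\,1 \mid T\,]$, where $T$ holds a small number of
partial-least-squares (PLS) summary predictors of the geographic covariates,
and exponential residual covariance

$$ \Sigma_{ij} = \sigma^2 e^{-d_{ij}/\phi} + \tau^2\,\mathbf 1(i = j), $$

parameterised by the range $\phi$ (km; distance scale of spatial
correlation), the partial sill $\sigma^2$ (spatially structured variance) and
the nugget $\tau^2$ (non-spatial variance), all on the sqrt scale.  With no
covariates ($X = 1$) the model reduces to ordinary kriging.

Covariates offered to PLS are chosen by greedy forward selection: at each
step the variable that most reduces the residual sum of squares of the linear
model of $y$ on the selected set is added.  The selection criterion is a
deliberate design choice — refitting the full PLS + kriging model for every
candidate at every step would require hundreds of thousands of
maximum-likelihood fits per sweep and the selection exists only to feed PLS —
so selection is a fast linear-model screen and PLS/kriging see the chosen
subset.  Greedy forward selection is nested: the $k$-variable subset is a
prefix of every larger one, which the sweep exploits.

All parameters ($\beta$, $\phi$, $\sigma^2$, $\tau^2$) are estimated by
maximum likelihood (not REML; a `reml` variant is deliberately not offered).
$\beta$ is profiled out by generalised least squares, and the concentrated
likelihood is optimised over $(\log\phi, \log\sigma^2, \log\tau^2)$ with
L-BFGS-B under bound constraints ($\phi \in [1\,\mathrm{km},\,10\times$
domain diameter$]$, variances within $[10^{-6}, 10^{3}]\times$ the residual
variance).  Three starting points are used: a moment/variogram-informed
start (short-distance semivariance → nugget, remainder → partial sill,
distance at 63% of the sill → range), an even variance split at half the
median inter-site distance, and a wide-range start.  The best local optimum
is kept; non-convergence of individual starts is flagged, not raised.

Two numerical choices matter in practice:

* **Ridge jitter.** $10^{-10}(\sigma^2+\tau^2)$ is added to the covariance
  diagonal before Cholesky factorisation.
* **Nugget-boundary tie-break.** At ranges below the inter-site spacing a
  positive partial sill is likelihood-equivalent to nugget, so on data
  without spatial structure the optimiser can land anywhere on that flat
  ridge and arbitrarily label non-spatial variance as "spatial".  When a
  pure-nugget model comes within 0.5 log-likelihood units of the optimum,
  the fit is therefore snapped to the nugget-only boundary.  On data with
  genuine spatial structure the spatial model wins by far more than 0.5 and
  the tie-break never fires.

Prediction is the universal-kriging BLUP
$\hat y_0 = x_0'\hat\beta + c_0'\Sigma^{-1}(y - X\hat\beta)$ with the
standard prediction variance (including the nugget, i.e. for a new
measurement), evaluated in chunks so large prediction sets never build an
$n \times m$ dense block.  The nugget enters covariances only at identically
zero distance; predictions at monitor locations therefore shrink to the
observation as $\tau^2 \to 0$ and interpolate exactly at $\tau^2 = 0$.
Native-scale predictions square the sqrt-scale BLUP after flooring negative
values at zero (the floor count is surfaced).  Prediction uncertainty is
reported on the sqrt scale only; no native-scale transform of the kriging
variance is defined here.

## PLS summary predictors

PLS components maximise covariance between the standardised covariates and
the sqrt-scale response; unlike principal components they are
response-guided.  Fitting is delegated to scikit-learn's NIPALS
implementation (validated against an independent NIPALS reference in the
test suite); component signs are fixed by making the largest-magnitude
weight positive so folds are comparable.  Defaults are 2 components for
conventional-CV model building and 3 for spatially clustered CV, exposed as
configuration.  Covariate scaling statistics are always estimated on
training sites only and reused verbatim at prediction locations.  The exact
covariance-free limit (response orthogonal to every covariate) falls back to
principal axes with zero response loadings.

## Covariate screening

Before modelling, variables with no spatial variability (identical 10th and
90th percentiles — this also removes rare-event indicators such as a
binary variable that is 1 at under 10% of sites) or fewer than 10 distinct
values are excluded, with reasons recorded.  Percentiles use linear
interpolation between order statistics and the equality test is exact, so
the decision is bit-stable.  `min_unique = 10` is a conservative reading of
"few distinct values" against networks of hundreds of sites.  Missing
covariate values are rejected at load rather than imputed.

## Model evaluation

* **Conventional 10-fold CV** randomly partitions sites (fold sizes differ
  by at most one): performance at a random location amid the network.
* **Spatially clustered 10-fold CV** uses k-means clusters of the site
  coordinates (20 restarts, best inertia) as folds: performance far from any
  monitor.
* **Buffer-out CV** scores a leave-one-out prediction per site after
  removing every site within a radius (50/100/200/300 km default) from
  training; sites whose training set falls below 10 are skipped and counted.

In the main analysis, scaling, selection and PLS estimation are done once on
all sites and only the regression/covariance parameters are re-estimated per
training fold; a `selection_inside_cv` flag repeats the entire
model-building chain inside each fold for the stricter evaluation.

Statistics are computed on the native concentration scale after
back-transformation (their units are concentration units, which is how such
tables are reported): RMSE; standardized RMSE (RMSE over the mean observed
concentration, comparable across pollutants); and the MSE-based
$R^2 = \max(0,\, 1 - \mathrm{MSE}/\mathrm{Var}(y))$ with population variance
(divide by $n$) for scale consistency with the MSE.  The MSE-based $R^2$
measures agreement about the 1:1 line and is truncated at zero — a model
worse than predicting the mean scores 0.  The share of prediction carried by
the PLS predictors is
$\sum_i |P_i| / (\sum_i |P_i| + \sum_i |K_i|)$ where $P_i$ is the
non-intercept regression contribution and $K_i$ the kriging adjustment of
held-out prediction $i$; this decomposition-based definition is this
package's own choice (reported as NaN when both sums vanish).

## Annual-average completeness rules

A day of hourly gas data is valid with ≥ 18 valid hours; the ozone metric is
the daily maximum over 8-hour windows starting at hours 0–16 (windows never
cross midnight, require ≥ 6 valid hours, and average their valid hours; the
day needs ≥ 18 operating hours and one contributing window).  An annual
average requires ≥ 244 / 61 / 41 valid days for every-day / 1-in-3 / 1-in-6
schedules and no more than 45 consecutive calendar days without a valid
measurement.  The gap is measured in calendar days regardless of schedule
(so a healthy 1-in-6 record with 5-day gaps passes) and includes the
leading and trailing stretches of the year; the same absolute thresholds
apply in leap years.  The ozone season average (May 1 – Sep 30, 153 days)
requires ≥ ⌈2·153/3⌉ = 102 valid season days and a gap of at most
round(45·153/365) = 19 days — the season rule is this module's own scaling
of the annual criteria, since only the season window itself is standard.

## Synthetic study conditions

The generator emulates the national monitoring problem with known truth:

* **Sites:** 300 monitors in 10 Gaussian clumps (sd 30 km) with uniform
  clump centres on a 1000 × 1000 km planar domain, coordinates reflected at
  the edges.  Coordinates are planar km throughout; lon/lat inputs are
  projected (equirectangular about the centroid) at load time.
* **Covariates:** 350 columns, 10 informative.  Every column — informative
  or not — is a spatially smooth surface (a sum of Gaussian bumps, width
  10 km, enough bumps to tile the domain) standardised to unit variance;
  informative columns add 10% white noise, and irrelevant columns share
  pairwise correlation 0.3 through one common surface.  The 10 km width is
  far below inter-clump distances, emulating locally driven covariates
  (traffic, land use): a model that observes the covariates can predict far
  from monitors while spatial interpolation alone cannot.  That irrelevant
  covariates are *spatially structured* is essential — spatially structured
  nuisance surfaces produce chance correlations within training regions
  that fail to generalise to held-out clusters, which is what penalises
  all-variable models under clustered CV; white-noise columns would simply
  average out in PLS.
* **Response:** sqrt-scale value = 6 (intercept) + Z·β + field, with β
  magnitudes 0.45 ± 50% and random sign on z-scored covariates, and a
  Gaussian residual field with exponential covariance (range 100 km, partial
  sill 0.3, nugget 0.1) drawn through a dense symmetric factorisation.
  Negative sqrt draws are clipped at zero and counted so the generator is
  total.  Native values (≈ 41 ± 21 in concentration units) are the squares.
* **Time series:** hourly values (base level + diurnal cycle + 5% noise) on
  1-in-1/3/6 schedules with configurable whole-day and within-day
  missingness, feeding the completeness rules.

What the generator does **not** emulate: satellite-retrieval grids, real
land-use rasters, temporal trends across years, non-Gaussian residuals,
covariate distribution shift between monitors and prediction locations, and
measurement-error heteroscedasticity.  Passing recovery tests on this
synthetic family therefore demonstrates correctness of the estimation and
evaluation machinery under the model's own assumptions, not fidelity of any
particular real-world exposure surface.

## Problem sizes in the checks

The bundled end-to-end checks use: 50 replicates of 300 uniform sites for
covariance-parameter recovery against truth (200 km, 4, 1) with known mean
(median |log(est/true)| per parameter; the ML range estimate on a single
field realisation is intrinsically noisy at a 5:1 domain-to-range ratio —
its population median error is ≈ 0.25 on the log scale); 20 random
instances of ≤ 25 sites for dense-oracle agreement; one 300-site / 350-
covariate dataset for the clustered-CV parsimony pattern (subset sizes 0,
10, 20, 30, all); 20 replicates of 150 sites / 60 covariates for the
conventional-versus-clustered ordering; and 20 replicates of 400 sites /
100 covariates with 3 strong informative variables for forward-selection
recovery.  These sizes keep a full run on one CPU in a few minutes while
leaving each check's Monte-Carlo noise well inside its margin.

## Known limitations

* The selection criterion (linear-model RSS screen) is not guaranteed to
  match a selection that evaluates kriging in the loop.
* ML covariance estimates at small n are biased low in the partial sill;
  no REML option is provided.
* The buffer-out scheme refits one model per site and is quadratic-ish in
  n; it is intended for sensitivity analyses, not routine sweeps.
* The equirectangular projection for lon/lat inputs distorts distances at
  continental scale by up to a few percent; no geodesic distance option is
  threaded through the kriging itself.
* `k_vars` below the configured number of PLS components silently reduces
  the component count to `k_vars`.
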