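# Methods

This note records the models implemented in `pm25risk`, the defaults and
why, the numerical choices, and what the synthetic-data experiments do and
do not demonstrate.

## The regression model

The concentration model is a single-hidden-layer feed-forward network,
`H_j = f(Σ_i ω_ij x_i − α_j)` with the standard logistic
`f(t) = 1/(1+e^−t)` and a linear output `O_k = Σ_j H_j ω_jk − b_k`.
Thresholds are subtracted, following the classic formulation. Some printed
statements of this formulation give the activation as `1/(1+e^x)`; that
form is decreasing and inconsistent with the logistic it is said to be, so
the standard sigmoid is used.

Inputs are min-max normalized to [0, 1]; targets to [0.1, 0.9] so that the
inverse map is stable at the edges of the training range. Weights start
uniform(−0.5, 0.5) from the run seed; thresholds start at zero. The hidden
width defaults to `2n+1` for `n` inputs — a common heuristic; nothing in
the package is sensitive to it at these problem sizes. Features are the
seven covariates (temperature, precipitation, wind, SO2, NO2, GDP,
population density); station coordinates are deliberately excluded so the
model is a time-series regression, not a spatial one.

### Training algorithms

* **`gd`** applies the classic per-sample update rules in presentation
  order, reshuffled each epoch. These rules are implemented verbatim,
  including two idiosyncrasies of the classic statement: the threshold
  updates carry the opposite sign of a strict gradient derivation, and the
  output-threshold update has no learning-rate factor. As printed, the
  output-threshold rule is numerically divergent (each visit doubles the
  output error), so a `strict_bias_update=False` switch applies the learning rate
  to that update too; the verbatim form remains the default for fidelity,
  and every convergence-oriented use of `gd` in tests and examples sets the
  switch. Even then the method crawls: it exists as a baseline, not as the
  recommended trainer.
* **`trainrp`** is resilient backpropagation in its sign-only form: each
  parameter keeps its own step `Δ`, grown by `η+ = 1.2` when the gradient
  sign repeats (capped at `Δmax = 50`), shrunk by `η− = 0.5` on a flip
  (floored at `Δmin = 1e−6`, sign memory reset), and the parameter always
  moves by `−Δ·sign(g)`. The constants are the field-standard defaults;
  the initial step is `Δ0 = 0.07`. Because the update never backtracks,
  the iteration oscillates near an optimum; on a noise-free toy its SSE
  floor is around 1e−4 on the normalized scale, which is far below any
  statistically meaningful residual but not machine precision. The best
  visited parameters are returned if the final iterate is worse.
* **`trainlm`** is Levenberg–Marquardt on the full-batch residual vector:
  solve `(JᵀJ + βI)d = −Jᵀe`, accept the step only if the SSE decreases
  (then `β /= 10`), otherwise inflate `β ×= 10` and retry, at most 30
  inflations per iteration. `JᵀJ` stands in for the exact Hessian (the
  Gauss–Newton surrogate) and the damping metric is the identity; the full
  step is always taken. `β0 = 1e−3`. A gradient below `1e−12·max(1, SSE)`
  is treated as stationary. Accepted steps never increase the SSE by
  construction, which the tests assert on every trace.

Both batch optimizers consume the analytic gradient/Jacobian of SSE/2,
which is finite-difference verified to relative error ≤ 1e−5 in the test
suite. Training stops when the epoch SSE on normalized targets reaches
`tol` (default 0, i.e. run to `max_epochs`).

### Prediction protocol

Forecasting is fit-then-forecast: the normalization fitted on the training
covariates is frozen and applied to projected future covariates; the
network is never refitted. Two safeguards are applied at prediction time,
both on by default and recorded in the saved model:

* inverse-normalized concentration predictions are clipped at zero
  (`clip_nonneg`) — concentrations are physical;
* normalized inputs are clamped to the training range (`clip_inputs`) —
  a logistic network extrapolates non-monotonically outside the covariate
  support it was trained on, and projected covariates under aggressive
  scenarios can leave that support. Clamping freezes the response at the
  support edge instead, which keeps scenario analyses (e.g. declining SO2)
  directionally sensible.

## Validation statistics

Per-station Pearson r, index of agreement
`IA = 1 − Σ(S_i−O_i)² / Σ(|S_i−Ō|+|O_i−Ō|)²` (in [0, 1], 1 iff exact
agreement), mean bias error (positive = over-forecast) and RMSE, all on the
concentration scale after inverse normalization. Undefined cases (constant
series, vanishing IA denominator) are reported as an explicit `undefined`
marker, never silently as zero.

## Screening

The correlation stage reports pairwise Pearson r over complete rows with
two-sided p-values from the t-transform `t = r√((n−2)/(1−r²))`, flagged at
0.05/0.01. The PCA stage standardizes variables, eigendecomposes the
correlation matrix, retains components by the Kaiser eigenvalue>1 rule
applied to the unrotated eigenvalues (a `kaiser_after_rotation` switch
re-applies it to rotated sums of squares; a `n_components` argument
overrides the rule) and varimax-rotates the retained loadings by pairwise
Jacobi sweeps to a criterion tolerance of 1e−8. Column signs are fixed so
the largest-magnitude loading is positive; rows with missing values are
dropped listwise.

A fact worth recording: the eight-variable correlation targets the
generator reproduces have eigenvalues (3.63, 1.92, 0.69, 0.67, …) — only
two exceed one, so the Kaiser rule retains two components at ≈70%
cumulative variance. Retaining four components instead explains ≈86.4% of
the variance; published analyses of this variable set report exactly that
four-component figure, which is therefore a retention *choice*, not a
consequence of the eigenvalue rule. Cumulative percentages are computed
from rotated sums of squared loadings; the total over all retained
components is rotation-invariant.

## Spatial machinery

IDW with power 2 over all stations (12 points need no neighborhood
restriction; a `k_nearest` option exists), grid 200×200 cells over the
station bounding box padded 10% by default — the source analyses state
neither power nor resolution, so these are package defaults, recorded in
run manifests. A cell within 1e−9 km of a station takes the station value
exactly. All coordinates are planar km; no geodesy.

Jenks natural breaks are computed by the exact O(kn²) dynamic program on
sorted values (verified against exhaustive partition enumeration for small
n). Classifying a raster with more than 4000 valid cells uses an evenly
spaced quantile subsample of the sorted cell values — deterministic, and
the breaks of a 4000-point quantile skeleton are indistinguishable from the
exact ones at map scale. Class intervals are closed on the right; k = 3
carries labels low/moderate/high.

## Exposure risk

`ADD = C·IR·ED/(BW·AT)`, `SFI = UR·BW·IR`, `R_i = ADD·SFI`,
`POP_risk = R_i × population density`, with defaults IR = 11.7 m³/day,
UR = 0.008 per μg/m³, BW = 57 kg, ED = AT (under which `R_i = C·IR²·UR`
exactly — asserted as an identity in tests). ED and AT remain explicit
parameters so unequal-duration scenarios stay expressible. UR is printed in
the source literature with unit "μg/m³"; it is used as per-(μg/m³), the
only dimensionally sensible reading. Risk maps inherit the IDW grid;
population-density surfaces come from IDW over station-area densities, and
future densities from the covariate projector (geometric trend is the
natural choice for demographic growth).

## Synthetic data: what it emulates and what it does not

The generator draws daily standard-normal latents per station from a
Gaussian copula and pushes them through monotone marginals: lognormal for
SO2, NO2, precipitation, wind, GDP and population density; linear for
temperature; linear-truncated-at-zero for PM2.5 (mean 100, SD 50 μg/m³ —
an inland industrial city's distribution; the truncated fraction is ≈2%
and is reported in `df.attrs`). Because nonlinear marginals attenuate
Pearson correlation, the latent correlations are calibrated pair by pair
(Gauss–Hermite quadrature + root finding, NORTA-style) so the
*post-transform* correlations hit the targets; the calibrated matrix is
projected to the nearest correlation matrix if rounding makes it
indefinite.

Seasonality enters as a deterministic driver: the day-of-year cosine
(peaking mid-July) mapped through van der Waerden normal scores, so its
empirical distribution over the sampled dates is exactly Gaussian and the
copula calibration stays exact even over partial years. Every variable
loads on the driver proportionally to its target correlation with
temperature, scaled by `season_strength = 0.7` (temperature's seasonal
share of variance ≈ 0.7² — winters near 0 °C, summers near 27 °C, and the
seasonal PM2.5 contrast of ≈70 μg/m³ between winter and summer that makes
the winter > summer ordering checks meaningful). Station heterogeneity is
a station-level random effect with the same correlation structure,
`station_sd = 0.15` of the daily variance — enough spatial contrast for
interpolation and risk zoning without disturbing the pooled correlations.

PM2.5 is generated as `response(covariates) + N(0, noise_sd)`, truncated at
zero. The default response (`copula_mean`) is the conditional mean implied
by the copula: each covariate is mapped back to its latent score (a log
transform for the lognormal channels — smooth and nonlinear in the raw
covariates), combined with the conditional-mean coefficients, and rescaled
to concentration units. The default `noise_sd` is the conditional residual
SD (≈25 μg/m³, residual share 1−R² ≈ 0.25), which makes the full
eight-variable correlation matrix — PM2.5 rows included — converge to the
targets. This is the only response/noise pair with that property, which is
why it is the default rather than a free choice. The conditional-mean
coefficients are partial effects: temperature, precipitation and SO2
dominate with the expected signs; the GDP coefficient is slightly negative
(−0.03) even though the marginal GDP–PM2.5 correlation target is +0.029 —
a standard marginal-vs-partial reversal, accepted as is because correlation
fidelity is the property under test. A second registered response
(`so2_identity`) equates mean PM2.5 with the SO2 channel for plumbing
tests.

What passing tests on this data do **not** show about real data: daily
precipitation here is lognormal (no dry days or zero inflation), GDP and
population density fluctuate daily around a station level instead of being
annual constants, there is no spatial correlation in the daily weather
beyond the shared seasonal cycle and station effects, no trend (the
stationary generator means trend projections fitted on it reflect noise,
which is why scenario analyses use the constant projection plus explicit
annual factors), and no measurement error structure. The generator
demonstrates that the *pipeline* recovers a known smooth response under
realistic correlation structure and noise — not that a network trained on
any particular city generalizes.

## Pipeline defaults and problem sizes

The pipeline aggregates daily records to station-month means (arithmetic
mean), trains one pooled network on the station-months, and evaluates on a
chronological 80/20 split of the months, per station. Defaults: 12
stations, 730 days, trainlm with 200 epochs, horizons +7 and +12 years
(mirroring a base-year → five/ten-years-ahead design), 200×200 rasters.
The worked examples and the acceptance script use two to three years of
daily data, 40–80-cell rasters and 80–600 training iterations — sizes
chosen so a full analysis reruns in seconds while leaving the statistical
conclusions unchanged. Covariate projection needs at least two calendar
years of history; with only two, per-month linear trends interpolate two
points exactly and extrapolate their noise, so three or more years (or the
constant projection with scenario factors) is recommended for forecasts.

Run manifests record configuration, seed and content hashes of every
artifact, and contain no timestamps: a configuration and seed reproduce a
run byte for byte. Wall-clock timings go to `run.log`, outside the
manifest.
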