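# Methods

`lagrisk` implements three model families for estimating delayed health
effects of an environmental exposure from daily time series — the setting
is daily respiratory hospitalization counts versus the daily maximum 8-h
mean ozone concentration (µg/m³), with temperature, relative humidity,
wind speed, weekday and season as covariates.

Throughout, day 0 is the event (hospitalization) day and lag *l* refers to
exposure *l* days earlier; the maximum lag is L = 21 days. Rows whose lag
history reaches before the start of the series are excluded from every fit
(no imputation), so all model families are compared on the same n − L
rows.

## Model families

### Almon polynomial distributed-lag regression

The unconstrained distributed-lag model
y_t = ε_t + Σ_{l=0}^{L} β_l x_{t−l}
is nearly unidentifiable for smooth exposure series because adjacent lags
are heavily collinear. The Almon device constrains the lag coefficients to
a degree-p polynomial in the lag,
β_l = α_0 + α_1 l + … + α_p l^p,
so the fit reduces to OLS on the p+1 transformed columns
z_{t,j} = Σ_l l^j x_{t−l}. Lag coefficients and their covariance come from
the exact linear map β = Hα, H[l,j] = l^j, hence
vcov(β) = H vcov(α) Hᵀ. The constraint is applied over l = 0…L (lag 0
included — the event day matters). Counts are treated as continuous here by
design; this family predates the count models. Degree selection minimizes
the Gaussian AIC (−2ℓ + 2(k+1), σ² counted) over a candidate list. No
endpoint constraints (β_{L+1} = 0 variants) are imposed.

### Quasi-Poisson distributed-lag GLM

log E(y_t) = β_0 + Σ_l β_l x_{t−l} + season + weekday + temp + rh + wind,
with astronomical-season indicators (winter reference), weekday indicators
(Monday reference) and same-day linear meteorology. Daily counts are
overdispersed (Var > mean), so the working family is quasi-Poisson:
coefficients as Poisson, covariance inflated by the Pearson dispersion
φ̂ = Σ (y−μ̂)²/μ̂ / (n−k). The lag-specific relative risk of an increment
Δx is RR_l = exp(Δx·β_l) with a delta-method interval; the default
increment is 50.3 µg/m³, the interquartile range of daily max 8-h ozone in
the motivating study window.

### Distributed-lag non-linear model (DLNM)

Both the exposure-response and the lag-response are given spline bases and
their tensor product (the cross-basis)
c_{jk}(t) = Σ_{l=0}^{L} R_j(x_{t−l}) C_k(l)
enters a quasi-Poisson regression together with cubic B-spline smooths of
temperature, humidity and wind, a long-term seasonality natural spline on
the day index, and weekday indicators. Choices:

- **Exposure basis R**: natural cubic spline, interior knots at the 10/50/90
  or 10/75/90 percentiles of the exposure (both variants are fit and the
  lower quasi-AIC retained), boundary at the data range. A natural spline is
  linear beyond its boundary, so relative risks remain defined above the
  observed range — needed for contrasts against the 120 µg/m³ limit value.
- **Lag basis C**: natural cubic spline on 0…21 with interior knots at the
  log-spaced lags (1, 3, 9) and an intercept column, a standard DLNM
  lag-dimension choice.
- **Seasonality**: natural spline on the day index with 12 equally spaced
  interior knots across the 608-day window (≈7 per year), absorbing slow
  trends; climatic-season labels are therefore not covariates in this model.
- **Covariate smooths**: cubic B-splines with 3 interior knots at the same
  percentile set as the exposure, no intercept column (a single global
  intercept serves the whole model).

The lag-specific RR of x* versus a reference x_ref is
log RR(l) = Σ_{jk} η_{jk} [R_j(x*) − R_j(x_ref)] C_k(l),
with delta-method intervals from the scaled covariance; a cumulative RR
over a lag window sums log RR(l) with the summed weight vector (lag
correlations accounted for). By construction RR at the reference is exactly
1 at every lag. The default contrast is +10 µg/m³ against 120 µg/m³ (the EU
daily max 8-h limit value); median-centered whole-curve output is available
through the same interface.

## Inference engine

One IRLS implementation serves all count fits: log link, working response
z = η + (y−μ)/μ, weights μ, convergence when the relative deviance change
falls below 1e-9 (max 100 iterations), fitted means floored at 1e-10.
Columns are internally scaled to unit norm and the covariance is built from
the R factor of the weighted design, which keeps the cross-basis +
seasonality designs (condition numbers ~1e8) numerically sound; results
are identical to the unscaled algebra. Rank deficiency (reciprocal
condition < 1e-10 in the pivoted QR) raises an error naming the dependent
columns. The quasi-AIC convention is

  qAIC = −2ℓ/φ̂ + 2(k+1)   (quasi-Poisson; φ̂ counted as a parameter)
  AIC  = −2ℓ + 2k          (Poisson; dispersion fixed at 1)

with ℓ the Poisson log-likelihood at the fit. Only Δ-qAIC between models
matters; for nested comparisons `quasi_aic` accepts a shared dispersion
(conventionally from the largest model). No offsets are used (the
population is treated as constant over a 1.67-year window) and no
autocorrelation-robust errors are provided.

## Basis construction

- Percentile knots use the linear-interpolation percentile definition;
  collapsing knots (ties) raise rather than silently merging.
- B-splines are Cox–de Boor (via `scipy.interpolate.BSpline`), degree 3 by
  default; with an intercept the rows sum to one inside the boundary and
  evaluation outside the boundary is an error.
- Natural cubic splines use the textbook truncated-power construction
  (N_k = d_k − d_{K−1} with d_k(x) = [(x−ξ_k)₊³ − (x−ξ_K)₊³]/(ξ_K − ξ_k)),
  which is linear beyond the boundary knots by construction. Evaluation
  happens on the knot-normalized scale (x − ξ_1)/(ξ_K − ξ_1) — a fixed
  affine reparameterization determined by the boundary alone that leaves
  every model span and every contrast unchanged while keeping cubic columns
  O(1). With no interior knot the basis degrades to linear with a warning.

## Synthetic data generator

The generator produces the study conditions the models assume, for a
southern-Poland-style window of 608 days from 1 January 2016:

- **Temperature**: 9 + 11·sin(annual phase peaking late July) +
  AR(1)(ρ=0.7, σ=3) °C.
- **Ozone (daily max 8-h)**: 70 + 1.5·(temp−9) + 6·s(t) +
  24·max(0, g_t)·max(0, s(t))² + AR(1)(ρ=0.5, σ=12), clipped at 0, where
  s(t) is the annual sinusoid and g_t an AR(1)(ρ=0.55) episode process. The
  half-normal episodic term reproduces the clustered summer photochemical
  episodes seen in monitoring data: all-period median ≈ 70 µg/m³, summer
  monthly medians in the 90s, and a few tens of days per window above the
  120 µg/m³ limit. The realized annual IQR (~36 µg/m³) is below the ~50 of
  the motivating monitoring record: a sinusoid-plus-episodes model cannot
  deliver that IQR without pushing summer medians far above their observed
  envelope, and the summer level/exceedance structure is what the threshold
  analyses are sensitive to, so it takes priority.
- **Humidity / wind**: anti-correlated with temperature, clipped to
  [30, 100] %; log-normal(ln 0.8, 0.6) m/s.
- **Counts**: log μ_t = log(baseline) + Σ_l f(x_{t−l}, l) + weekday +
  seasonal cosine (winter-peaking, amplitude 0.15). Truths: null, linear in
  (x − reference), threshold (linear in max(0, x−120)), or quadratic. φ > 1
  overdispersion is realized by a negative binomial with Var = φμ (the
  quasi-Poisson moment assumption; quasi-likelihood itself has no generative
  form). The first 21 days use wrapped pre-history (the window's own first
  21 exposure days recycled before day 0) so simulated and fitted sample
  sizes line up.

The **headline scenario** is a threshold truth with RR exactly 1.15 per
10 µg/m³ above 120 at lag 2 and half the log effect at lags 1 and 3,
baseline 7.7 events/day, φ = 1.3 — the shape and scale of the effect the
motivating analysis reports, used for recovery experiments (the registry
data themselves are not available and are not reproduced).

What the generator does **not** emulate: multi-pollutant correlations
(PM, SO₂, NO₂ …), holidays, long-term trends beyond one window,
measurement error in the monitoring data, and the left-skewed winter ozone
tail. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated data-generating process, not validity of any
epidemiological conclusion about real registries.

## Known limitations

- **Smooth-basis attenuation of kinked truths.** The cross-basis spans
  smooth surfaces. When the true exposure-response has a kink (zero below a
  threshold, linear above) and the lag profile is spiky, the quasi-Poisson
  fit converges to the best smooth approximation, which under-states the
  local contrast at the kink: in the headline scenario the mean estimated
  RR(lag 2, 130 vs 120) is ≈1.07 against a true 1.15, regardless of sample
  size, and the delta-method intervals — which quantify variance, not
  approximation bias — then under-cover. This is a structural property of
  parametric spline DLNMs, visible in the acceptance suite, not an
  estimation bug: fitting the exactly-true threshold structure through the
  same cross-basis and prediction code recovers the truth without bias.
- The Wald block test for the cross-basis uses the χ² reference
  distribution; with estimated dispersion it is mildly conservative at this
  sample size.
- Model selection by qAIC across the two percentile-knot variants compares
  equally sized models; qAIC values are not comparable across families
  (Gaussian AIC vs count qAIC), and the comparison table says so.

## Problem sizes

Simulation-based checks run at the design scale: 608-day series, lag 21,
100–200 Monte-Carlo replicates for recovery, coverage and type-I error;
surface-recovery checks use n = 600 against n = 5000 to verify error
shrinkage. These sizes give Monte-Carlo standard errors comfortably inside
the asserted ranges.
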