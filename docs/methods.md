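# Methods

This note documents the statistical machinery implemented in `anthrorisk`,
the choices made where the methodology leaves room, and what the synthetic
cohorts do and do not establish.

## 1. Allometric indices

Body measurements scale with overall body size by approximate power laws.
The package's general engine fits, by weighted least squares on natural
logarithms,

    ln C = b0 + bH · ln H + bW · ln W + bF · f ,

where C is a circumference (cm), H height, W weight (kg) and f a female
indicator. The normalized index divides the fitted size dependence out and
re-expresses the circumference at a reference body size:

    index = C · (H/⟨H⟩)^(−bH) · (W/⟨W⟩)^(−bW) .

At (⟨H⟩, ⟨W⟩) the index equals the raw circumference; within a fitting
sample (and sex) its log is an affine function of the regression residual
and therefore uncorrelated with ln H and ln W.

The shipped default hip model is `HIP_MODEL_NHANES3`
(b0 = 2.658, bH = −0.310, bW = 0.482, bF = 0.083, ⟨H⟩ = 166 cm,
⟨W⟩ = 73 kg, R² = 0.887). **Unit convention:** the intercept is on the
scale with the circumference in cm and *height in metres* — the published
intercept is only arithmetically consistent with metres (it predicts
HC ≈ 100 cm at H = 1.66 m, W = 73 kg), so the fitter converts height to
metres inside the log regression. Index application uses only the
scale-invariant ratios H/⟨H⟩ and W/⟨W⟩. BMI = W/H² (kg/m²) and
ABSI = WC / (BMI^(2/3) · H^(1/2)) (metre-kg units, population values
≈ 0.08) are special cases of the same normalization idea; WHR = WC/HC is
provided for comparison.

The sample-weight question (whether the published regression was
survey-weighted) is unresolved in the source; the default here is weighted,
with `use_sample_weights=False` available. Reference height/weight default
to the weighted means rounded to integers (matching 166/73); exact means are
available via `round_reference=False`.

## 2. Reference normalization

Index values are standardized to z-scores within sex and age bin:
z = (value − cell mean)/cell SD. Defaults:

* **Bins:** 5-year bins from age 18 with a terminal open bin ([83, ∞));
  configurable width. The source does not state its binning granularity, so
  this is a declared approximation (no LMS/Box–Cox smoothing).
* **SD convention:** frequency-weighted population SD (denominator = total
  weight) because the table describes a population; the n−1 convention is
  available.
* **Out-of-range ages:** error by default; `clamp_age=True` maps them to the
  nearest covered bin, the policy used when scoring an external (older)
  cohort against another population's normals.
* **Empty/degenerate cells:** flagged and refused at use time; no
  interpolation across bins.
* **Percentiles:** normal method 100·Φ(z) by default; an empirical weighted
  ECDF method is available when a reference cohort is attached.

Correlation diagnostics are weighted Pearson matrices of raw values and of
z-scores, exportable in the combined upper-raw/lower-z triangle layout.

## 3. Cox fitting on the age timescale

Age is the timescale, so subjects enter the risk set at their examination
age (delayed entry) and leave at death or censoring age. The partial
likelihood uses the **Efron correction** for tied event ages (many ties are
expected on a yearly-ish age scale; the source is silent, Efron is the safer
default) and **case weights** for survey weights; variance is model-based
(no survey cluster/robust correction). Risk-set sums are computed as
differences of suffix sums over exit- and entry-sorted subjects, and the
observed information is accumulated by sweeping per-event coefficients back
onto subjects with prefix sums, making one Newton iteration O(n·p) — fits on
20,000 subjects take seconds. Newton iteration starts at β = 0 with step
halving; separation is flagged when |β| > 30.

### Penalized splines

Nonlinear covariate effects use cubic B-splines with 10 interior knots at
covariate quantiles. The penalty is the **integrated squared second
derivative** (O'Sullivan penalty) rather than a coefficient-difference
penalty: with non-uniform (quantile) knots a difference penalty's null space
is not {linear functions of z}, whereas the curvature integral's null space
is exactly {constant, linear} for any knot placement, so at heavy smoothing
the fit provably collapses onto the linear Cox model — a property the test
suite checks. The constant direction (adding c to all spline coefficients
shifts the predictor by c, which the partial likelihood cannot identify) is
removed by fitting in the orthogonal complement of the ones vector.

Smoothing is selected by **AICc** over a 33-point grid λ ∈ 10^(−2) … 10^6
(swept from smoothest to roughest with warm starts), with

    df_eff = trace[(H + λP)^(−1) H],   AICc = −2ℓ + 2·df + 2·df(df+1)/(m−df−1),

H the unpenalized observed information at the optimum and m the number of
events (event-driven sample size; both declared conventions). Pointwise
curve SEs come from the penalized covariance (H + λP)^(−1). Fitted curves
are **centered** so their weighted mean over the fitting cohort is zero, and
clamp to their boundary values outside the observed z-range (clamping is
logged) — required when scoring external subjects.

### Model comparison metrics

* Δi = AIC_i − min AIC; Δi > 6 flags a significantly worse model.
* R² = 1 − exp(2(ℓ_null − ℓ_model)/m) with m = events and ℓ_null the
  no-predictor partial likelihood. The exact explained-variation measure the
  original analysis used is not identified in the source; this
  likelihood-ratio form is a documented stand-in and is labelled as such.
* Concordance: Harrell-type with delayed entry — a pair is comparable when
  one subject dies at t while the other is observed strictly beyond t;
  predictor ties count ½; weighted by products of sample weights. Whether
  the original concordance restricted comparability this way is unstated.

## 4. ARI composition

The four fitted, centered log-hazard curves (height, BMI, ABSI, HI) are
evaluated at a subject's z-scores and **summed**; under the working
assumption of independent component hazards the sum is the log combined
hazard ratio. Sex/race adjuster coefficients from the component fits are
*not* part of ARI (they re-enter any downstream Cox fit of ARI). ARI is
reported raw and standardized by the source cohort's weighted mean/SD, so
"per SD of ARI" hazard ratios are well defined. A truncated ARI
(height+BMI+ABSI, for settings without hip circumference) is a first-class
option. Transfer to an external cohort uses the source model's reference
statistics, hip model and curves throughout (including for the external
cohort's own single-index comparison models), with age/z clamping.

`ARIModel` serializes to a single JSON document (reference table, curves
with basis + redundant evaluation grid, hip model, standardization
constants, provenance) with a deterministic byte layout: rebuilding from the
same cohort and config reproduces the file exactly.

## 5. Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
dataset:

* Sex (51% female), race (11% black), entry ages uniform 18–80.
* Log-height normal within sex (medians 162/176 cm, log-sd 0.04); log-weight
  linear in log-height with slope 2 (making BMI height-free by construction,
  matching the near-zero observed BMI–height correlation) and residual
  log-sd 0.20, giving height–weight correlation ≈ 0.5 and median weight
  ≈ 73 kg.
* Hip from the published allometry with log-noise sd 0.03; waist constructed
  so the ABSI analog is independent of BMI and height by design
  (ln WC = const + ⅔·ln BMI + ½·ln H − 0.06·f + noise, sd 0.05), placing
  median WC ≈ 92 cm and ABSI ≈ 0.080.
* Mortality: Gompertz baseline a = 3e−5/yr, b = 0.09/yr (an arbitrary
  adult-mortality calibration, not a published value) times
  exp(β_f·f + β_b·black + Σ components), with components in cohort-self
  z-units: height linear −0.04 (HR 0.96/SD), BMI quadratic with minimum at
  z = −0.5 (curvature 0.10), ABSI linear 0.15 (HR 1.16/SD), HI quadratic
  with minimum at 0 (curvature 0.06). Death ages are drawn by closed-form
  inverse transform conditional on survival to entry; censoring is
  administrative at 20 years (no loss to follow-up). The defaults yield an
  event fraction ≈ 0.26.
* The population R² of the hip regression has a closed form under this
  generator (mixture-of-sexes moments), so the noise sd reproducing a target
  R² is solved exactly (`hip_noise_sd_for_r2`).

**What a green test does not establish:** the generator has no survey
design (clusters/strata/oversampling), no age trends in body measurements,
no measurement error, no loss to follow-up, and its component effects are
exactly additive and proportional — so recovery tests validate the
machinery, not the epidemiology of any real population. Quantities computed
on real cohorts in the source (its tables and figures) are out of scope
here.

## 6. Numerical notes

* Partial-likelihood evaluation shifts the linear predictor by its maximum
  (translation invariance) to guard `exp` overflow.
* AICc selection ties break toward larger λ (smoother fit) via the
  descending sweep order.
* The dense curve grid (z = −4…4, step 0.05) is a portability convenience;
  scoring always evaluates the basis exactly (grid interpolation differs by
  O(curvature·h²/8) ≈ 1e−4).
* Reference CSVs are written at %.17g and read with round-trip float
  parsing, so table round trips are bit-exact.
* Generator determinism: numpy `default_rng` (PCG64), one stream per
  cohort; identical config ⇒ identical cohort.

## 7. Known limitations

No time-varying covariates, stratified baselines, competing risks, frailty
terms, survey-design variance, NRI/IDI, or recalibration machinery for
non-source populations. The R² convention is a stand-in (see §3). Linear
fits report Wald CIs; spline CIs are pointwise, not simultaneous, and
ignore the (small) covariance of the centering offset.
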