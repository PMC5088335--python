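# anthrorisk

Allometric body-shape indices and a combined anthropometric mortality risk
index, for epidemiologists and biostatisticians working with cohort data
that records height, weight, waist and hip circumference together with
mortality follow-up.

## The problem and the method

Single anthropometric measures are entangled: hip circumference, waist
circumference and BMI correlate at 0.8–0.9, which is why adding more tape
measurements has historically added little predictive value. The approach
implemented here decorrelates first, then combines:

1. **Allometric normalization.** A power law
   `ln HC = b0 + bH·ln H + bW·ln W + bF·f` is fitted to hip circumference by
   weighted log-log least squares (female indicator `f`), and the **hip
   index** divides the fitted size dependence out:

   `HI = HC · (H/⟨H⟩)^0.310 · (W/⟨W⟩)^(−0.482)`  (⟨H⟩ = 166 cm, ⟨W⟩ = 73 kg)

   By construction HI is uncorrelated with height and weight, the same trick
   that makes BMI = W/H² height-free and
   ABSI = WC/(BMI^(2/3)·H^(1/2)) BMI- and height-free.
2. **z-scoring.** Height, BMI, ABSI and HI are standardized to age- and
   sex-specific z-scores against a reference table of means and SDs; the
   four z-scores are mutually near-uncorrelated (|r| < 0.1).
3. **Hazard curves.** Each index's association with mortality is fitted by
   Cox regression on the **age timescale** (delayed entry, Efron ties,
   survey case weights, sex/race adjusters), with the nonlinear shape
   estimated by a penalized cubic spline whose smoothing is chosen by AICc.
4. **Composition.** The **anthropometric risk index** of a subject is the
   sum of the four fitted, centered log-hazard-ratio curves evaluated at the
   subject's z-scores — the log of the combined hazard ratio under
   independent component hazards. The bundled model (reference table,
   curves, hip allometry, standardization constants) serializes to one JSON
   file and can score external cohorts unchanged.

Model skill is compared by AIC differences (Δi, with Δi > 6 flagging a
significantly worse model), a likelihood-ratio explained-variation R², and
delayed-entry Harrell concordance. A seeded synthetic-cohort generator
reproduces the anthropometric and survival structure the method assumes, so
everything is testable without access to restricted cohort data.
See `docs/methods.md` for conventions and assumptions.

## Worked example

```python
from anthrorisk import (default_config, generate_cohort, fit_allometric_model,
                        model_comparison, build_ari_model, compute_ari,
                        AnthropometryRecord)

cohort = generate_cohort(default_config(n=20000, seed=1))   # 20,000 subjects, 5,124 deaths
hip = fit_allometric_model(cohort, "hip_cm")
```

The fitted hip allometry on this synthetic cohort (generated from the
published coefficients plus log-noise 0.03):

```text
ln HC = 2.659 -0.304 ln H +0.481 ln W +0.083 f   (R^2 = 0.917, n = 20000)
```

`model_comparison(cohort)` fits the baseline, all single-index linear and
nonlinear models and the linear ARI, and tabulates them:

```text
         predictor      form  hr_per_sd  ci_lo  ci_hi  delta_i    r2     c
      ARI (linear)    linear      1.341  1.310  1.372    0.000 0.128 0.601
   bmi (nonlinear) nonlinear        NaN    NaN    NaN  190.339 0.096 0.583
      bmi (linear)    linear      1.203  1.170  1.237  338.598 0.068 0.576
  absi (nonlinear) nonlinear        NaN    NaN    NaN  369.729 0.064 0.576
     absi (linear)    linear      1.172  1.140  1.204  370.640 0.062 0.575
    hi (nonlinear) nonlinear        NaN    NaN    NaN  467.662 0.046 0.562
   height (linear)    linear      0.962  0.936  0.989  491.885 0.040 0.559
height (nonlinear) nonlinear        NaN    NaN    NaN  491.886 0.040 0.559
              None  baseline        NaN    NaN    NaN  497.378 0.039 0.554
       hi (linear)    linear      1.005  0.977  1.034  499.245 0.039 0.554
```

Read: the combined index is the best mortality predictor by a wide AIC
margin (every single-index model sits Δi > 6 behind it); hazard rises 34%
per SD of ARI; BMI's association is strongly nonlinear (its spline beats its
linear fit by ~148 AIC points) because risk is U-shaped around a minimum
about half an SD below the population median.

Scoring one 55-year-old man (176 cm, 95 kg, waist 107 cm, hip 104 cm):

```python
model = build_ari_model(cohort)
rec = AnthropometryRecord("example", female=0, race_black=0, age_years=55.0,
                          height_cm=176.0, weight_kg=95.0, waist_cm=107.0, hip_cm=104.0)
score = compute_ari(model, rec)
# z-scores:      {'height': -0.005, 'bmi': 0.83, 'absi': -0.089, 'hi': -1.089}
# contributions: {'height': 0.0, 'bmi': 0.057, 'absi': -0.011, 'hi': 0.013}
# ARI 0.059  (0.21 SD above the cohort mean)
```

His elevated BMI adds risk, his slightly low ABSI subtracts a little, and
the total puts him 0.21 SD above average combined anthropometric risk.

The same pipeline is available from the shell:

```sh
anthrorisk simulate --n 20000 --seed 1 --out cohort.csv
anthrorisk build-ari --cohort cohort.csv --out ari.json
anthrorisk score --model ari.json --cohort cohort.csv --out scores.csv
anthrorisk transfer --model ari.json --cohort other_cohort.csv --out comparison.csv
```

## Acceptance script

`scripts/acceptance.py` regenerates the stated synthetic world from scratch
and recomputes the quantities the methodology itself defines: the
coefficients of the weighted log-log hip regression fitted to a cohort
generated from the published allometry, the correlation between the derived
hip-index and BMI z-scores, and the regression R² when the generator's
noise is calibrated so the population R² matches the published value.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes one JSON object mapping each target id to the recomputed value
and the problem size used.
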