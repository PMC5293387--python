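# renovol

Geometric prediction of renal functional change after partial nephrectomy.

## The problem

Partial nephrectomy (PN) removes a kidney tumor together with a margin of
healthy parenchyma while sparing the rest of the kidney.  How much kidney
function a patient loses is driven chiefly by how much functioning
parenchyma is resected or devitalized — yet that quantity is rarely measured
before surgery.  `renovol` implements a simple geometric surrogate that a
urologist can compute from six routine radiographic measurements, and the
statistical machinery to relate it to post-operative renal function.  It is
aimed at clinical researchers studying functional outcomes after PN and at
anyone who needs a fully synthetic, reproducible test bed for that analysis.

## The model

The kidney is idealized as an ellipsoid with full axis lengths *L*, *W*, *H*
(bilateral kidneys assumed equal) and the tumor as a sphere of radius *r*
that has invaded a depth *d* below the renal surface.  Excision with a
uniform peritumoral margin *w* (default 0.5 cm) removes the spherical cap of
the margin-enlarged sphere below the (locally planar) renal surface:

- **RAIV** (resected and ischemic volume, cm³) = cap of height *h = d + w*
  cut from the sphere of radius *a = r + w*:
  RAIV = π ∫ from a−h to a of (a² − x²) dx = π h² (3a − h) / 3
- **Functional renal volume** = 2 · (π/6) L·W·H − (4/3) π r³
- **PRAIV** (%) = 100 · RAIV / functional renal volume

Renal function is tracked as eGFR from the 4-variable MDRD equation
(k · Scr⁻¹·¹⁵⁴ · age⁻⁰·²⁰³ · 0.742 if female · 1.212 if black; k = 186 by
default, 175 optional), the post-operative **nadir** is the lowest eGFR
between 3 and 12 months after surgery, and the outcome is the percent eGFR
reduction 100·(preop − nadir)/preop.  The outcome is regressed on PRAIV and
the other clinical covariates by ordinary least squares — a univariate
screen followed by one multivariate model — with standardized betas
(coefficients after z-scoring) so effect strengths are comparable.

Because no patient-level data are publicly available, a synthetic-cohort
generator reproduces the published 63-patient cohort's covariate marginals
(truncated normal distributions matching each reported mean and range) and
its published outcome regressions (percent eGFR reduction = 1.512 +
2.752·PRAIV, R² = 0.194; and −4.958 + 0.324·age, R² = 0.073), with noise
calibrated in closed form to hit the reported R².

## Worked example

A 3.4 cm tumor invading 1.7 cm deep, in an 11 × 6 × 4.5 cm kidney, with the
default 0.5 cm margin:

```console
$ renovol praiv --diameter 3.4 --depth 1.7 --kidney 11 6 4.5
RAIV (cm3): 22.301
PRAIV (%): 7.678
```

22.3 cm³ of parenchyma are resected or ischemized — 7.68% of the patient's
functional renal volume.  Via the shipped literature-derived regression
line, an expected percent eGFR reduction of 1.512 + 2.752 × 7.678 ≈ 22.6%.

Simulate a cohort and run the univariate/multivariate analysis:

```console
$ renovol simulate --n 63 --seed 42 --out cohort.csv
wrote 63 patients to cohort.csv
$ renovol analyze cohort.csv --univariate praiv,age --multivariate praiv,age --out run
63 rows in; multivariate model on 63 complete cases (0 dropped)
covariate  uni_beta    uni_p  multi_beta  multi_p
    praiv  0.557600 0.000002    0.569527 0.000002
      age -0.054541 0.671160   -0.114082 0.289476
```

At this cohort size PRAIV is a strong predictor (standardized beta 0.56,
p < 0.001) while this particular draw shows no age effect — the age signal
(true standardized beta ≈ 0.27) is frequently lost at n = 63, which is the
point of having a generator: sampling variability at the study scale is
visible.  The same analysis from Python:

```python
import renovol as rv
from renovol.simulate import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n=5000, seed=1))
print(rv.fit_univariate(cohort, "pct_reduction", "praiv").summary())
```

```
OLS: pct_reduction ~ praiv
n = 5000 (dropped 0 incomplete), R2 = 0.2126, intercept = 0.9654
covariate   coef     se  std_beta  p_value
    praiv 2.8873 0.0786    0.4611   0.0000
```

At n = 5000 the refit recovers the generating slope 2.752 within two
standard errors and the generating R² 0.194 within sampling noise.

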