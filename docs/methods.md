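# Methods

## Geometric model

The resected-and-ischemic volume (RAIV) treats the excised region as the
spherical cap of the margin-enlarged tumor sphere (radius a = r + w) cut at
the renal surface, at cap height h = d + w, where r is tumor radius, d the
endophytic invasion depth and w the peritumoral margin:

    RAIV = π ∫_{a−h}^{a} (a² − x²) dx = π h² (3a − h) / 3

Assumptions, in decreasing order of importance:

- **Planar surface at the cut.** The renal surface is treated as a plane
  where it intersects the tumor sphere; the curvature of the kidney enters
  only through total ellipsoid volume.  Justified by tumor ≪ kidney; it buys
  a closed form.  The cap integrand is a swappable strategy (`cap_volume=`
  argument of `renovol.geometry.raiv`), so an alternative resection shape
  (e.g. a cylindrical or shell model) can be substituted without touching
  anything downstream.
- **Uniform margin.** w defaults to 0.5 cm everywhere around the tumor; real
  margins vary suture by suture.
- **Cap height clamp.** h is clamped to [0, 2a], so a deeply endophytic
  tumor saturates at the full enlarged-sphere volume and input tables may
  report depths exceeding the tumor diameter without error.
- **Functional renal volume** = 2 × single-kidney ellipsoid − full tumor
  sphere.  Bilateral kidneys are assumed equal (one kidney is measured), and
  the whole tumor is treated as non-functional, including any exophytic
  portion.  Subtracting only the endophytic portion would be equally
  defensible; the whole-sphere convention was chosen as the simpler one and
  is localized in `functional_renal_volume`.
- **Units** are fixed: cm, cm³, eGFR in mL/min/1.73 m², creatinine in mg/dL.
  CSV readers validate rather than convert.

With these conventions, PRAIV = 100·RAIV/FRV evaluated at the cohort-mean
inputs (r = 1.7, d = 1.7, w = 0.5, kidney 11 × 6 × 4.5) gives RAIV ≈ 22.3 cm³
— larger than the ~12 cm³ cohort-mean RAIV reported with the original
(unpublished) integrand, which evidently differs from this cap model.  The
strategy seam exists for exactly that reason; no result in this package
depends on reproducing the original RAIV scale, and the regression layer is
agnostic to it.

## Renal function

eGFR uses the abbreviated 4-variable MDRD equation.  The literature is
ambiguous between the original constant 186 and the IDMS-traceable 175;
`egfr_mdrd` defaults to 186 with `k=175` available.  The race factor is
retained for completeness and defaults to false.  The nadir eGFR is the
minimum over the inclusive window [90, 365] days post-op (a day-level
reading of "3 to 12 months"); an empty window is a hard error rather than a
silent fallback to early post-operative values, which reflect transient
ischemic injury rather than ultimate function.

## Nephrometry covariates

The C-index is computed as the 3-D Euclidean distance from tumor center to
kidney center divided by tumor radius — a simplification of the original
axial-plane construction that coincides with it when the inputs are true
center coordinates.  RENAL and PADUA are validated pass-through integers
(ranges 4–12 and 6–13); their rubrics are out of scope.

## Regression layer

Ordinary least squares via statsmodels; two-sided t-test p-values, no
multiple-testing correction (raw p-values, α = 0.05 convention).
Standardized betas are raw coefficients rescaled by sd(x)/sd(y) over the
complete cases (equivalent to refitting on z-scores); gender is coded
male = 1, female = 0 before standardization — the coding, and hence the sign
of the gender beta, is arbitrary.  Missing data: complete-case per model,
with dropped-row counts on the results object.  Rank-deficient designs
raise a `CollinearityError` naming the offending columns (identified by
QR with pivoting); zero-variance covariates and n below covariates + 2 are
separate, explicit errors.

The two published univariate models (outcome = percent eGFR reduction):

| model | intercept | slope | R² |
|-------|-----------|-------|----|
| PRAIV | 1.512 | 2.752 | 0.194 |
| age   | −4.958 | 0.324 | 0.073 |

are shipped as frozen `PublishedUnivariateModel` objects used for prediction
and simulation calibration only; they are never refitted.

## Synthetic cohort generator

The generator emulates the published 63-patient open-PN cohort, for which
only per-covariate means and observed ranges are available.

- Each continuous covariate is a **truncated normal** on the reported range
  with parent sd = (max − min)/6 (range ≈ mean ± 3 sd, a conventional
  heuristic).  Because several ranges are strongly asymmetric around the
  mean, the parent location is recentred numerically (Brent root-finding on
  the truncated-normal mean) so the mean of the truncated distribution
  equals the reported sample mean; with the naive location the realized
  PRAIV mean would be ≈ 4.83 instead of 4.4.
- Sex is Bernoulli with P(male) = 0.667; nephrometry scores are rounded to
  integers.
- **Noise calibration** is closed form: for y = α + βx + ε the population R²
  is β²Var(x)/(β²Var(x) + σ²), so σ = |β|·sd(x)·√((1−R²)/R²), with Var(x)
  taken from the sampled covariate column.
- **Direct mode** (default) samples RAIV and PRAIV from their published
  marginals and emits no kidney columns, so the table cannot contradict its
  own geometry.  **Geometric mode** draws kidney axes from
  literature-typical adult dimensions (11 ± 1, 6 ± 0.6, 4.5 ± 0.5 cm —
  synthetic defaults, not from any cohort report) and computes RAIV/PRAIV
  through the geometry module; rows whose joint draw is geometrically
  impossible or whose derived PRAIV falls outside the observed 1–16% range
  are resampled, because independently drawn tumor-size and kidney marginals
  otherwise over-produce high-PRAIV patients relative to the study.
  Recomputing PRAIV from a geometric-mode table's stored geometry reproduces
  the stored column bit-for-bit.
- The **joint** outcome model (PRAIV + age) is illustrative: no joint
  coefficients were published, so it combines the two univariate slopes,
  anchors the intercept to the published cohort-mean outcome (13.7%), and
  adds the two calibrated noise sds in quadrature.
- What the generator does **not** emulate: the right-skew of tumor size
  (one 15 cm tumor among mostly pT1a; no shape information is published, so
  the truncated normal is symmetric), within-cohort covariate correlations
  (unreported; geometric mode's correlations emerge from geometry alone),
  measurement error in eGFR, and loss to follow-up.  Tests passing on these
  cohorts therefore validate the computational pipeline and the statistical
  identities, not the clinical generalizability of the published model.

A dedicated helper draws RAIV/PRAIV as a Gaussian copula with correlation
0.7 and outcomes driven by PRAIV alone; at n = 63 this reproduces the
qualitative collinearity signature reported for such cohorts — RAIV
significant in the univariate screen yet non-significant once PRAIV enters
the multivariate model.

## Problem sizes and numerical choices

Statistical recovery checks run at n = 5000 (slope/intercept within 2
standard errors; sample R² within ±0.02 of the calibration target), with
50 seeded replicates for coverage-rate assertions; Monte-Carlo volume
oracles use 10⁶ points per parameter set, sampled in the cap's own bounding
box so the hit fraction never falls below ≈ 0.39 and the oracle's relative
error stays ≈ 0.13%, against a 0.5% agreement tolerance.  Brent root-finds
use xtol = 1e-12; CSV floats are serialized via `repr` and parsed with
pandas' round-trip parser so write → read is exact.

## Known limitations

- Real tumors and kidneys are not spheres and ellipsoids; cyst and
  collecting-system volumes are not subtracted from functional volume.
- The RAIV cap formula is one defensible reading of an integrand that was
  never printed; absolute RAIV values should not be compared across
  formulas (PRAIV, being a ratio-based *predictor*, is less sensitive but
  not immune).
- Single-kidney split function (scintigraphy) is out of scope; bilateral
  symmetry is assumed throughout.
- The simplified C-index is a stand-in for the image-based original.
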