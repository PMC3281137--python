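# Methods

`cartchem` implements a depth-wise calibration of FT-IR spectroscopic imaging
data against Safranin-O digital densitometry for articular cartilage
proteoglycan (PG) quantification, and a synthetic hyperspectral phantom on
which the whole analysis can be validated against known ground truth.

## The calibration problem

A vertical cartilage section is imaged in transmission from the articular
surface to the bone interface (rows = depth, 25 µm pitch; columns = a 400 µm
transverse strip; one absorbance spectrum per pixel at 4 cm⁻¹ resolution).
Safranin-O is a cationic stain whose optical density (OD, calibrated 0–3) is
proportional to the sulphated glycosaminoglycan content, so the transverse-
averaged OD depth profile of a parallel stained section is the PG reference.
After matching surface and bone junction and resampling the OD profile to the
spectral row count, each depth-wise mean spectrum carries exactly one
reference value, giving a calibration set of (spectrum, OD) pairs pooled over
specimens.

Six predictors of OD are compared:

* **carb_area** — trapezoidal area of the carbohydrate band, 984–1140 cm⁻¹;
* **carb_amide_ratio** — the same area normalised by the amide I area,
  1584–1720 cm⁻¹;
* **d2_1062**, **d2_1374** — depths of the Savitzky-Golay second-derivative
  minima nearest 1062 cm⁻¹ (sulphate) and 1374 cm⁻¹ (CH₃), reported negated
  so larger = more PG;
* **plsr** — PLS1 regression (NIPALS) on the masked spectrum;
* **pcr** — principal component regression on the same variables.

Univariate parameters are converted to OD by ordinary least squares.
Multivariate models use the offset-baseline-corrected absorbance restricted
to 1000–1440 and 1480–1700 cm⁻¹ (1440–1480 cm⁻¹ is excluded because residual
embedding paraffin absorbs there); mean-centred X and y, no variance scaling.
The second-derivative domain is available as a configuration option
(`domain: second_derivative`), since chemometric practice supports either
choice; absorbance is the default.

## Latent-variable models and component choice

PLS1 components are extracted by NIPALS: per component the weight vector is
`w ∝ X'y` (unit norm), scores `t = Xw`, loadings `p = X't/t't`,
`q = y't/t't`, followed by deflation of X and y.  The regression vector is
assembled through the Gram-Schmidt recursion `r_a = w_a − Σ_{j<a}(p_j'w_a)r_j`,
so coefficient paths for every component count come from a single fit.  PCR
projects centred X onto its leading right singular vectors and regresses y on
the (orthogonal) scores.  Components whose score norm falls below 1e-12 of
the initial scale terminate extraction (rank guard).

The component count is chosen from leave-one-out cross-validation: RMSECV(k)
is the root-mean-square held-out error at k components, and the selected k is
the smallest for which no larger k reduces RMSECV by more than 2% relative
("no significant decrease"; the 2% tolerance is configurable).  The LOO unit
is a single depth point by default; grouped leave-one-specimen-out is
available (`cv_unit: sample`) because both readings of "one sample in turn"
are defensible.  The stratified calibration-set rule (all points with
OD ≤ 1.5, plus 50 seeded draws without replacement from each of (1.5, 2.0],
(2.0, 2.15] and (2.15, ∞)) is applied once, before CV; an undersized stratum
is an error in `stratified_select` itself, while `run_study` in its default
`stratify: auto` mode falls back to the full pool and records the fallback in
the study metadata.

## Statistical comparison

All predictors are correlated with the same reference, so pairs of
correlations are dependent and overlapping; they are compared with Steiger's
Z (pooled-r Fisher transform variant):
`Z = (z_jk − z_jh)·√((n−3)/(2−2c̄))` with
`c̄ = [r_kh(1−2r̄²) − r̄²(1−2r̄²−r_kh²)/2]/(1−r̄²)²` and `r̄ = (r_jk+r_jh)/2`.
Family-wise error over multiple pairs is controlled by Bonferroni; the
default report tests all 15 pairs (threshold α/15), and the seven-pair
"performance-adjacent" preset reproduces the N = 7 setting
(0.05/7 ≈ 0.007).  Which seven comparisons constitute the canonical family is
a judgement call; the preset pairs each method with its nearest competitor
(area vs ratio, the two derivative peaks, each derivative peak vs area, each
multivariate model vs the best univariate parameter, PLSR vs PCR) and the
comparison list is user-configurable.  Relative prediction error is
|error|/predicted, binned by reference OD ([0–1.5, 1.5–2.0, 2.0–2.15, >2.15]);
predictions below 0.05 OD are excluded from the relative (not absolute) error
means and counted separately, because division by near-zero predictions is
unstable — the report makes the growth of relative error toward zero OD
visible rather than hiding it.

## The synthetic phantom

The generator emulates the study material statistically; wet-lab steps are
out of scope.  Absorbance follows a Beer-Lambert mixture of three
Gaussian-sum basis spectra (defaults):

| component | peaks (centre cm⁻¹, σ, height) |
|---|---|
| PG | (1062, 14, 1.0), (1374, 10, 0.5), broad (1080, 45, 0.5) |
| collagen | (1655, 25, 1.0), (1550, 25, 0.75), (1240, 20, 0.35), (1080, 30, 0.95) |
| paraffin | (1462, 8, 1.0), support truncated to 1440–1480 |

The collagen (1080, 0.95) term is the deliberate collagen–carbohydrate
overlap: roughly 40% of a typical deep-zone carbohydrate-band area is
collagen, which is what makes depth-blind band integration non-specific.
The CH₃ 1374 cm⁻¹ band belongs to PG alone, so `d2_1374` is the best
univariate parameter by construction, as observed on the real tissue.
Paraffin is confined to the excluded band, encoding the reason that band is
masked.  The wavenumber grid is uniform 900–1800 cm⁻¹ at 4 cm⁻¹ (the stated
spectral resolution; the data-point spacing is not separately specified, so
grid step = resolution).

Composition profiles per virtual specimen (depth z, section thickness Z,
60 rows × 25 µm by default): PG is a logistic rise from a depleted surface
value 0.12 to a plateau (nominal 1.0, lognormal between-sample SD 0.12) with
midpoint 150 ± 40 µm and width 55 µm; collagen rises monotonically from 0.45
to a deep level (nominal 1.40, lognormal SD 0.35) as (z/Z)^γ with
γ = 1.3 ± 50% — the between-animal variation of the collagen depth gradient
is what decouples collagen from PG across specimens.  Enzymatic depletion
zeroes PG over the superficial 35% of depth and leaves the rest identical to
the control drawn with the same seed.  Acquisition: one lognormal thickness
factor per section (CV 0.10, mean 1), a uniform residual paraffin level in
[0, 0.04], and additive pixel noise with SD = 0.15/√8 ≈ 0.053 absorbance
units (single-scan SD 0.15, eight averaged scans).  The real instrument's
noise level is not published; 0.15 AU is a plausible single-scan figure for
a focal-plane imaging detector and is a free parameter — the acceptance
properties are statements at this default, not claims about the instrument.
The OD reference is od_scale (2.3) × PG, averaged over three independent
thickness draws (the three-section averaging of the reference protocol),
resampled to 5 µm pitch and clipped to the calibrated 0–3 range (with a
warning when clipping occurs).

### What the phantom does and does not show

The phantom reproduces, with known truth: the collagen-to-PG ratio varying
with depth, superficial PG depletion, section-thickness variation hitting
both modalities, derivative noise amplification, and the excluded paraffin
band.  It deliberately omits scattering artefacts, instrument line-shape,
chondrocytes, atmospheric lines, and any constituent beyond the three basis
components.  One consequence is structural: the masked spectra span an
exactly two-dimensional signal subspace, so PLSR and PCR coincide once both
use two components and their cross-validated correlations agree to ~1e-7 —
the ordering r(PLSR) ≥ r(PCR) holds as a tie here, whereas real cartilage
spectra are higher-rank (the original analysis selected seven components)
and separate the two methods.  Passing the phantom study therefore validates
the machinery and the direction of the univariate-vs-multivariate contrast,
not the magnitudes observed on tissue.

## Numerical choices and degenerate inputs

* Savitzky-Golay: 7-point window, polynomial order 2 (orders 2 and 3 share
  the same second-derivative coefficients on a symmetric window), derivative
  scaled by 1/h²; the three edge points per side are NaN rather than
  extrapolated, and peak reads skip them; non-uniform grids (beyond 1e-6
  relative) are rejected.
* Offset baseline: subtract the spectrum minimum over 1000–1700 cm⁻¹ (the
  union of the analysis regions); band integrals then use the global offset
  only, with no per-band local baselines.
* Band and mask boundaries are inclusive at both ends; integration is
  trapezoidal on the native grid without resampling.
* Derivative peak read: deepest raw-derivative minimum within ±8 cm⁻¹ (two
  grid steps) of the nominal centre, ties broken toward the centre; the
  value is read at the located point, not from a fitted peak.
* OD resampling: linear interpolation on normalised depth with endpoints
  pinned (surface/bone matching); exact on linear profiles for any target
  length.
* Pairs with |r| = 1 (noiseless studies) make Fisher's z infinite; the
  report records those Steiger entries as NaN instead of failing.
* All randomness flows from explicit seeds through `numpy` generators;
  rerunning a study with the same configuration is bit-identical.

## Default study scale

The default `StudyConfig` mirrors the study design: 16 virtual specimens
(8 control + 8 depleted), one of each group held out of all model fitting
for the imaging demonstration, 60 depth points per specimen, k_max = 15.
Depending on the seed the stratified rule either applies (≈350 calibration
points) or falls back to the full ≈840-point pool; both complete in seconds
on one core, which is why the test suite runs the full study rather than a
reduced stand-in.
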