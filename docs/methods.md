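# Methods

This note documents the models, conventions and numerical choices behind
`petrad`, in the order the pipeline runs: SUV calibration → tumor
delineation → texture quantisation and the 665-feature catalogue →
feature-vector discovery and scoring → survival inference → the synthetic
data that exercises all of it.

## SUV calibration and routine PET variables

Voxel values are body-weight SUV: activity concentration (kBq/ml) divided
by decay-corrected injected dose (kBq) per body weight (kg), with the dose
decayed from injection to scan start using the 18F half-life (109.771 min).
Lean-body-mass and body-surface-area variants are out of scope. Volumes are
indexed `[x, y, z]` (z = slice axis), physical position = origin + index ×
spacing, 0-based; masks live on the PET grid and nothing is ever resampled
— voxel sizes are analysed as acquired, which is also why texture distances
(below) are in index space.

`SUVpeak` has no universal definition; we adopt a ~1 ml sphere-mean: the
kernel is the set of voxels whose centers fall within the analytic radius
of a 1 ml sphere (r ≈ 6.2 mm), built from the voxel spacing, center voxel
always included; kernel voxels outside the image are dropped from the
mean. `MTV` is voxel count × voxel volume (ml); `TLG = SUVmean × MTV` holds
exactly by construction.

DICOM series are required to carry consistent slice positions (steps equal
within 1% — a missing slice is a hard error, never a silently truncated
volume), `PixelSpacing`, and rescale slope/intercept; volumes are returned
in SUV only when the `Units` tag says the data are already calibrated
(GML/SUV), otherwise flagged as raw activity that must pass
`convert_to_suv`.

## Tumor delineation

The lesion is the 26-connected component, around a user seed, of voxels
with SUV ≥ f × SUVmax, starting at f = 0.40. SUVmax here is the maximum
*within the seed's component*, found by fixed-point iteration from the seed
value (the local max is non-decreasing and bounded, so the iteration
terminates; the result is deterministic). 26-connectivity matches the
texture engine's 3D neighbourhood convention throughout the package.

Clinical workflows lower the threshold when the PET VOI visibly
under-covers the tumor on CT. We operationalize that visual check as a
coverage fraction against a supplied reference-extent mask: the fraction is
decremented in steps of 0.05 until the mask covers ≥ 90% of the reference
or a floor of 0.20 is reached (then returned with a warning flag). The
0.05/0.20 schedule reflects that reported threshold choices cluster at
discrete values of 40% and 30%, and the floor prevents background flooding.
Manual voxel edits are set operations that mark the mask as edited; the
single-component invariant is re-checked and reported, not enforced.
Lesions below 5.0 ml (inclusive gate: exactly 5.0 ml is accepted) are
excluded from analysis, reflecting the poor statistics of PET texture in
small volumes.

## Quantisation and texture matrices

In-mask SUV is quantised to G ∈ {4, 8, 16, 32, 64, 128, 256} equal-width
bins over the VOI's own min–max: `label = ceil(G (v − min)/(max − min))`
clamped to [1, G]; a constant VOI maps to label 1. Min–max-relative binning
makes every quantised-texture feature invariant under global SUV scaling —
a property the tests verify directly. A fixed-bounds mode exists but is not
the default.

* **GLCM** — pair counts at index-space distance 1 over the 13 unique 3D
  directions, summed and symmetrized (merged-matrix strategy; statistics
  are computed once on the merged matrix, not averaged per direction).
* **GLRLM** — maximal same-label runs along each of the 13 directions
  within the mask (a mask gap breaks a run), counts aggregated. The
  builders satisfy the count identity Σ runs × length = 13 × voxels.
* **GLSZM** — 26-connected zones of equal label; entry (i, s) = number of
  zones of level i and size s; Σ zones × size = voxels.
* **NGTDM** — for each voxel with ≥ 1 in-mask 26-neighbour, the absolute
  difference to the mean neighbour label, accumulated per level (s_i),
  with occupancy fractions p_i over the n counted voxels.

All four builders are tested for exact integer equality against naive
brute-force implementations (double loops, flood fill, neighbourhood
scans) on random VOIs.

## The 665-feature catalogue

The full composition, per gray level:

| block | count |
|---|---|
| 9 bands × 13 first-order | 117 |
| 9 bands × 22 GLCM | 198 |
| 9 bands × 16 GLRLM | 144 |
| 9 bands × 16 GLSZM | 144 |
| 9 bands × 5 NGTDM | 45 |
| shape | 14 |
| fractal | 3 |
| **total** | **665** |

The 9 bands are the original image plus the 8 sub-bands (LLL…HHH) of a
one-level separable 3D discrete wavelet transform, first-order Coiflet
(`coif1`), periodized boundaries. Periodization keeps the transform
orthogonal, so the sub-band energies sum exactly to the input energy
(tested); band grids are half-size and the VOI mask is max-pooled onto
them. VOIs whose bounding box is smaller than the filter length (6 voxels)
along any axis skip wavelet features: the names remain in the catalogue
with the value recorded missing plus a reason — the 665-name invariant is
on names, and missingness is never a silent NaN.

Conventions worth noting:

* First-order entropy/uniformity use the quantised histogram (bits);
  kurtosis is Fisher excess; skewness/kurtosis of a constant VOI are 0.
* Two surface areas are reported: a marching-cubes mesh area (used for
  sphericity, compactness, surface-to-volume; converges to the true area
  for smooth shapes) and the voxel-face-count area (6 mm² for a unit
  voxel). Maximum 3D diameter is the largest center-to-center distance
  between boundary voxels (convex hull first when the boundary is large).
  Principal axis lengths are 4√λ of the physical-coordinate covariance
  eigenvalues; a single-voxel mask has elongation = flatness = 1 (a point
  is isotropic).
* Degenerate single-level VOIs take limiting values where they exist:
  GLCM correlation 1, inverse variance 0, NGTDM complexity/contrast/
  busyness 0, coarseness capped at 10⁶ when Σ p_i s_i = 0.
* Fractal features are box-counting on the full grid: box edges 1, 2, 4, …
  up to half the largest grid dimension (≥ 3 ladder points required);
  dimension = −slope of log N(ε) vs log ε for the mask boundary (and the
  filled mask), abundance = the fit intercept.
* The two constituents of the published classifier follow the formulas
  they are tested against by hand: GLSZM size-zone variance
  Σ p(i,s)(s − μ)² with p = zone count / total zones, and Amadasun–King
  complexity Σ |i−j| (p_i s_i + p_j s_j) / (n (p_i + p_j)).

## Feature-vector discovery and scoring

**Volume screening.** Features whose Spearman |ρ| with tumor volume is
≥ 0.7 across patients are replaced by feature/volume; zero-variance
features are left untouched and logged. The operation is idempotent once
the normalised feature no longer crosses the threshold.

**LASSO-Cox.** Discovery at one gray level is an L1-penalized Cox partial
likelihood (coordinate-descent path via scikit-survival's Coxnet).
Features are standardized internally; reported weights are back-transformed
to the original feature scale. The penalty is chosen by K-fold (default 10,
seeded) cross-validated partial-likelihood deviance, computed as −2 × the
Breslow log partial likelihood of the held-out fold under the training-fold
coefficients. Both the minimum-deviance and 1-SE rules are exposed; the
default is the minimum (the discovery literature does not dictate one; the
1-SE rule is the sparser, more conservative choice and is what the null
simulations use). At least 20 events are required; a fit whose selected
penalty zeroes every weight returns an empty model with a warning.

**Optimal FV across gray levels.** The criterion that crowns one
candidate "most predictive" is a cross-validated Harrell C-index of the
fixed-weight score on the training cohort (no refitting inside folds —
the weights are part of the candidate); ties break toward fewer terms,
then the lower gray level. This is a documented surrogate for an unstated
selection rule.

**Scoring and dichotomisation.** An FV score is the exact linear
combination Σ weight × feature. Risk groups come from one of: the sample
median (ties to the low-score group); Youden's J on the ROC against the
binary label "survived beyond the cohort median OS" (patients censored
before the median are not evaluable); or a maximally selected log-rank
search over interior cutoffs with each group ≥ 10% of the cohort.

## Survival inference

Cox models use lifelines (Efron tie handling), Wald 95% CIs and two-sided
p-values; Harrell's C is computed on the linear predictor. Backward
stepwise elimination removes the largest Wald p > 0.05 per step, all
candidates entered as continuous variables. Kaplan–Meier estimation and
the log-rank test are delegated to lifelines and verified against the
empirical survival function (no censoring) and a hand-tabulated O−E
oracle. ICC is computed from the two-way ANOVA mean squares — ICC(2,1)
"agreement" (default) and ICC(3,1) "consistency" — and cross-checked
against an independent ANOVA-table oracle and pingouin.

**Scanner invariance** is summarized by centered PCA of the classifier's
constituent features: explained-variance spectrum, per-group centroids,
and the between/within mean-square ratio of PC1–2 scores, which is ≈ 1
when scanner groups are draws from one distribution and ≫ 1 under a batch
effect. With few groups the per-cohort ratio is noisy (χ²-like numerator),
so null checks average replicates.

**Power / sample size.** Required events follow Schoenfeld's formula for a
two-arm log-rank comparison,

    D = 4 (z₁₋α/₂ + z₁₋β)² / ln²(HR),

which gives D = 83.50 (84 events) at HR 1.78, α 0.05, power 0.75. Events
convert to patients through an exponential survival model: the two arm
hazards are λ·HR^{±1/2} with λ = ln 2 / median survival (a geometric split
around the pooled median), pooled on the hazard scale, λ̄ = (λ₁+λ₂)/2;
with competing exponential dropout at the stated yearly censoring rate and
administrative truncation at the median-follow-up horizon τ,

    P(event) = λ̄/(λ̄+c) · (1 − e^{−(λ̄+c)τ}),   N = round(D / P).

At the design inputs (median survival 2.92 y, follow-up 2.17 y, censoring
0.012/y) this yields P = 0.4104 and N = 203. No standard software variant
is universal here; among the defensible conversions (probability-scale
averaging of per-arm event probabilities gives 199–207 depending on how
follow-up and dropout are treated), this hazard-scale-pooled variant is
the one the package documents and freezes. N is strictly decreasing in
|ln HR| and increasing in power (tested).

## Synthetic data

Phantoms are hard-edged spheres (default: radius 19.3 mm ≈ 30 ml, SUVmax
16 on background 1, 4 mm isotropic voxels — the scale of a medium-large
NSCLC primary) with a zero-mean Gaussian random field added inside the
tumor (correlation length 8 mm, amplitude = 1 SD; a single interpretable
heterogeneity knob that maps monotonically onto size-zone texture) plus
Gaussian image noise, clipped at 0. The truth mask is the analytic sphere.

Cohorts emulate a validation-scale radiotherapy dataset: default n = 204,
median OS 21 months, exponential dropout 0.001/month (~0.012/y) plus an
85-month administrative window (~70% deaths), stage mix 16/18/66%
(I/II/III), scanners drawn from a multi-centre pool of named models.
Features are jointly Gaussian with AR(1) correlation 0.3 between adjacent
columns; two designated columns carry the true log-hazard weights
(default ±ln 1.8 per SD, with the published classifier's signs), and
survival times are exponential with rate (ln 2 / median) · exp(centered
linear predictor).

What the generator does *not* emulate: scanner PSF and reconstruction,
partial-volume effects, respiratory motion, non-spherical and multi-focal
lesions, non-proportional hazards, and the real joint distribution of
radiomics features. Passing tests therefore demonstrate the correctness
of the algorithms and the recoverability of planted effects at realistic
scale — not clinical performance on patient data.

## Problem sizes used by the test suite

Oracle equivalence uses 100 random 6³ VOIs; discovery recovery uses 50
replicate cohorts of n = 300 with 2 planted features among 50; Cox
calibration uses 40 replicates of n = 2000 with a binary covariate at
HR 2; null simulations use 40–60 replicates of n = 80–150. These sizes
keep every distributional check statistically meaningful while the whole
suite runs in well under a minute on one CPU.

## Known limitations

* The catalogue is a documented engineering reconstruction; it is not
  certified against the IBSI reference values, and 2D slice-wise variants
  are out of scope.
* The wavelet family (coif1) and boundary mode (periodization) are
  defaults chosen for orthogonality; other toolchains use other families.
* The threshold-adaptation schedule (0.05 steps to a 0.20 floor, 90%
  coverage) is a testable surrogate for a visual CT-comparison step.
* The power-calculation conversion is one frozen variant among several
  defensible ones; its derivation is given above precisely so it can be
  compared against alternatives.
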