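# Methods

This note documents the models, numerical choices and synthetic-data
design behind `mvq`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the phantom validation does and does
not demonstrate about real data.

## Phase correction (homodyne high-pass filter)

The complex gradient-echo volume `I = m·exp(iφ)` is filtered slice by
slice (axial). The 2D FFT of each slice is centered (DC at index `n//2`),
every bin outside the central `k × k` block is zeroed (`k = 32` by
default, matching a 32 × 32 central matrix on a 256 × 256 acquisition),
and the inverse FFT gives a smooth complex reference `L`. The corrected
phase is `arg(I·conj(L))`, wrapped to (−π, π].

Numerical conventions, fixed for bit-reproducibility:

- Even block sizes take the DC bin plus `k//2` bins below and `k//2 − 1`
  bins above it (the extra bin goes to the lower index).
- A raised-cosine (Hann) taper on the block is available (`taper=True`)
  but off by default; the sharp block is the reference behaviour.
- An all-zero slice has no phase; its filtered phase is defined as zero
  and a warning is logged.
- Scanner integer phase dialects (e.g. ±4096 scaling) are converted by an
  explicit `phase_scale` factor, never guessed from the data.

Properties verified on phantoms: a constant global phase cancels exactly;
a second-order polynomial background field is suppressed by ≥ 90% RMS
within the brain; at least half of a 0.6 rad vein dip survives at the vein
voxels; repeated filtering does not amplify (RMS change < 25%).

Two behaviours of the sharp filter matter downstream. First, thin
structures are attenuated: a 1–3 voxel wide vein loses roughly 25–45% of
its dip amplitude, more on a coarser grid relative to the block. Second,
the filter *overshoots* around dense dips — the low-pass reference absorbs
part of the vein phase, so parenchyma adjacent to veins acquires positive
phase. With a dense vein fan this overshoot, not the acquisition noise,
dominates the spread of the filtered parenchyma distribution.

## Intensity model and threshold segmentation

Both segmentations share one primitive: fit a Gaussian to the parenchyma
intensities of a region, then threshold at a fixed SD multiple — strictly
above μ + 3σ for lesions on FLAIR, strictly below μ − 2σ for veins on
corrected phase (voxels exactly at the threshold are not segmented).

The default fit (`method="robust"`) restricts the sample to a percentile
band and least-squares fits a scaled Gaussian `A·exp(−(x−μ)²/2σ²)` to its
histogram (Freedman–Diaconis bins, clamped to [16, 4096]); the free
amplitude makes the estimate insensitive to truncating a contaminated
tail. A plain moments estimator (`method="moments"`) is provided for
comparison and is visibly biased by lesion tails. Band defaults:

- FLAIR: (2, 90) percentiles — lesions live in the far upper tail.
- Corrected phase in the vein-counting slab: (30, 70) — veins contaminate
  the lower tail *and* filter overshoot contaminates the upper tail, so
  only the central body is trustworthy. A narrow band under-constrains σ
  on perfectly clean data (the Gaussian is nearly flat over ±0.5σ), but in
  vein-laden slabs the contamination widens the band in value space and
  the fit is stable; on vein-free data the wide FLAIR band applies.

The fitted σ in a dense-vein slab is moderately inflated (~0.14 rad
against a far-from-vein spread of ~0.11 rad in the default phantom). This
is not corrected: the inflation deepens the threshold, trading false
positives against false negatives, and the measured net vein-count error
across seeds is −3% to −6% (tolerance ±10%). Both fit method and band are
configuration, not hard-coded.

Bilateral counting splits at the mid-sagittal grid plane (stored
explicitly by the phantom; never inferred): voxels with x-index strictly
below the midline are "left". Left + right equals the total by
construction.

False-vein flagging (`flag_false_dmv_candidates`) replaces the manual
screening step that is performed visually on patient data: connected
components (26-neighbourhood) are flagged when larger than a volume cap
(default 500 mm³), when near-spherical (principal-axis extent ratio
< 2 with ≥ 8 voxels), or optionally when touching the analysis-region
boundary. The result is an advisory exclusion mask; it is never applied
automatically.

## Volumetry

- `mask_volume_ml`: voxel count × voxel volume / 1000.
- `CWMHV = WMHV × meanICV / ICV`; the mean ICV is always bound at cohort
  run time (it is cohort-relative by definition), so per-subject corrected
  volumes are filled only when the cohort is assembled.
- PVH/DWMH: full 3D Euclidean distance transform from the ventricle mask,
  with the physical voxel spacing as sampling, so anisotropic grids are
  exact. WMH voxels at distance ≤ 10 mm (inclusive at exactly 10 mm) are
  periventricular. The partition is applied uniformly to all lesions,
  rather than to confluent lesions only — simpler and monotone; this is a
  deliberate deviation from the clinical convention the rule derives from.
- The periventricular slab is the `n` (default 5) consecutive axial slices
  starting at the first ventricle-containing slice strictly above a
  caller-supplied basal-ganglia top slice; every slab slice must contain
  ventricle. "Immediately above the basal ganglia" is anatomically fuzzy,
  so the reference slice is always an explicit input (phantoms store their
  own), never inferred from images.
- The intracranial mask is an input (phantom truth or external
  preprocessing); ICV is its volume, with a validation warning when it is
  smaller than the parenchyma volume (it must include CSF).

## Rigid coregistration

The FLAIR volume is registered to the phase grid; the phase volume is the
fixed reference and is never resampled. The transform maps reference-space
mm coordinates (about the grid center) to moving-space coordinates,
`x_mov = R(θx, θy, θz)·x_ref + t` with `R = Rz·Ry·Rx` in degrees.
Similarity is normalized mutual information (32-bin joint histogram) by
default; mean squared error is available for same-modality tests.
Optimization is deterministic: an axis-wise coarse sweep over ±5° / ±5 mm
plus a joint in-plane sweep (z-rotation with x/y shifts — the dominant
modes of axial acquisitions) on a 2× in-plane downsampled grid, then
Powell refinement at full resolution (xtol = ftol = 1e−5, ≤ 200
iterations). Registration fails loudly when the volumes do not overlap at
the initial transform or when the optimum does not improve on it.
Masks are resampled with nearest-neighbour interpolation. On phantoms, a
3° / 2 mm perturbation is recovered to ≈ 1e−12 (the optimum is sharp), and
the acceptance test requires 0.5° / 0.5 voxel with round-trip Dice ≥ 0.95.

## Statistics

All inferential steps are implemented directly and cross-checked against
independent references in the tests (scipy for the t-test and 2×2 Fisher,
statsmodels for logistic likelihoods, pingouin for ICC, brute-force
enumeration elsewhere):

- **Fisher's exact test**, r×c with r·c ≤ 12: full recursive enumeration
  of margin-preserving tables; two-sided p is the summed conditional
  (multivariate hypergeometric) probability of tables no more probable
  than the observed one (the probability method; ties included with a
  1e−9 relative log-probability tolerance). Larger tables raise with a
  suggestion to use chi-square — never applied automatically.
- **t-test**: Welch by default (the variance-equality assumption is not
  defensible for these covariates); pooled by flag. Zero variance in both
  groups with equal means is defined as t = 0, p = 1.
- **Partial Pearson correlation**: residualize both variables on
  [intercept + covariates] by OLS; r is the Pearson correlation of the
  residuals; two-sided p from `t = r·√(df/(1−r²))`, `df = n − q − 2`.
  Rank-deficient covariate matrices are rejected naming the collinear
  columns.
- **Logistic regression**: IRLS to relative log-likelihood change < 1e−8
  (≤ 100 iterations), Wald SEs from the inverse Fisher information,
  OR = exp(β) with 95% CI exp(β ± 1.96·SE). Separation is detected by the
  perfect-classification diagnostic (all fitted probabilities on the
  correct side of 1 − 1e−8 / 1e−8) rather than a coefficient-magnitude
  heuristic, which misfires on legitimate large intercepts.
- **Backward stepwise**: start from forced terms + prespecified
  always-include terms + candidates passing a univariate screen
  (p < 0.1); repeatedly drop the non-forced term with the largest
  likelihood-ratio removal p above 0.10, refitting the reduced model
  exactly for each test (not the conditional-estimate approximation found
  in legacy software — the exact refit LR test is better defined and
  testable). Forced terms are never removal candidates. The removal trace
  (term, step, p) is recorded. In the cohort plan, age is forced; sex,
  education and the vein count (in 10³ voxels, so ORs read "per thousand
  vein voxels") are always included; MMSE is excluded by design because
  cognitive score is a consequence of lesion burden, not a candidate
  cause.
- **ICC**: two-way ANOVA mean squares (subjects, raters, error);
  single-measures; absolute agreement `(MSB−MSE)/(MSB+(k−1)MSE+k(MSC−MSE)/n)`
  by default (the stricter form), consistency `(MSB−MSE)/(MSB+(k−1)MSE)`
  by flag.
- **Bonferroni**: `min(1, p·m)`; the partial-correlation report shows raw
  and adjusted p side by side, since it is not obvious whether the
  region-specific correlations should share a family.

Median dichotomization assigns ties to the low group (≤ median), matching
the ≤/> convention of the cohort tables this analysis layout mirrors.

## Synthetic data

**Image phantoms.** Geometry is evaluated in physical mm on anisotropic
grids: an ellipsoidal brain (parenchyma ~ N(100, 10) in arbitrary units —
stated config values, not measured ones) inside an intracranial envelope
with a CSF rim; two lateral-ventricle ellipsoids at CSF-like intensity;
spherical lesions offset by a stated multiple of the parenchyma SD
(default +6σ, comfortably beyond the +3σ threshold, per the design rule
that planted pathology must be unambiguously detectable); veins as
piecewise-linear tubes rasterized by exact distance-to-segment ≤ radius.
Phase = polynomial background (normalized coordinates, order ≤ 2) + vein
dips + Gaussian noise, wrapped to (−π, π] after summation; magnitude is
uniform inside the intracranial envelope. The seed fixes everything;
geometry is seed-independent, only noise varies.

Default scaled-down extents (≈ 45–60 mm fields of view, 10–20 slices)
keep a full phantom under half a second to generate while preserving the
protocol voxel geometry. The default vein fan (165 veins of radius
0.7 mm over the 5 slab slices, ≈ 24% of slab parenchyma) and dip depth
(1.6 rad against 0.1 rad phase noise) are chosen so that the vein dip
after filter attenuation (~45%) still clears the μ − 2σ threshold of the
overshoot-widened parenchyma distribution: with that density, vein-count
false positives (the 2.3% Gaussian lower tail of the non-vein slab) and
false negatives nearly cancel, giving the −3% to −6% net recovery the
acceptance tests require. A shallower dip (e.g. 4× the raw noise SD)
fails on this phantom — not because the thresholding is wrong but because
filter attenuation plus overshoot-inflated σ̂ push the miss rate past the
tolerance; the depth is a generator design choice, documented here rather
than hidden.

**Cohort tables.** Covariates (age, sex, education, blood pressure, labs,
Poisson lacune/microbleed counts, MMSE) are drawn from parametric
families with means/SDs typical of an elderly small-vessel-disease
cohort. The two outcomes are built from the *realized, standardized*
covariate columns: `x = a·Z + √(1−‖a‖²)·e₁` (standardized log lesion
volume) and `y = b·Z + √(1−‖b‖²)·e₂` (standardized vein count) with
`corr(e₁, e₂) = ρ`, the requested target. Because both outcomes are
linear in the covariates plus residual, the population partial
correlation of x and y given the covariates is exactly ρ — no matrix
inversion needed, and the sample estimate converges at the usual 1/√n
rate (verified: |r̂| < 0.04 at ρ = 0, n = 5000). Lesion volume is
exp(3.22 + 0.83·x) ml (median ≈ 25 ml, right-skewed); vein count is
3676 + 1071·y, rounded and floored at 1.

**What phantom validation does not show.** The phantoms have no partial
volume effects, no B0/B1 inhomogeneity beyond the polynomial field, no
physiological vein-geometry variability, uniform magnitude, and exact
masks; the cohort generator has no missing data, no overdispersion in
counts, and linear covariate effects. Passing tests therefore demonstrate
the *correctness of the measurement chain* under its stated model, not
clinical-grade robustness on scanner data.

## Problem sizes

The test suite and acceptance script use phantom grids of 64–128 voxels
in-plane and 6–20 slices, cohorts of 60–200 subjects (5000 for
convergence checks), 100-seed repetition for the stepwise and power
properties, and full enumeration for Fisher oracles up to N = 40 (2×2)
and N = 12 (2×3). These sizes were chosen so the whole suite runs in a
few minutes on one CPU while keeping every statistical tolerance at least
3 Monte-Carlo standard errors wide.
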