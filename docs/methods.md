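# Methods

## Problem

Single-case voxel-based morphometry (VBM) compares one subject's gray-matter
map against a control group with a mass-univariate general linear model. It is
the most extreme unbalanced two-sample design: with one observation in the
"patient" group, the central limit theorem offers no protection, so the
parametric t reference distribution — and the random-field-theory (RFT)
correction built on it — is only valid if the voxel intensities really are
Gaussian. A max-statistic permutation test needs only exchangeability of
subjects under the null and therefore controls the family-wise error rate
(FWER) exactly, at any marginal distribution.

This package implements both inference engines over a shared GLM core and
measures their empirical FWER on synthetic null cohorts where the marginal
distribution is known and controllable.

## Synthetic cohorts

`solocase.synthdata` generates brain-like volumes with exactly the properties
the inference stages are sensitive to, and nothing else:

* **Smoothness.** White noise is convolved with an isotropic Gaussian kernel
  of FWHM 4, 8 or 12 mm (sigma = FWHM / (2·sqrt(2 ln 2)) per axis) on a
  *periodic* lattice and rescaled by the exact kernel norm, giving a strictly
  stationary, unit-variance smooth field.
* **Marginal shape.** The Gaussian regime uses the field `z` directly. The
  skewed regime applies the monotone map `z -> exp(s·z)`, restandardized to
  mean 0 and variance 1. Because the transform is monotone and pointwise it
  preserves the spatial rank-correlation structure while producing marginal
  skewness `(e^{s^2}+2)·sqrt(e^{s^2}-1)`. The default `s = 0.5` (skewness
  ≈ 1.75) was chosen once as a realistic degree of non-normality for
  tissue-density-like maps; real VBM data are not characterized well enough
  to calibrate it, and the qualitative conclusions do not depend on it —
  larger `s` only inflates the parametric error rate further.
* **Intensity model.** Subject i's volume is `g_i · (1 + a·w_i)` inside an
  axis-aligned ellipsoidal support (≈ half the grid) and 0 outside, clipped at
  0, where `w_i` is the standardized (possibly skew-transformed) field,
  `a` the marginal amplitude, and `g_i = 1 + cv·eta_i` a per-subject global
  factor (default cv = 0.10) that proportional scaling must remove.
* **"Modulation".** The modulated / unmodulated labels are two generator
  parameterizations (amplitude 0.20 vs 0.15). Real modulation is a Jacobian
  operation on deformation fields and is deliberately out of scope; here the
  factor exists so the harness can test that it does *not* affect error rates.
* **Covariates.** Age ~ Normal(21.1, 1.8) years, gender ~ Bernoulli(0.5),
  independent of the image noise, matching a young-adult volunteer cohort.
* **Seeding.** One master seed; covariates and each subject's field use
  `SeedSequence`-spawned Philox substreams, so cohorts are bit-reproducible
  and independent of scheduling.

What the generator does **not** emulate: anatomical tissue boundaries,
registration error, spatially varying smoothness or skewness, and
age/gender-related structure in the images. Passing calibration tests here
therefore shows the engines behave correctly under their stated assumptions
(exchangeable subjects, stationary smooth fields); it does not quantify error
rates on any particular real data set.

## Shared GLM core

Per comparison (1 case + N controls, default N = 100):

1. **Global intensity** of each image: the mean of voxels above one-eighth of
   the image's overall mean (the classical single-pass convention). The
   defining software's manual never states this; the choice is recorded here
   because the relative mask depends on it.
2. **Proportional scaling**: each image multiplied by `target / global`
   (target 100; t-statistics are invariant to the value).
3. **Analysis mask**: a voxel is kept only if its intensity exceeds 20% of the
   image's global in *every* image of the comparison (intersection rule — the
   per-image reading of the ambiguous "20% of the mean image intensity").
4. **Design**: columns [case indicator, intercept, age (mean-centred),
   gender]; `df_error = n − rank` (97 for 101 subjects). Degenerate covariates
   lower the rank with a warning. A covariate-free two-column variant exists
   and reproduces the textbook pooled two-sample t exactly.
5. **t-map**: voxelwise OLS, `t = c'β / sqrt(σ̂² c'(X'X)⁻c)`, vectorized
   across voxels. Zero-residual-variance voxels get ±inf, are flagged, and are
   excluded from max-statistic extrema and from peak lists.

## Permutation engine

With N controls there are exactly N + 1 relabelings of the case role (the
observed one first). For each, the design is rebuilt with that subject as the
case — covariates stay attached to their subjects — and the t-map refit; the
maximum and minimum t over the mask form the null distribution of the
image-wide extremum. The FWE-corrected p at a voxel is the fraction of
relabelings whose maximum reaches that voxel's t (ties count as extreme;
the observed labeling counts itself, so p ≥ 1/(N+1) and every p is a multiple
of 1/(N+1); with 16 controls the floor is 1/17 = 0.0588). Increases and
decreases are tested separately at alpha = 0.05 with no extent threshold,
matching the convention of reporting the two directions as separate columns.
Simple relabeling of the case indicator (covariates fixed) is the default
nuisance-handling scheme; it is exact here because the synthetic covariates
are independent of the images.

## Parametric engine

The identical pipeline up to the t-map, then peak-level RFT correction:

* **Smoothness** is estimated from the residuals: each voxel's residual vector
  is normalized to unit length, and the per-axis roughness is the mean summed
  squared forward difference of these normalized residual fields over in-mask
  neighbour pairs; `FWHM_a = sqrt(4 ln 2 / λ_a)` voxels. On fields of known
  smoothness the estimator recovers the applied FWHM within a few percent
  (small positive bias from the discrete derivative).
* **RESEL counts** R0..R3 come from box-counting the mask lattice (points,
  edges, faces, cubes), the convention of the reference implementation. For a
  full n³ box R3 = (n−1)³/∏FWHM. This lattice convention — rather than
  `n_voxels/∏FWHM` — is what the Monte Carlo max-t oracle validates; the voxel
  convention would bias the 0.05 threshold upward by ≈ 0.06 t-units on the
  32³ validation grid.
* **EC densities** of a t-field with ν df are the standard closed forms; they
  converge to the Gaussian-field densities as ν → ∞. The corrected peak p is
  `min(1, Σ_d R_d ρ_d(t), V·ρ0(t))` — expected Euler characteristic capped by
  Bonferroni and by 1. The EC sum is negative for t ≲ 1, where the expansion
  is meaningless; it is treated as imposing no constraint there, keeping p
  monotone. df is fixed at n − rank with no Welch correction — deliberately
  the model whose fragility is under study.

Validation: on 32³ stationary t-fields (FWHM 3 voxels, df 20), the RFT
alpha = 0.05 peak threshold matches the empirical 95th percentile of the
max-t over 2000 Monte Carlo realizations within 0.15 t-units; in the
significance-relevant tail the permutation and RFT p-values of the global
maximum agree to within 0.03 on smooth Gaussian data.

## Experiment harness

An experiment draws, per condition (smoothing × modulation tag), a null pool
once, then runs M comparisons, each with a distinct case and a fresh draw of
N controls from the remainder. Controls are shared across comparisons — the
same non-independence the original design has, accepted deliberately; it
leaves the mean FWER untouched but widens its sampling variability beyond
binomial. Aggregation per condition and direction: the FWE count out of M, the
empirical FWER in percent, and the 95% Monte Carlo band
`100·(α ± 1.96·sqrt(α(1−α)/M))` floored at 0 — (0.7%, 9.3%) at α = 0.05,
M = 100.

Logistic regressions use the presence of a family-wise error per comparison
as outcome: model 1 on modulated data with smoothing (categorical, 4 mm
reference) and direction (increase = 1); model 2 at the shared smoothing level
with modulation and direction. Fitting is maximum likelihood
(`statsmodels.Logit`); each factor gets a joint Wald test, and goodness of fit
the Hosmer–Lemeshow chi-square over deciles of fitted risk (g = 10, df = g−2;
duplicate quantile edges are merged with a warning). Complete separation —
common when a factor level has zero errors at these rates — raises a named
error and the harness records the model as not fit.

Localization tallies suprathreshold peaks (local maxima under 18-connectivity,
face + edge neighbours) over a deterministic slab partition of the support
(linearly growing slab volumes, a stand-in for an anatomical lobe partition
with unequal region sizes), and Spearman's correlation relates region volume
to false-positive count; constant counts are reported as rho = 0, p = 1 with
a degeneracy flag.

## Problem sizes and numerical choices

The shipped analyses and tests use scaled-down study sizes chosen to keep the
full suite reproducible on a single CPU while leaving every statistical
property measurable: 24³ grids of 3 mm voxels (pool 120, 100 controls,
M = 100) for the headline calibration and inflation runs; 18³/14³ grids with
40–50 controls for multi-condition and replicate experiments; 2000 Monte
Carlo fields for the RFT threshold check. Tolerances: exact oracles at
1e-8–1e-10; stochastic checks use 95% Monte Carlo bands or 3-sigma binomial
bounds. Degenerate inputs (all-zero images, empty masks, flat residuals,
rank-deficient designs, constant outcomes) raise descriptive errors or
warnings rather than propagating NaNs.

## Known limitations

* Stationary smoothness and a single skew parameter per cohort: the spatially
  varying non-normality that concentrates real false positives in specific
  regions is not modelled, so the localization machinery is exercised but no
  anatomically meaningful clustering should be expected.
* Peak-level inference only; no cluster-extent or TFCE methods, no variance
  smoothing (pseudo-t), no Freedman–Lane residual permutation.
* The RFT implementation follows the standard expected-EC formulation; exact
  agreement with any particular release of the historical software is not
  claimed — validation is against the Monte Carlo max-t law instead.
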