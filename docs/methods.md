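# Methods

## Feature extraction model

All computation starts from a 3D scalar volume with spacing `(P, P, T)` mm
(`P` in-plane pixel size, `T` slice thickness along z) and a binary VOI mask
on the same grid. The number of masked voxels `N` and the physical VOI
volume are linked by the identity `N = VOI / (P·P·T)`, which the containers
maintain exactly (to floating-point rounding) and the pipeline re-verifies
on every data set.

The masked intensities are enumerated in a fixed z-major scan order,
discretized into `d` equispaced gray levels calibrated to the VOI's own
min–max range (`level = 1 + floor(d·(I − I_min)/(I_max − I_min))`, clamped
at `d`; a constant VOI maps to level 1 with a warning). Fixed-range
calibration is available as an option but relative (min–max) binning is the
default, matching common radiomics practice for CT.

Texture matrices are built volumetrically:

* **GLCM** — voxel pairs at Chebyshev distance 1 over the 13 unique 3D
  directions, both voxels in-mask; per-direction count matrices are
  symmetrized, normalized and averaged. Distance is 1 voxel (not mm).
* **GLRLM** — maximal equal-level runs along the same 13 directions, counts
  summed over directions (averaging available).
* **GLSZM** — zones are 26-connected equal-level components inside the mask.
* **NGTDM** — for each in-mask voxel with at least one in-mask 26-neighbor,
  `|level − mean in-mask neighbor level|` accumulated per level. Restricting
  neighborhoods to in-mask voxels (rather than requiring complete
  neighborhoods) keeps small and thin VOIs usable.

The 24 features are: Intensity TGV (total gray-level variation over in-mask
6-neighbor ordered pairs), Energy (Σ I²), Entropy (Shannon entropy of a
64-bin VOI-range histogram, bits) and Contrast (intensity range); 11 GLCM
features (Entropy, Sum/Difference Entropy, Sum/Difference Average,
Dissimilarity, Sum/Difference Variance, Mean, Contrast, Inverse Variance);
GLRLM GLNU, RLNU, HGRE, SRHGE; GLSZM HIE; NGTDM Contrast, Complexity,
Coarseness, Texture Strength. Sum Variance and Difference Variance are
mean-centered (second central moments of the `p_{x+y}` / `p_{x−y}`
marginals). Entropies use log₂.

## Normalizations

**Voxel-size normalization** replaces `f` by exactly one of `f·N`, `f/N`,
`f/ln N` per feature. The shipped assignment (an editable dict) was chosen
by scaling analysis of each feature's `N`-dependence:

| rule | features |
|---|---|
| `f/N` | Intensity-Energy, Intensity-TGV, GLRLM-GLNU, GLRLM-RLNU |
| `f/ln N` | Intensity-Entropy, Intensity-Contrast, GLCM-Mean, GLCM-Inverse Variance |
| `f·N` | NGTDM-Coarseness, NGTDM-Texture Strength |

Energy, TGV, GLNU and RLNU grow essentially linearly in `N` on stationary
texture; Coarseness and Texture Strength shrink with `N`; the `f/ln N`
group shows only a weak, sublinear dependence, so the least aggressive
correction is applied. Natural log is used in `f/ln N` (the base only
rescales values and leaves rank-correlation analyses invariant).

**Gray-level normalization** divides 17 texture features by `g(d)`:
`log₂ d` for the three GLCM entropies; `d` for GLCM Sum/Difference Average,
Dissimilarity, Mean and NGTDM Complexity; `d²` for GLCM Contrast and Sum
Variance, GLRLM HGRE/SRHGE, GLSZM HIE, NGTDM Contrast and Texture Strength;
`1` for GLRLM-GLNU and NGTDM-Coarseness (panel members needing no
rescaling). The factors follow each feature's leading `d`-scaling: level
indices enter averages linearly (`d`), squared differences quadratically
(`d²`), and entropies logarithmically.

## Robustness statistics

`|r_s|` between a feature and `N` uses average ranks for ties and a
Fisher-z 95% CI (`SE = 1/√(n−3)`); categories no / moderate / high at
0.5 and 0.9, boundaries falling in the middle category.

The ICC across gray-level counts is `(BMS − RMS)/(BMS + (d−1)·RMS)`. Two
readings of that formula exist and both are implemented; the default is the
**one-way random-effects ICC(1,1)**, where RMS is the within-subject mean
square, so that a systematic gray-level trend counts as instability. This
choice is forced by the scientific question: gray-level normalization is
designed to remove the common `d`-dependence of a feature, and a two-way
consistency model (ICC(3,1), available as `model="twoway"`) removes that
main effect itself — under it a normalization can only ever convert a
removable additive trend into a non-removable interaction, i.e. it can
never look beneficial. Negative ICCs are legitimate outputs (within-subject
variance exceeding between-subject variance). CIs use the standard
F-distribution bounds on BMS/RMS; categories not stable / intermediate /
highly stable at 0.5 and 0.8, boundaries in the middle category. Both
models are cross-checked in the tests against pingouin's ICC(1,1) and
ICC(C,1) and against a from-scratch sum-of-squares oracle.

## Resampling design

Each subject is expanded one-factor-at-a-time into 11 data sets: the
original, 4 pixel-size variants at the original thickness, and 6 thickness
variants at the original pixel size. Defaults: pixel sizes
{0.58, 0.84, 1.11, 1.38} mm (endpoints of the studied 0.58–1.38 mm range
with interior points evenly spread, chosen not to duplicate the typical
original pixel sizes 1.17 and 0.98 mm) and thicknesses
{1, 1.5, 2, 2.5, 3.5, 4} mm (six values over 1–4 mm avoiding the original
3 mm). Interpolation is trilinear; voxels are treated as cells, output
grids cover the input physical extent, and boundary samples clamp to edge
values. Masks are interpolated as float fields and re-thresholded at 0.5,
which preserves the physical VOI volume of smooth convex shapes to within
10% across this design (verified on ellipsoids). Nearest-neighbor mask
resampling is available as an option.

## Synthetic data generator

The generator emulates the *statistical* situation of a lung-SBRT cohort,
not anatomy:

* **Tumor cohort** (default 18 subjects): analytic volumes drawn
  log-uniformly from 4–123 cm³ (log-uniform mirrors the heavy spread of
  clinical volumes), realized as ellipsoids with axis ratios from
  [0.6, 1.4] voxelized at 1.17×1.17×3 mm (realized volume within 5% of the
  analytic draw), embedded with margin in stationary Gaussian random
  fields. Between-subject heterogeneity — without which between-subject
  variance, and hence any ICC, would be degenerate — comes from per-subject
  texture correlation length ~ U(3, 12) mm, texture SD ~ U(60, 140) HU and
  mean ~ N(40, 20) HU, plus 10 HU white voxel noise. Geometry (volume
  draws, shapes, sub-voxel centers) is driven by a separate fixed geometry
  seed so the cohort design stays constant while the texture seed varies
  realizations.
* **Phantom** : a cuboidal 14.2 cm³ VOI at 0.98×0.98×3 mm (integer voxel
  dimensions chosen to hit the target volume within about one voxel layer)
  over a single shared texture (correlation length 4 mm, SD 40 HU),
  replicated across 8 pseudo-scanners that add an intensity offset
  (SD 5 HU) and independent noise (SD 8 HU); zero perturbation reproduces
  identical scans.

The texture model is white noise convolved with a Gaussian kernel whose
width realizes autocorrelation `exp(−h²/(2ℓ²))` at lag `h` mm, rescaled to
the exact requested mean/SD. It is the simplest stationary model in which
the feature-vs-`N` and feature-vs-`d` scaling laws can be exercised.

**What passing tests do and do not show.** The generator reproduces the
bookkeeping of the study designs exactly and the qualitative direction of
both normalizations: raw GLNU/RLNU/Energy track `N` (|r_s| ≈ 0.9–1.0) while
their normalized versions drop sharply; every non-normalized entropy-type
ICC lies below its GL-normalized counterpart; and 8/17 GL-normalized
texture features reach ICC > 0.8 versus 1/17 non-normalized. Some patterns
reported for real CT are, however, *not reproducible* with Gaussian
fields, and this is a property of the texture model, not of the
normalization code:

* real CT texture stays rough at the voxel scale, so run lengths remain ~1
  at every resampled voxel size; a smooth Gaussian field's runs lengthen
  systematically under trilinear upsampling, leaving a monotone residual
  trend in RLNU/N that rank correlation detects however small;
* the GLCM entropy of a discretized Gaussian field is ≈ α·log₂ d + c with
  an O(1) intercept c, so entropy/log₂ d is not per-subject constant (for
  per-subject flatness within a few percent the intercept would have to be
  ≲ 0.5, and even pure white Gaussian noise has c ≈ −1.07);
* GLNU's robustness to `d` requires heavy-tailed intensity histograms (a
  few dominant bins at every `d`), which Gaussian marginals lack;
* NGTDM-Coarseness scales as 1/N only over narrow ranges (its denominator
  Σ p_i s_i is bounded by `d`), so the ×N correction over a 30-fold `N`
  range necessarily overcorrects.

## Numerical choices and degenerate inputs

* ε = 10⁻⁶ guards NGTDM denominators; a perfectly homogeneous VOI yields
  Coarseness 1/ε, Contrast/Complexity 0.
* GLCM Inverse Variance returns 0 when there is no off-diagonal mass
  (single-level VOI); constant VOIs are flagged (`degenerate_constant_voi`)
  rather than rejected.
* Intensity-histogram entropy treats a range at floating-point noise level
  as constant (entropy 0).
* GLCM is undefined (error) for VOIs with no valid voxel pair; NGTDM for
  VOIs where no voxel has an in-mask neighbor; Spearman for < 4 pairs or a
  constant sequence; ICC for < 2 levels, < 3 subjects or zero total
  variance.
* Mask binarization threshold is 0.5 everywhere (tolerant of interpolated
  masks).
* Default problem sizes: the 18-subject cohort at its native spacing gives
  grids of roughly 20–80 voxels per axis (up to ~120k VOI voxels at the
  finest resampling); the full two-experiment analysis completes in well
  under a minute on one CPU.

## Known limitations

No CT physics (reconstruction kernels, beam hardening, HU calibration),
no DICOM/RTSTRUCT ingestion (NIfTI only), no 2D slice-wise texture mode,
single-distance GLCM only, and no shape features beyond volume. The
synthetic cohort is a scaling test-bed: absolute feature values and
correlation magnitudes on real tumors will differ, in the directions
discussed above.
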