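# radnorm

Voxel-size and gray-level normalization of CT radiomic texture features, with
an end-to-end robustness analysis on synthetic tumor cohorts and phantom
scans.

## The problem

Radiomic features — intensity-histogram statistics and Haralick-style texture
features computed inside a segmented volume of interest (VOI) — are candidate
imaging biomarkers, but many of them depend intrinsically on two extraction
parameters rather than on tissue:

* the **number of voxels** `N(P, T) = VOI / (P·P·T)` inside the VOI, set
  jointly by tumor volume, in-plane pixel size `P` and slice thickness `T`;
* the **number of gray levels** `d` used to discretize the VOI intensities
  before building texture matrices.

A feature that tracks `N` or `d` mostly re-measures scanner geometry and
binning choices, not biology. `radnorm` implements 24 such features in 3D
(4 intensity-histogram, 11 GLCM, 4 GLRLM, 1 GLSZM, 4 NGTDM), plus the
per-feature normalizations that cancel those dependencies:

* **voxel-size normalization** — each affected feature `f` is replaced by
  exactly one of

  `f_n = f·N`,  `f_n = f/N`,  or  `f_n = f/log N`

  (10 features; the rule table is an editable dict,
  `radnorm.VOXEL_NORM_RULES`);
* **gray-level normalization** — each affected texture feature is divided by
  a factor `g(d) ∈ {1, d, d², log₂ d}` (17 features,
  `radnorm.GL_NORM_FACTORS`).

Robustness is quantified the way radiomics stability studies do it: the
absolute Spearman rank correlation `|r_s|` between a feature and `N` across
data sets (categories: no < 0.5, moderate 0.5–0.9, high > 0.9), and the
one-way intraclass correlation coefficient across gray-level counts,

`ICC = (BMS − RMS) / (BMS + (d − 1)·RMS)`

with BMS/RMS the between-subject and within-subject mean squares
(categories: not stable < 0.5, intermediate 0.5–0.8, highly stable > 0.8).
Both come with 95% confidence intervals (Fisher-z and F-bounds).

Because clinical scans are rarely shareable, the package ships a synthetic
data generator: ellipsoidal tumor VOIs with volumes drawn log-uniformly from
4–123 cm³ embedded in correlated Gaussian random fields at 1.17×1.17×3 mm
spacing, and a homogeneous-texture 14.2 cm³ phantom VOI at 0.98×0.98×3 mm
replicated across 8 pseudo-scanners. Volumes and masks round-trip through
NIfTI.

## Worked example

```python
from radnorm import (CohortSpec, generate_tumor_cohort,
                     extract_features, apply_voxel_normalization)

subject = generate_tumor_cohort(CohortSpec(n_subjects=1, seed=0))[0]
print("N =", subject.mask.n_voxels,
      " VOI volume =", round(subject.mask.voi_volume / 1000, 1), "cm^3")
rec = extract_features(subject.volume, subject.mask, d=64)
norm = apply_voxel_normalization(rec)
for name in ("Intensity-Energy", "GLRLM-GLNU", "GLRLM-RLNU", "NGTDM-Coarseness"):
    print(f"{name:<18} raw = {rec.values[name]:.4g}"
          f"   voxel-normalized = {norm.values[name]:.4g}")
```

prints

```
N = 27657  VOI volume = 113.6 cm^3
Intensity-Energy   raw = 3.474e+08   voxel-normalized = 1.256e+04
GLRLM-GLNU         raw = 1.13e+04   voxel-normalized = 0.4087
GLRLM-RLNU         raw = 2.664e+05   voxel-normalized = 9.631
NGTDM-Coarseness   raw = 0.0008022   voxel-normalized = 22.19
```

The raw Energy/GLNU/RLNU values are dominated by the ~28k voxels in this
large tumor; the normalized values are per-voxel quantities that can be
compared across tumors and voxel sizes. Coarseness is multiplied by `N`
because its raw value shrinks as voxels are added.

The same machinery runs as a CLI:

```bash
radnorm simulate --outdir data --seed 0          # NIfTI cohort + phantom + manifest
radnorm extract --volume v.nii.gz --mask m.nii.gz --out features.csv
radnorm run --mode both --outdir results --seed 0   # both experiments end-to-end
radnorm evaluate --features features_voxel.csv --stat spearman --out report.csv
```

`radnorm run` expands every subject into 11 data sets (the original plus 4
pixel sizes in 0.58–1.38 mm and 6 slice thicknesses in 1–4 mm, resampled
trilinearly), extracts the feature panel at 64 gray levels, and reports
`|r_s|` vs `N` per feature before/after voxel-size normalization; the
gray-level arm re-extracts the texture panel at d ∈ {8, 16, 32, 64, 128,
256} and reports the ICC before/after gray-level normalization, writing CSV
tables, a JSON report with a config echo, and paired bar charts
(black = non-normalized, gray = normalized).

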