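"""The 24 radiomic features and their voxel-count / gray-level normalizations.

Feature families
----------------
* Intensity histogram (4): TGV, Energy, Entropy, Contrast.
* GLCM (11): Entropy, Sum Entropy, Difference Entropy, Sum Average,
  Difference Average, Dissimilarity, Sum Variance, Difference Variance,
  Mean, Contrast, Inverse Variance.
* GLRLM (4): GLNU, RLNU, HGRE, SRHGE.
* GLSZM (1): HIE.
* NGTDM (4): Contrast, Complexity, Coarseness, Texture Strength.

Normalizations
--------------
Several of these features scale intrinsically with the number of voxels N
inside the VOI (equivalently with VOI size or voxel size, since
``N = VOI / (P*P*T)``).  Voxel-size normalization replaces the feature value
``f`` by exactly one of ``f*N``, ``f/N`` or ``f/log N`` per feature
(:data:`VOXEL_NORM_RULES`, 10 features).  Similarly, texture features depend
on the number of gray levels ``d`` used for discretization; gray-level
normalization divides each of 17 texture features by a feature-specific
factor ``g(d)`` in {1, d, d^2, log2 d} (:data:`GL_NORM_FACTORS`).  Both
tables are plain dicts and can be edited or passed explicitly.

Sum Variance and Difference Variance use mean-centered definitions (second
central moments of the p_{x+y} and p_{x-y} marginals).  Entropies use log2;
the ``f/log N`` rule uses the natural log (the base only rescales and leaves
rank-correlation analyses invariant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .discretize import discretize
from .texture import (
    GLCMatrix,
    GLRLMatrix,
    GLSZMatrix,
    NGTDMatrix,
    _offset_slices,
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
)
from .volume import ImageVolume, VOIExtract, VOIMask, extract_voi

__all__ = [
    "FEATURE_NAMES",
    "VOXEL_NORM_RULES",
    "GL_NORM_FACTORS",
    "VOXEL_PANEL",
    "GL_PANEL",
    "FeatureRecord",
    "intensity_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "extract_features",
    "apply_voxel_normalization",
    "apply_gl_normalization",
]

FEATURE_NAMES: tuple[str, ...] = (
    "Intensity-TGV",
    "Intensity-Energy",
    "Intensity-Entropy",
    "Intensity-Contrast",
    "GLCM-Entropy",
    "GLCM-Sum Entropy",
    "GLCM-Difference Entropy",
    "GLCM-Sum Average",
    "GLCM-Difference Average",
    "GLCM-Dissimilarity",
    "GLCM-Sum Variance",
    "GLCM-Difference Variance",
    "GLCM-Mean",
    "GLCM-Contrast",
    "GLCM-Inverse Variance",
    "GLRLM-GLNU",
    "GLRLM-RLNU",
    "GLRLM-HGRE",
    "GLRLM-SRHGE",
    "GLSZM-HIE",
    "NGTDM-Contrast",
    "NGTDM-Complexity",
    "NGTDM-Coarseness",
    "NGTDM-Texture Strength",
)

#: Per-feature voxel-size normalization rule: exactly one of multiply_N
#: (f*N), divide_N (f/N) or divide_logN (f/ln N) per normalized feature.
#: Features absent from this table pass through unchanged.
VOXEL_NORM_RULES: dict[str, str] = {
    "Intensity-TGV": "divide_N",
    "Intensity-Energy": "divide_N",
    "Intensity-Entropy": "divide_logN",
    "Intensity-Contrast": "divide_logN",
    "GLCM-Mean": "divide_logN",
    "GLCM-Inverse Variance": "divide_logN",
    "GLRLM-GLNU": "divide_N",
    "GLRLM-RLNU": "divide_N",
    "NGTDM-Coarseness": "multiply_N",
    "NGTDM-Texture Strength": "multiply_N",
}

#: Per-feature gray-level normalization factor g(d); the normalized value is
#: f / g(d).  Factor "1" marks features that belong to the GL-normalized
#: panel but need no rescaling.
GL_NORM_FACTORS: dict[str, str] = {
    "GLCM-Entropy": "log2d",
    "GLCM-Sum Entropy": "log2d",
    "GLCM-Difference Entropy": "log2d",
    "GLCM-Sum Average": "d",
    "GLCM-Difference Average": "d",
    "GLCM-Dissimilarity": "d",
    "GLCM-Mean": "d",
    "GLCM-Contrast": "d2",
    "GLCM-Sum Variance": "d2",
    "GLRLM-GLNU": "1",
    "GLRLM-HGRE": "d2",
    "GLRLM-SRHGE": "d2",
    "GLSZM-HIE": "d2",
    "NGTDM-Contrast": "d2",
    "NGTDM-Complexity": "d",
    "NGTDM-Coarseness": "1",
    "NGTDM-Texture Strength": "d2",
}

#: The 10-feature voxel-size normalization panel.
VOXEL_PANEL: tuple[str, ...] = tuple(VOXEL_NORM_RULES)

#: The 17-feature gray-level normalization panel (GLCM 9, GLRLM 3, GLSZM 1,
#: NGTDM 4).
GL_PANEL: tuple[str, ...] = tuple(GL_NORM_FACTORS)

_GL_FACTOR_FUNCS = {
    "1": lambda d: 1.0,
    "d": lambda d: float(d),
    "d2": lambda d: float(d) ** 2,
    "log2d": lambda d: math.log2(d),
}


@dataclass(frozen=True)
class FeatureRecord:
    """Named feature values with variant tag and (P, T, d) provenance."""

    subject: str
    variant: str                      # non_normalized | voxel_normalized | gl_normalized
    pixel_size: float
    slice_thickness: float
    n_gray_levels: int
    n_voxels: int
    values: dict[str, float]
    flags: tuple[str, ...] = field(default=())


def intensity_features(voi: VOIExtract, bins: int = 64) -> dict[str, float]:
    """First-order features from the VOI intensity histogram.

    Energy is the raw sum of squared intensities; Entropy the Shannon
    entropy (bits) of a ``bins``-bin histogram over the VOI min-max range;
    TGV the total gray-level variation, i.e. the summed absolute intensity
    difference over ordered in-mask 6-neighbor pairs; Contrast the VOI
    intensity range.
    """
    intensities = voi.intensities
    if intensities.size == 0:
        raise ValueError("empty VOI")
    energy = float(np.sum(intensities ** 2))
    lo, hi = float(intensities.min()), float(intensities.max())
    # a range at floating-point noise level (e.g. an interpolated constant
    # field) cannot support finite-width bins
    if hi - lo <= 1e-12 * max(abs(lo), abs(hi), 1.0):
        entropy = 0.0
    else:
        hist, _ = np.histogram(intensities, bins=bins, range=(lo, hi))
        p = hist[hist > 0] / intensities.size
        entropy = float(-np.sum(p * np.log2(p)))

    # total gray-level variation over 6-neighbor ordered pairs
    vol = np.zeros(voi.shape, dtype=np.float64)
    inmask = np.zeros(voi.shape, dtype=bool)
    idx = voi.index_map
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = intensities
    inmask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    tgv = 0.0
    for off in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        src, dst = _offset_slices(voi.shape, off)
        valid = inmask[src] & inmask[dst]
        tgv += 2.0 * float(np.abs(vol[src] - vol[dst])[valid].sum())

    return {
        "Intensity-TGV": tgv,
        "Intensity-Energy": energy,
        "Intensity-Entropy": entropy,
        "Intensity-Contrast": hi - lo,
    }


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The 11 co-occurrence features from a direction-averaged GLCM.

    Inverse Variance sums off-diagonal mass only; a single-level matrix has
    none and yields 0.
    """
    p = m.p
    d = m.d
    i = np.arange(1, d + 1, dtype=np.float64)
    diff_ij = i[:, None] - i[None, :]

    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))

    ps = m.p_sum
    k_sum = np.arange(2, 2 * d + 1, dtype=np.float64)
    nzs = ps > 0
    sum_entropy = float(-np.sum(ps[nzs] * np.log2(ps[nzs])))
    sum_average = float(np.sum(k_sum * ps))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * ps))

    pd_ = m.p_diff
    k_diff = np.arange(0, d, dtype=np.float64)
    nzd = pd_ > 0
    diff_entropy = float(-np.sum(pd_[nzd] * np.log2(pd_[nzd])))
    diff_average = float(np.sum(k_diff * pd_))
    diff_variance = float(np.sum((k_diff - diff_average) ** 2 * pd_))

    dissimilarity = float(np.sum(np.abs(diff_ij) * p))
    mean = float(np.sum(i[:, None] * p))
    contrast = float(np.sum(diff_ij ** 2 * p))
    off_diag = ~np.eye(d, dtype=bool)
    inverse_variance = float(np.sum(p[off_diag] / diff_ij[off_diag] ** 2)) if d > 1 else 0.0

    return {
        "GLCM-Entropy": entropy,
        "GLCM-Sum Entropy": sum_entropy,
        "GLCM-Difference Entropy": diff_entropy,
        "GLCM-Sum Average": sum_average,
        "GLCM-Difference Average": diff_average,
        "GLCM-Dissimilarity": dissimilarity,
        "GLCM-Sum Variance": sum_variance,
        "GLCM-Difference Variance": diff_variance,
        "GLCM-Mean": mean,
        "GLCM-Contrast": contrast,
        "GLCM-Inverse Variance": inverse_variance,
    }


def glrlm_features(m: GLRLMatrix) -> dict[str, float]:
    """Gray-level / run-length non-uniformity and high-gray-level emphases."""
    r = m.counts
    n_runs = r.sum()
    if n_runs <= 0:
        raise ValueError("GLRLM features undefined: zero runs")
    i2 = np.arange(1, m.d + 1, dtype=np.float64)[:, None] ** 2
    j2 = np.arange(1, m.max_run_length + 1, dtype=np.float64)[None, :] ** 2
    return {
        "GLRLM-GLNU": float(np.sum(r.sum(axis=1) ** 2) / n_runs),
        "GLRLM-RLNU": float(np.sum(r.sum(axis=0) ** 2) / n_runs),
        "GLRLM-HGRE": float(np.sum(r * i2) / n_runs),
        "GLRLM-SRHGE": float(np.sum(r * i2 / j2) / n_runs),
    }


def glszm_features(m: GLSZMatrix) -> dict[str, float]:
    """High-intensity emphasis on zones."""
    s = m.counts
    n_zones = s.sum()
    if n_zones <= 0:
        raise ValueError("GLSZM features undefined: zero zones")
    i2 = np.arange(1, m.d + 1, dtype=np.float64)[:, None] ** 2
    return {"GLSZM-HIE": float(np.sum(s * i2) / n_zones)}


def ngtdm_features(m: NGTDMatrix, eps: float = 1e-6) -> dict[str, float]:
    """Coarseness, Contrast, Complexity and Texture Strength.

    ``eps`` guards the Coarseness and Strength denominators; a perfectly
    homogeneous VOI therefore yields Coarseness 1/eps rather than infinity.
    """
    occ = m.n > 0
    levels = np.arange(1, m.d + 1, dtype=np.float64)
    p = m.p
    s = m.s

    coarseness = 1.0 / (eps + float(np.sum(p * s)))

    li = levels[occ]
    pi = p[occ]
    si = s[occ]
    n_gp = int(occ.sum())
    dij = li[:, None] - li[None, :]

    if n_gp > 1:
        contrast = (
            float(np.sum(pi[:, None] * pi[None, :] * dij ** 2)) / (n_gp * (n_gp - 1))
        ) * (float(s.sum()) / m.n_valid)
    else:
        contrast = 0.0

    pisi = pi * si
    denom = pi[:, None] + pi[None, :]
    complexity = float(
        np.sum(np.abs(dij) * (pisi[:, None] + pisi[None, :]) / denom)
    ) / m.n_valid

    strength_num = float(np.sum(denom * dij ** 2))
    strength = strength_num / (eps + float(s.sum()))

    return {
        "NGTDM-Contrast": contrast,
        "NGTDM-Complexity": complexity,
        "NGTDM-Coarseness": coarseness,
        "NGTDM-Texture Strength": strength,
    }


def features_from_discretized(voi: VOIExtract, dvoi, eps: float = 1e-6,
                              intensity_bins: int = 64) -> dict[str, float]:
    """All 24 features from an extracted VOI and its discretization."""
    values: dict[str, float] = {}
    values.update(intensity_features(voi, bins=intensity_bins))
    values.update(glcm_features(build_glcm(dvoi)))
    values.update(glrlm_features(build_glrlm(dvoi)))
    values.update(glszm_features(build_glszm(dvoi)))
    values.update(ngtdm_features(build_ngtdm(dvoi), eps=eps))
    return values


def extract_features(volume: ImageVolume, mask: VOIMask, d: int = 64,
                     subject: str = "subject", eps: float = 1e-6) -> FeatureRecord:
    """End-to-end non-normalized feature extraction for one (volume, mask).

    Discretizes the VOI to ``d`` equispaced gray levels (VOI min-max
    calibration) and computes the full 24-feature panel.  Degenerate
    constant VOIs are flagged rather than rejected.
    """
    voi = extract_voi(volume, mask)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        dvoi = discretize(voi, d)
    flags: tuple[str, ...] = ()
    if dvoi.calibration[0] == dvoi.calibration[1]:
        flags = ("degenerate_constant_voi",)
    values = features_from_discretized(voi, dvoi, eps=eps)
    return FeatureRecord(
        subject=subject,
        variant="non_normalized",
        pixel_size=volume.pixel_size,
        slice_thickness=volume.slice_thickness,
        n_gray_levels=d,
        n_voxels=voi.n_voxels,
        values=values,
        flags=flags,
    )


def apply_voxel_normalization(record: FeatureRecord,
                              rules: dict[str, str] | None = None) -> FeatureRecord:
    """Apply the per-feature voxel-count normalization.

    Exactly one of ``f*N``, ``f/N`` or ``f/ln N`` per feature in ``rules``;
    all other features pass through unchanged.  Requires ``N >= 2`` when any
    present feature uses the ``f/ln N`` rule.
    """
    if rules is None:
        rules = VOXEL_NORM_RULES
    n = record.n_voxels
    needs_log = any(
        rules.get(name) == "divide_logN" for name in record.values
    )
    if needs_log and n <= 1:
        raise ValueError(f"voxel normalization f/log N undefined for N = {n}")
    new_values: dict[str, float] = {}
    for name, value in record.values.items():
        rule = rules.get(name)
        if rule is None:
            new_values[name] = value
        elif rule == "multiply_N":
            new_values[name] = value * n
        elif rule == "divide_N":
            new_values[name] = value / n
        elif rule == "divide_logN":
            new_values[name] = value / math.log(n)
        else:
            raise ValueError(f"unknown voxel-normalization rule {rule!r} for {name}")
    return replace(record, variant="voxel_normalized", values=new_values)


def apply_gl_normalization(record: FeatureRecord,
                           factors: dict[str, str] | None = None) -> FeatureRecord:
    """Divide each panel feature by its gray-level factor g(d).

    Features absent from ``factors`` pass through unchanged; factor "1"
    keeps the value but marks panel membership.
    """
    if factors is None:
        factors = GL_NORM_FACTORS
    d = record.n_gray_levels
    if d < 2:
        raise ValueError(f"gray-level normalization undefined for d = {d}")
    new_values: dict[str, float] = {}
    for name, value in record.values.items():
        key = factors.get(name)
        if key is None:
            new_values[name] = value
        else:
            try:
                g = _GL_FACTOR_FUNCS[key](d)
            except KeyError:
                raise ValueError(f"unknown gray-level factor {key!r} for {name}") from None
            new_values[name] = value / g
    return replace(record, variant="gl_normalized", values=new_values)
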