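"""Synthetic stand-ins for the study data.

Real lung-tumor and texture-phantom CT scans are not publicly deposited, so
the experiments in this package run on synthetic emulations of the two
acquisitions:

* :func:`generate_tumor_cohort` — a cohort (default 18 subjects) of
  ellipsoidal VOIs with analytic volumes drawn log-uniformly from 4-123
  cm^3, embedded in stationary correlated Gaussian random fields at the
  clinical base spacing 1.17 x 1.17 x 3 mm.  Subjects differ in texture
  correlation length, texture amplitude and mean intensity, emulating
  between-patient tissue heterogeneity.
* :func:`generate_phantom_scans` — a homogeneous-texture cuboidal VOI of
  14.2 cm^3 at 0.98 x 0.98 x 3 mm, replicated across 8 pseudo-scanners that
  share one texture realization but add per-scanner intensity offsets and
  noise.

The texture model is a Gaussian-smoothed white-noise field — the simplest
stationary model in which feature-vs-N and feature-vs-d scaling laws are
exercisable; it makes no claim of anatomical realism.  The autocorrelation
of the generated field is Gaussian, rho(h) = exp(-h^2 / (2 ell^2)), where
``ell`` is the requested correlation length in mm.

Cohort geometry (volume draws, axis ratios, sub-voxel centers) is driven by
a dedicated geometry seed so that the cohort design stays fixed while the
texture seed varies realizations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import ImageVolume, VOIMask, save_mask, save_volume

__all__ = [
    "CohortSpec",
    "Subject",
    "generate_texture_field",
    "generate_tumor_cohort",
    "generate_phantom_scans",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic tumor cohort.

    Volumes are in cm^3, spacings and correlation lengths in mm,
    intensities in HU-like units.  ``seed`` drives texture and noise;
    ``geometry_seed`` drives tumor geometry (volume draws, axis ratios,
    sub-voxel centers), so the cohort design is reproducible independently
    of the texture realization.
    """

    n_subjects: int = 18
    volume_range_cm3: tuple[float, float] = (4.0, 123.0)
    spacing: tuple[float, float, float] = (1.17, 1.17, 3.0)
    correlation_length_range_mm: tuple[float, float] = (3.0, 12.0)
    mean_hu: float = 40.0
    mean_sd_hu: float = 20.0
    sd_range_hu: tuple[float, float] = (60.0, 140.0)
    noise_sd: float = 10.0
    axis_ratio_range: tuple[float, float] = (0.6, 1.4)
    margin_voxels: int = 6
    seed: int = 0
    geometry_seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.volume_range_cm3[0] <= 0 or self.volume_range_cm3[1] < self.volume_range_cm3[0]:
            raise ValueError(f"invalid volume range: {self.volume_range_cm3}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing: {self.spacing}")


@dataclass(frozen=True)
class Subject:
    """One synthetic scan: image volume, VOI mask and generation metadata."""

    subject_id: str
    volume: ImageVolume
    mask: VOIMask
    analytic_volume_mm3: float
    correlation_length_mm: float = float("nan")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_texture_field(shape, spacing, correlation_length: float,
                           mean: float, sd: float, seed=0) -> ImageVolume:
    """Stationary correlated Gaussian random field.

    White noise is convolved with a Gaussian kernel whose physical width
    realizes autocorrelation rho(h) = exp(-h^2 / (2 ell^2)) at lag h mm,
    then rescaled to the exact requested mean and standard deviation.
    Deterministic under ``seed`` (an int or a Generator).  Warns when the
    correlation length is below the voxel size along any axis (texture
    unresolvable at that sampling).
    """
    from scipy import ndimage

    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    if correlation_length <= 0 or sd < 0:
        raise ValueError("correlation length must be positive and sd non-negative")
    if correlation_length < min(spacing):
        warnings.warn(
            f"correlation length {correlation_length} mm below voxel size "
            f"{spacing} mm: texture unresolvable", stacklevel=2,
        )
    rng = _as_rng(seed)
    white = rng.standard_normal(shape)
    if sd == 0:
        return ImageVolume(np.full(shape, float(mean)), spacing)
    # kernel sigma ell/sqrt(2) (in mm) gives field autocorrelation
    # exp(-h^2/(2 ell^2)) after self-convolution of the kernel
    sigma_vox = [(correlation_length / math.sqrt(2)) / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    std = smooth.std()
    if std == 0:
        raise ValueError("degenerate field: smoothing removed all variance")
    values = mean + sd * (smooth - smooth.mean()) / std
    return ImageVolume(values, spacing)


def _ellipsoid_mask(shape, spacing, semi_axes_mm, center_vox) -> np.ndarray:
    """Analytic voxel-center membership of an axis-aligned ellipsoid."""
    grids = np.meshgrid(
        *(np.arange(n, dtype=np.float64) for n in shape), indexing="ij"
    )
    q = np.zeros(shape, dtype=np.float64)
    for g, c, a, s in zip(grids, center_vox, semi_axes_mm, spacing):
        q += ((g - c) * s / a) ** 2
    return q <= 1.0


def generate_tumor_cohort(spec: CohortSpec | None = None) -> list[Subject]:
    """Generate the synthetic tumor cohort defined by a :class:`CohortSpec`.

    Per subject: an analytic volume is drawn log-uniformly from the volume
    range, converted to an ellipsoid with axis ratios drawn from the
    configured range (volume preserved exactly), voxelized at the base
    spacing with a random sub-voxel center, and embedded in a textured
    field with a margin.  Raises when a requested volume is too small to
    contain at least 8 voxels.
    """
    if spec is None:
        spec = CohortSpec()
    geom_rng = np.random.default_rng(spec.geometry_seed)
    texture_rng = np.random.default_rng(spec.seed)
    lo, hi = spec.volume_range_cm3
    subjects: list[Subject] = []
    for k in range(spec.n_subjects):
        volume_mm3 = 1000.0 * math.exp(geom_rng.uniform(math.log(lo), math.log(hi)))
        ratios = geom_rng.uniform(*spec.axis_ratio_range, size=3)
        jitter = geom_rng.uniform(-0.5, 0.5, size=3)
        ell = geom_rng.uniform(*spec.correlation_length_range_mm)
        sd = geom_rng.uniform(*spec.sd_range_hu)
        mean = geom_rng.normal(spec.mean_hu, spec.mean_sd_hu)

        if volume_mm3 / (spec.spacing[0] * spec.spacing[1] * spec.spacing[2]) < 8:
            raise ValueError(
                f"requested volume {volume_mm3:.1f} mm^3 too small to contain "
                f">= 8 voxels at spacing {spec.spacing}"
            )
        r0 = (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        semi = r0 * ratios / ratios.prod() ** (1.0 / 3.0)
        shape = tuple(
            int(math.ceil(2.0 * a / s)) + 2 * spec.margin_voxels
            for a, s in zip(semi, spec.spacing)
        )
        center = tuple((n - 1) / 2.0 + j for n, j in zip(shape, jitter))
        flags = _ellipsoid_mask(shape, spec.spacing, semi, center)
        if flags.sum() < 8:
            raise ValueError(
                f"voxelized VOI of subject {k} has fewer than 8 voxels"
            )

        field = generate_texture_field(shape, spec.spacing, ell, mean, sd, texture_rng)
        values = field.values
        if spec.noise_sd > 0:
            values = values + texture_rng.normal(0.0, spec.noise_sd, size=shape)
        subjects.append(
            Subject(
                subject_id=f"subject{k + 1:02d}",
                volume=ImageVolume(values, spec.spacing),
                mask=VOIMask(flags, spec.spacing),
                analytic_volume_mm3=volume_mm3,
                correlation_length_mm=ell,
            )
        )
    return subjects


def generate_phantom_scans(n_scanners: int = 8, voi_volume_cm3: float = 14.2,
                           spacing: tuple[float, float, float] = (0.98, 0.98, 3.0),
                           seed=0, correlation_length: float = 4.0,
                           mean: float = 60.0, sd: float = 40.0,
                           scanner_offset_sd: float = 5.0,
                           scanner_noise_sd: float = 8.0,
                           margin_voxels: int = 6) -> list[Subject]:
    """Homogeneous-texture phantom VOI replicated across pseudo-scanners.

    One cuboidal VOI (integer voxel dimensions chosen to realize the target
    physical volume to within roughly one voxel layer) over a single shared
    stationary texture; each pseudo-scanner adds an intensity offset and
    independent noise.  With both perturbations set to 0 the scans are
    identical.
    """
    if n_scanners < 1 or voi_volume_cm3 <= 0:
        raise ValueError("need n_scanners >= 1 and a positive VOI volume")
    rng = _as_rng(seed)
    px, py, pz = (float(s) for s in spacing)
    target_n = voi_volume_cm3 * 1000.0 / (px * py * pz)
    side = (voi_volume_cm3 * 1000.0) ** (1.0 / 3.0)
    a = max(1, round(side / px))
    c = max(1, round(side / pz))
    b = max(1, round(target_n / (a * c)))
    m = margin_voxels
    shape = (a + 2 * m, b + 2 * m, c + 2 * m)
    base = generate_texture_field(shape, spacing, correlation_length, mean, sd, rng)
    flags = np.zeros(shape, dtype=bool)
    flags[m:m + a, m:m + b, m:m + c] = True
    mask = VOIMask(flags, (px, py, pz))

    scans: list[Subject] = []
    for k in range(n_scanners):
        offset = rng.normal(0.0, scanner_offset_sd) if scanner_offset_sd > 0 else 0.0
        values = base.values + offset
        if scanner_noise_sd > 0:
            values = values + rng.normal(0.0, scanner_noise_sd, size=shape)
        scans.append(
            Subject(
                subject_id=f"scanner{k + 1}",
                volume=ImageVolume(values, (px, py, pz)),
                mask=mask,
                analytic_volume_mm3=voi_volume_cm3 * 1000.0,
                correlation_length_mm=correlation_length,
            )
        )
    return scans


def write_cohort(subjects: list[Subject], outdir: str | Path) -> Path:
    """Write NIfTI (volume, mask) pairs plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        vol_path = outdir / f"{s.subject_id}_volume.nii.gz"
        mask_path = outdir / f"{s.subject_id}_mask.nii.gz"
        save_volume(s.volume, vol_path)
        save_mask(s.mask, mask_path)
        rows.append(
            {
                "subject": s.subject_id,
                "volume_file": vol_path.name,
                "mask_file": mask_path.name,
                "analytic_volume_mm3": s.analytic_volume_mm3,
                "realized_volume_mm3": s.mask.voi_volume,
                "n_voxels": s.mask.n_voxels,
                "pixel_size_mm": s.volume.pixel_size,
                "slice_thickness_mm": s.volume.slice_thickness,
                "correlation_length_mm": s.correlation_length_mm,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
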