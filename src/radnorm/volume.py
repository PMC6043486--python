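"""In-memory image volumes, VOI masks and NIfTI interchange.

The package represents a CT scan as a 3D scalar grid with per-axis spacing
``(P, P, T)`` in millimetres — in-plane pixel size ``P`` and slice thickness
``T`` along the longitudinal (z) axis — and a volume of interest (VOI) as a
binary grid aligned to it.  Everything downstream (resampling, discretization,
texture matrices, feature normalization) consumes these two containers plus
the ordered set of masked intensities extracted from them.

Conventions
-----------
* Axis order ``(x, y, z)`` with z the slice axis; 0-based voxel indices.
* World coordinates: ``origin + index * spacing`` (voxel centers).
* The VOI physical volume equals ``N * P * P * T`` for ``N`` masked voxels,
  so ``N = VOI / V_s(P, T)`` holds exactly up to floating-point rounding.
* NIfTI (.nii / .nii.gz) is the only interchange format; masks are uint8.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "VOIMask",
    "VOIExtract",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "extract_voi",
]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray
        3D grid of scalar intensities (HU-like; dimensionless for
        synthetic data), axis order (x, y, z).
    spacing : tuple of float
        Per-axis voxel spacing ``(P, P, T)`` in mm, all strictly positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"non-3D image: expected 3 axes, got {values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite intensities")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"non-positive spacing: {spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_size(self) -> float:
        """In-plane pixel size P in mm."""
        return self.spacing[0]

    @property
    def slice_thickness(self) -> float:
        """Slice thickness T in mm (z axis)."""
        return self.spacing[2]

    @property
    def voxel_volume(self) -> float:
        """Single-voxel volume ``V_s(P, T) = P * P * T`` in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass(frozen=True)
class VOIMask:
    """A binary VOI aligned with an :class:`ImageVolume` grid.

    Stores the boolean flags plus the spacing needed to convert the voxel
    count ``N`` into the physical VOI volume ``N * P * P * T`` (mm^3).
    """

    flags: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags)
        if flags.dtype != np.bool_:
            flags = flags > 0.5
        if flags.ndim != 3:
            raise ValueError(f"non-3D mask: expected 3 axes, got {flags.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"non-positive spacing: {spacing}")
        if not flags.any():
            raise ValueError("empty VOI: mask selects no voxels")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """Number of voxels N inside the VOI."""
        return int(self.flags.sum())

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voi_volume(self) -> float:
        """Physical VOI volume in mm^3 (``N * P * P * T``)."""
        return self.n_voxels * self.voxel_volume


@dataclass(frozen=True)
class VOIExtract:
    """The ordered collection of intensities at masked voxels.

    Enumeration order is deterministic: z-major, then y, then x (slices
    outermost).  ``index_map[k]`` gives the ``(x, y, z)`` grid coordinate of
    the k-th intensity, so downstream code can place derived quantities
    (e.g. discretized gray levels) back onto the 3D grid.
    """

    intensities: np.ndarray
    index_map: np.ndarray
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return int(self.intensities.size)

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume to NIfTI, spacing carried in the header."""
    path = Path(path)
    img = nib.Nifti1Image(volume.values, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)
    return path


def save_mask(mask: VOIMask, path: str | Path, origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Path:
    """Write a VOI mask to NIfTI as uint8 {0, 1}."""
    path = Path(path)
    img = nib.Nifti1Image(mask.flags.astype(np.uint8), _affine(mask.spacing, origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)
    return path


def load_volume(path: str | Path) -> ImageVolume:
    """Load a 3D scalar image from a NIfTI file.

    Spacing is read from the header zooms and the origin from the affine
    translation.  Raises for missing files, non-3D images and non-positive
    spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} axes")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive spacing in header of {path}: {zooms}")
    origin = tuple(float(t) for t in np.asarray(img.affine)[:3, 3])
    return ImageVolume(values=data.astype(np.float64), spacing=zooms, origin=origin)


def load_mask(path: str | Path, reference: ImageVolume) -> VOIMask:
    """Load a VOI mask from NIfTI and align it with a reference volume.

    Values above 0.5 are treated as inside the VOI (tolerant of
    interpolated float masks).  The mask grid must match the reference
    shape and must not be empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D mask: {path} has {data.ndim} axes")
    if data.shape != reference.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match volume shape {reference.shape}"
        )
    return VOIMask(flags=data > 0.5, spacing=reference.spacing)


def extract_voi(volume: ImageVolume, mask: VOIMask) -> VOIExtract:
    """Enumerate the masked intensities in fixed z-major scan order."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask shape {mask.shape}"
        )
    # argwhere on the (z, y, x)-transposed mask yields lexicographic (z, y, x)
    # order; flip columns back to (x, y, z).
    zyx = np.argwhere(np.transpose(mask.flags, (2, 1, 0)))
    coords = zyx[:, ::-1]
    intensities = volume.values[coords[:, 0], coords[:, 1], coords[:, 2]]
    return VOIExtract(
        intensities=intensities,
        index_map=coords,
        spacing=volume.spacing,
        shape=volume.shape,
    )
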