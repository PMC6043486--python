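"""Equispaced gray-level discretization of VOI intensities.

All texture matrices operate on gray levels ``1..d`` obtained by binning the
VOI intensities into ``d`` equal-width bins calibrated to the VOI's own
min-max range (relative binning).  ``d`` is conventionally a power of two
between 8 and 256; 64 is the default used for the voxel-size experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import VOIExtract

__all__ = ["DiscretizedVOI", "discretize"]


@dataclass(frozen=True)
class DiscretizedVOI:
    """Gray levels aligned with a :class:`~radnorm.volume.VOIExtract`.

    ``levels[k]`` is the level (in ``1..d``) of the k-th masked voxel in the
    extract's scan order; ``calibration`` records the (min, max) intensity
    used for binning.  :attr:`grid` places the levels back on the 3D grid
    with 0 marking out-of-mask voxels, which is what the texture-matrix
    builders consume.
    """

    levels: np.ndarray
    d: int
    calibration: tuple[float, float]
    voi: VOIExtract

    @property
    def n_voxels(self) -> int:
        return int(self.levels.size)

    @property
    def grid(self) -> np.ndarray:
        """3D int grid of levels, 0 outside the mask."""
        g = np.zeros(self.voi.shape, dtype=np.int32)
        idx = self.voi.index_map
        g[idx[:, 0], idx[:, 1], idx[:, 2]] = self.levels
        return g


def discretize(voi: VOIExtract, d: int, mode: str = "voi_minmax",
               fixed_range: tuple[float, float] | None = None) -> DiscretizedVOI:
    """Bin VOI intensities into ``d`` equispaced gray levels.

    ``level(v) = 1 + floor(d * (I(v) - lo) / (hi - lo))`` clamped to ``d``
    at the maximum, with ``(lo, hi)`` the VOI min-max (default) or a fixed
    intensity range.  A constant VOI maps every voxel to level 1 with a
    warning rather than failing.
    """
    if not 2 <= d <= 256:
        raise ValueError(f"number of gray levels must be in [2, 256], got {d}")
    if voi.n_voxels == 0:
        raise ValueError("cannot discretize an empty VOI")
    intensities = voi.intensities
    if mode == "voi_minmax":
        lo, hi = float(intensities.min()), float(intensities.max())
    elif mode == "fixed_range":
        if fixed_range is None:
            raise ValueError("fixed_range mode requires an explicit (lo, hi)")
        lo, hi = float(fixed_range[0]), float(fixed_range[1])
        if hi <= lo:
            raise ValueError(f"invalid fixed range: {fixed_range}")
    else:
        raise ValueError(f"unknown discretization mode: {mode!r}")

    if hi == lo:
        warnings.warn("constant VOI: all voxels assigned gray level 1", stacklevel=2)
        levels = np.ones(voi.n_voxels, dtype=np.int32)
    else:
        frac = (intensities - lo) / (hi - lo)
        levels = 1 + np.floor(d * frac).astype(np.int32)
        np.clip(levels, 1, d, out=levels)
    return DiscretizedVOI(levels=levels, d=int(d), calibration=(lo, hi), voi=voi)
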