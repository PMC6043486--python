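from __future__ import annotations

import numpy as np
import pytest

from radnorm.discretize import DiscretizedVOI
from radnorm.volume import VOIExtract


def dvoi_from_grid(grid: np.ndarray, d: int | None = None) -> DiscretizedVOI:
    """Wrap a ready-made level grid (0 = outside mask) as a DiscretizedVOI."""
    grid = np.asarray(grid, dtype=np.int32)
    if d is None:
        d = int(grid.max())
    zyx = np.argwhere(np.transpose(grid > 0, (2, 1, 0)))
    coords = zyx[:, ::-1]
    levels = grid[coords[:, 0], coords[:, 1], coords[:, 2]]
    voi = VOIExtract(
        intensities=levels.astype(np.float64),
        index_map=coords,
        spacing=(1.0, 1.0, 1.0),
        shape=grid.shape,
    )
    return DiscretizedVOI(levels=levels, d=d, calibration=(1.0, float(d)), voi=voi)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
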