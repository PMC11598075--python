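"""Shared fixtures: analytic solids and small phantom cohorts.

All geometry fixtures are generated programmatically so every expected
value has a closed form (ball, ellipsoid, cube) or a brute-force oracle
computed in the test itself.
"""

from __future__ import annotations

import numpy as np
import pytest

from ftvmorph.core import TumorMask


def make_ball(radius_mm: float, spacing: float = 1.0,
              n: int | None = None, stage: str = "raw") -> TumorMask:
    """Digital ball: voxel centers within radius of the grid center."""
    if n is None:
        n = int(np.ceil(2 * radius_mm / spacing)) + 7
    c = (n - 1) / 2
    ax = (np.arange(n) - c) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return TumorMask(x * x + y * y + z * z <= radius_mm**2,
                     (spacing,) * 3, stage=stage)


def make_ellipsoid(semi_axes_mm, spacing: float = 1.0,
                   rotation: np.ndarray | None = None,
                   stage: str = "raw") -> TumorMask:
    """Digital solid ellipsoid, optionally rotated about the center."""
    a = np.asarray(semi_axes_mm, dtype=float)
    half = float(np.max(a)) + 4 * spacing
    n = int(np.ceil(2 * half / spacing)) | 1
    c = (n - 1) / 2
    ax = (np.arange(n) - c) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([x, y, z], axis=-1)
    if rotation is not None:
        pts = pts @ rotation  # rotate coordinates into body frame
    inside = ((pts[..., 0] / a[0]) ** 2 + (pts[..., 1] / a[1]) ** 2
              + (pts[..., 2] / a[2]) ** 2) <= 1.0
    return TumorMask(inside, (spacing,) * 3, stage=stage)


def make_cube(side_mm: float, spacing: float = 1.0,
              stage: str = "raw") -> TumorMask:
    n_side = int(round(side_mm / spacing))
    n = n_side + 6
    arr = np.zeros((n, n, n), dtype=bool)
    arr[3:3 + n_side, 3:3 + n_side, 3:3 + n_side] = True
    return TumorMask(arr, (spacing,) * 3, stage=stage)


@pytest.fixture(scope="session")
def ball10() -> TumorMask:
    return make_ball(10.0)


@pytest.fixture(scope="session")
def ellipsoid_20_10_5() -> TumorMask:
    return make_ellipsoid((20.0, 10.0, 5.0))
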