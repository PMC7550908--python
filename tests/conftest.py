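"""Shared fixtures and brute-force oracle helpers.

Oracles here are deliberately naive (python loops, all-pairs distances,
voxel sorts) and independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from contourdose import DoseGrid, GridSpec, StructureMask


@pytest.fixture
def unit_grid() -> GridSpec:
    """8×8×8 grid, isotropic 1 mm, origin at 0."""
    return GridSpec(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def aniso_grid() -> GridSpec:
    """Anisotropic grid resembling CT geometry (thicker slices)."""
    return GridSpec(shape=(12, 10, 6), spacing=(1.5, 2.0, 5.0), origin=(-5.0, 3.0, 0.0))


def make_mask(grid: GridSpec, where, name: str = "s", source: str = "manual") -> StructureMask:
    vox = np.zeros(grid.shape, dtype=bool)
    vox[where] = True
    return StructureMask(grid=grid, voxels=vox, name=name, source=source)


def make_dose(grid: GridSpec, values) -> DoseGrid:
    return DoseGrid(grid=grid, values=np.broadcast_to(np.asarray(values, float), grid.shape).copy())


def random_blob(grid: GridSpec, rng: np.random.Generator, p_empty: float = 0.0) -> StructureMask:
    """Random connected-ish blob: union of a few random balls (may be lumpy)."""
    vox = np.zeros(grid.shape, dtype=bool)
    centers = grid.centers_mm()
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    if rng.random() >= p_empty:
        for _ in range(rng.integers(1, 4)):
            c = np.asarray(grid.origin) + extent * rng.random(3)
            r = extent.min() * (0.15 + 0.3 * rng.random())
            vox |= np.sum((centers - c) ** 2, axis=-1) <= r**2
    return StructureMask(grid=grid, voxels=vox, name="blob")


# --- oracles ---------------------------------------------------------------

def oracle_surface_points(mask: StructureMask) -> np.ndarray:
    """Boundary-voxel centers via an explicit 6-neighbor loop."""
    vox = mask.voxels
    nx, ny, nz = vox.shape
    pts = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not vox[i, j, k]:
                    continue
                exposed = False
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not vox[a, b, c]:
                        exposed = True
                        break
                if exposed:
                    pts.append((i, j, k))
    return np.asarray(mask.grid.origin) + np.asarray(pts, float) * np.asarray(mask.grid.spacing)


def oracle_directed_mda(a: StructureMask, b: StructureMask) -> float:
    """All-pairs nearest-distance mean from a's surface to b's surface."""
    pa, pb = oracle_surface_points(a), oracle_surface_points(b)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=-1))
    return float(d.min(axis=1).mean())


def oracle_dx(doses_in_mask: np.ndarray, x_percent: float) -> float:
    """Largest dose d with at least x% of voxels >= d (voxel-sort rule)."""
    s = np.sort(doses_in_mask)[::-1]
    k = int(np.ceil(x_percent / 100.0 * s.size))
    return float(s[k - 1])


def oracle_vx(doses_in_mask: np.ndarray, x_gy: float) -> float:
    return float(100.0 * np.mean(doses_in_mask >= x_gy))
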