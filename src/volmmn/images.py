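"""Scalp-time images: channel-to-grid interpolation and mask-aware smoothing.

Sensor data are interpolated onto a regular 2D scalp grid (linear
interpolation on the Delaunay triangulation of the 2D channel positions,
nearest-neighbour fill inside the hull margin) for every retained time
sample between 100 and 400 ms, giving a 3D (x, y, time) volume per trial or
condition. Volumes are smoothed with a spatial-only Gaussian kernel
(default FWHM 16 mm x 16 mm), renormalized inside the scalp mask so that
constant images are preserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay

from .montage import Montage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ImageGeometry:
    """Regular scalp-time grid.

    x/y are scalp millimetres (left-right / posterior-anterior), z is
    peristimulus time in ms.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    t_ms: np.ndarray
    smooth_fwhm_mm: tuple[float, float] = (16.0, 16.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x_mm.size, self.y_mm.size, self.t_ms.size)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return (
            float(self.x_mm[1] - self.x_mm[0]),
            float(self.y_mm[1] - self.y_mm[0]),
            float(self.t_ms[1] - self.t_ms[0]),
        )

    @classmethod
    def default(cls, montage: Montage) -> "ImageGeometry":
        """Published geometry: 4.2 x 5.4 mm x 4.0 ms voxels, 100-400 ms."""
        return cls._from_spacing(montage, 4.2, 5.4, 4.0)

    @classmethod
    def reduced(cls, montage: Montage) -> "ImageGeometry":
        """Coarse 16 x 16 x 38 grid (8 ms bins) for simulation studies."""
        lo = montage.pos2d.min(axis=0)
        hi = montage.pos2d.max(axis=0)
        x = np.linspace(lo[0] - 5, hi[0] + 5, 16)
        y = np.linspace(lo[1] - 5, hi[1] + 5, 16)
        t = np.arange(100.0, 400.1, 8.0)  # 38 bins
        return cls(x_mm=x, y_mm=y, t_ms=t)

    @classmethod
    def _from_spacing(cls, montage: Montage, dx: float, dy: float, dt: float) -> "ImageGeometry":
        lo = montage.pos2d.min(axis=0) - np.array([dx, dy])
        hi = montage.pos2d.max(axis=0) + np.array([dx, dy])
        x = np.arange(lo[0], hi[0] + dx / 2, dx)
        y = np.arange(lo[1], hi[1] + dy / 2, dy)
        t = np.arange(100.0, 400.0 + dt / 2, dt)
        return cls(x_mm=x, y_mm=y, t_ms=t)

    def sigma_vox(self) -> tuple[float, float]:
        dx, dy, _ = self.voxel_size
        return (
            self.smooth_fwhm_mm[0] * FWHM_TO_SIGMA / dx,
            self.smooth_fwhm_mm[1] * FWHM_TO_SIGMA / dy,
        )


class ScalpMapper:
    """Precomputed channel-to-grid interpolation for one montage/geometry."""

    def __init__(self, montage: Montage, geometry: ImageGeometry):
        self.montage = montage
        self.geometry = geometry
        pts = montage.pos2d
        gx, gy = np.meshgrid(geometry.x_mm, geometry.y_mm, indexing="ij")
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        hull = Delaunay(pts)
        inside = hull.find_simplex(grid) >= 0
        self.mask2d = inside.reshape(gx.shape)

        lin = LinearNDInterpolator(pts, np.eye(len(pts)))
        w = lin(grid)  # (n_grid, n_ch), NaN outside hull
        near = NearestNDInterpolator(pts, np.eye(len(pts)))
        nan_rows = np.isnan(w).any(axis=1)
        w[nan_rows] = near(grid[nan_rows])
        self.weights = w  # (n_grid, n_ch)

    @property
    def mask3d(self) -> np.ndarray:
        return np.broadcast_to(
            self.mask2d[:, :, None], self.geometry.shape
        ).copy()

    def time_indices(self, times_ms: np.ndarray) -> np.ndarray:
        idx = np.array([np.argmin(np.abs(times_ms - t)) for t in self.geometry.t_ms])
        if np.max(np.abs(times_ms[idx] - self.geometry.t_ms)) > 1e-6:
            raise ValueError("geometry time bins are not sampled by the epochs")
        return idx

    def to_images(self, data: np.ndarray, times_ms: np.ndarray) -> np.ndarray:
        """Interpolate (…, n_ch, n_times) sensor data to (…, nx, ny, nt).

        Grid voxels outside the scalp hull are zeroed (and masked).
        """
        idx = self.time_indices(times_ms)
        sel = np.asarray(data)[..., idx]  # (..., ch, nt)
        img = np.einsum("gc,...ct->...gt", self.weights, sel)
        nx, ny, nt = self.geometry.shape
        img = img.reshape(*data.shape[:-2], nx, ny, nt)
        img *= self.mask2d[..., :, :, None]
        return img


def smooth_images(stack: np.ndarray, mapper: ScalpMapper) -> np.ndarray:
    """Spatial-only Gaussian smoothing, mask-aware so constants are preserved."""
    geom = mapper.geometry
    sx, sy = geom.sigma_vox()
    mask = mapper.mask2d.astype(float)
    sm_mask = ndimage.gaussian_filter(mask, (sx, sy), mode="constant")
    out = np.empty_like(stack, dtype=float)
    flat = stack.reshape(-1, *geom.shape)
    oflat = out.reshape(-1, *geom.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(flat.shape[0]):
            sm = ndimage.gaussian_filter(
                flat[i] * mask[:, :, None], (sx, sy, 0), mode="constant"
            )
            oflat[i] = np.where(mask[:, :, None] > 0, sm / sm_mask[:, :, None], 0.0)
    return out


def make_images(
    data: np.ndarray,
    times_ms: np.ndarray,
    mapper: ScalpMapper,
    smooth: bool = True,
) -> np.ndarray:
    """Convenience: interpolate then (optionally) smooth."""
    img = mapper.to_images(data, times_ms)
    return smooth_images(img, mapper) if smooth else img
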