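"""Radial power spectrum of a region via the 3D discrete Fourier transform.

Each region unit is zero-embedded into an N^3 cube (relative voxel geometry
preserved, bounding box centered), transformed with the 3D DFT, and the
magnitude spectrum is averaged over concentric rings of width one in
integer frequency radius r = round(sqrt(u^2 + v^2 + w^2)), with the DC
component at radius zero.  The descriptor has floor(N/2) rings (up to the
Nyquist frequency); the magnitude |F|, not |F|^2, is averaged.  Frequency
radii treat the three axes isotropically.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .roi import RegionUnit, SamplingTemplate, extract_region_stack
from .series import DynamicSeries
from .trajectory import DescriptorTrajectory

__all__ = ["embed_region", "dft3_magnitude", "radial_average", "rps",
           "rps_trajectory", "n_rings"]


def n_rings(cube_side: int) -> int:
    return cube_side // 2


def embed_region(values: np.ndarray, coords: np.ndarray, cube_side: int) -> np.ndarray:
    """Zero-embed region voxels into a cube, bounding box centered.

    ``coords`` are (slice, row, col) voxel indices; translation preserves the
    relative geometry, so the magnitude spectrum is translation invariant.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be V x 3")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    extent = hi - lo + 1
    if np.any(extent > cube_side):
        raise ValueError(
            f"region bounding box {tuple(extent)} exceeds cube side {cube_side}")
    offset = (cube_side - extent) // 2 - lo
    cube = np.zeros((cube_side,) * 3)
    shifted = coords + offset
    cube[shifted[:, 0], shifted[:, 1], shifted[:, 2]] = values
    return cube


def dft3_magnitude(cube: np.ndarray) -> np.ndarray:
    """Magnitude of the 3D DFT of a cubic volume."""
    cube = np.asarray(cube)
    if cube.ndim != 3 or len(set(cube.shape)) != 1:
        raise ValueError(f"input must be a cube, got shape {cube.shape}")
    return np.abs(np.fft.fftn(cube))


@lru_cache(maxsize=4)
def _ring_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat ring index per frequency voxel and member count per ring."""
    f = (np.fft.fftfreq(n) * n).astype(np.float32)
    r2 = f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2
    rings = np.rint(np.sqrt(r2)).astype(np.int32).ravel()
    counts = np.bincount(rings)
    return rings, counts


def radial_average(magnitude: np.ndarray) -> np.ndarray:
    """Mean of |F| over integer-radius rings; floor(N/2) rings returned.

    Ring r holds frequency voxels whose centered radius rounds to r; ring 0
    is the DC component alone.  Rings without members (none below Nyquist)
    would be zero.
    """
    magnitude = np.asarray(magnitude)
    if magnitude.ndim != 3 or len(set(magnitude.shape)) != 1:
        raise ValueError(f"spectrum must be a cube, got shape {magnitude.shape}")
    n = magnitude.shape[0]
    rings, counts = _ring_index(n)
    sums = np.bincount(rings, weights=magnitude.ravel(), minlength=len(counts))
    nb = n_rings(n)
    out = np.zeros(nb)
    nonzero = counts[:nb] > 0
    out[nonzero] = sums[:nb][nonzero] / counts[:nb][nonzero]
    return out


def rps(values: np.ndarray, coords: np.ndarray, cube_side: int) -> np.ndarray:
    """Radial power spectrum of one region at one frame."""
    return radial_average(dft3_magnitude(embed_region(values, coords, cube_side)))


def rps_trajectory(series: DynamicSeries, template: SamplingTemplate,
                   unit: RegionUnit, cube_side: int = 256) -> DescriptorTrajectory:
    """RPS per frame: a floor(cube_side/2) x T trajectory."""
    stack = extract_region_stack(series, template, unit)
    T = stack.values.shape[0]
    out = np.empty((n_rings(cube_side), T))
    for t in range(T):
        out[:, t] = rps(stack.values[t], stack.coords, cube_side)
    names = [f"ring{r:03d}" for r in range(out.shape[0])]
    return DescriptorTrajectory(descriptor="RPS", unit=unit, values=out,
                                frame_times_s=stack.frame_times_s,
                                feature_names=names)
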