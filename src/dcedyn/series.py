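"""Acquisition geometry and the 4D dynamic series container.

A DCE-MRI acquisition is a stack of T1-weighted volumes taken before and
after contrast injection.  Axis order here is (time, slice, row, col); the
NIfTI on-disk order (col, row, slice, time) is handled at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["AcquisitionGeometry", "DynamicSeries", "load_series", "load_label_map",
           "save_label_map"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Spatial and temporal layout of a dynamic acquisition.

    Defaults reproduce the study protocol: 256x192 reconstruction over a
    24 cm field of view (0.9375 mm in-plane), 42 slices of 4 mm, and 21
    frames at 73 s giving a ~24 min dynamic run.
    """

    n_rows: int = 256
    n_cols: int = 192
    n_slices: int = 42
    in_plane_spacing: float = 0.9375  # mm / voxel
    slice_thickness: float = 4.0      # mm
    n_frames: int = 21
    frame_interval: float = 73.0      # seconds

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "n_slices", "n_frames"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("in_plane_spacing", "slice_thickness", "frame_interval"):
            if float(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @classmethod
    def paper(cls) -> "AcquisitionGeometry":
        """The full-protocol geometry (the default field values)."""
        return cls()

    @classmethod
    def small(cls, n_frames: int = 21) -> "AcquisitionGeometry":
        """A 64x64x8 test geometry.

        Keeps the 0.9375 mm in-plane spacing (i.e. a cropped field of view,
        not a coarser grid) so that a 12 mm^2 circular sample still covers
        13 voxels and texture descriptors remain well defined.
        """
        return cls(n_rows=64, n_cols=64, n_slices=8, n_frames=n_frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape as (slices, rows, cols)."""
        return (self.n_slices, self.n_rows, self.n_cols)

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def frame_times_min(self) -> np.ndarray:
        return self.frame_times_s / 60.0


@dataclass
class DynamicSeries:
    """A 4D dynamic image: ``data[t, z, r, c]`` plus its geometry."""

    data: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        expected = (self.geometry.n_frames,) + self.geometry.shape
        if self.data.shape != expected:
            raise ValueError(
                f"series shape {self.data.shape} does not match geometry {expected}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]

    def _affine(self) -> np.ndarray:
        g = self.geometry
        return np.diag([g.in_plane_spacing, g.in_plane_spacing, g.slice_thickness, 1.0])

    def to_nifti(self, path) -> None:
        """Write as NIfTI-1 with on-disk axis order (col, row, slice, time)."""
        arr = np.transpose(self.data, (3, 2, 1, 0))
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), self._affine())
        img.header.set_zooms((self.geometry.in_plane_spacing,
                              self.geometry.in_plane_spacing,
                              self.geometry.slice_thickness,
                              self.geometry.frame_interval))
        nib.save(img, str(path))


def load_series(path, geometry: AcquisitionGeometry | None = None) -> DynamicSeries:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {arr.shape}")
    data = np.transpose(arr, (3, 2, 1, 0)).astype(np.float64)
    if geometry is None:
        zooms = img.header.get_zooms()
        geometry = AcquisitionGeometry(
            n_rows=data.shape[2], n_cols=data.shape[3], n_slices=data.shape[1],
            in_plane_spacing=float(zooms[0]), slice_thickness=float(zooms[2]),
            n_frames=data.shape[0],
            frame_interval=float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 73.0)
    return DynamicSeries(data=data, geometry=geometry)


def save_label_map(label_map: np.ndarray, geometry: AcquisitionGeometry, path) -> None:
    arr = np.transpose(label_map.astype(np.int16), (2, 1, 0))
    affine = np.diag([geometry.in_plane_spacing, geometry.in_plane_spacing,
                      geometry.slice_thickness, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_label_map(path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D label map, got shape {arr.shape}")
    return np.transpose(arr, (2, 1, 0)).astype(np.int16)
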