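import numpy as np
import pytest

from dcedyn import phantom, roi
from dcedyn.series import AcquisitionGeometry, DynamicSeries


@pytest.fixture(scope="session")
def geometry_small():
    return AcquisitionGeometry.small()


@pytest.fixture(scope="session")
def label_map_small(geometry_small):
    return phantom.make_label_map(geometry_small)


@pytest.fixture(scope="session")
def template_small(label_map_small, geometry_small):
    """Full default sampling plan placed on the small test geometry."""
    return roi.build_template(label_map_small, geometry_small, seed=11)


@pytest.fixture(scope="session")
def phantom_subject(geometry_small):
    """One deterministic synthetic subject: (series, label_map, truth, kinetics)."""
    cov = phantom.generate_covariates(1, seed=5)
    kinetics = phantom.KineticsModel()
    truth = phantom.truth_from_covariates(cov.iloc[0], kinetics)
    series, labels = phantom.generate_series(truth, geometry_small, kinetics, seed=6)
    return series, labels, truth, kinetics


def patch_stack(patch, frame_times_s=None, origin=(0, 1, 1)):
    """Build a RegionStack whose single disc covers a 2D (or T x H x W) patch.

    The patch is treated as one sample; coordinates start at ``origin`` so
    embedding the patch in a padded volume leaves a border for LBP tests.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 2:
        patch = patch[None]
    T, H, W = patch.shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    coords = np.column_stack([
        np.full(H * W, origin[0]),
        rr.ravel() + origin[1],
        cc.ravel() + origin[2],
    ])
    values = patch.reshape(T, -1)
    if frame_times_s is None:
        frame_times_s = np.arange(T) * 73.0
    return roi.RegionStack(unit=roi.RegionUnit("WM", "high"), values=values,
                           coords=coords, sample_ids=np.zeros(H * W, dtype=int),
                           frame_times_s=np.asarray(frame_times_s, dtype=float))


def patch_series(patch, geometry=None):
    """Embed a T x H x W patch at (slice 0, offset 1,1) in a padded series."""
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 2:
        patch = patch[None]
    T, H, W = patch.shape
    geometry = geometry or AcquisitionGeometry(
        n_rows=H + 2, n_cols=W + 2, n_slices=1, n_frames=T)
    data = np.zeros((T, 1, H + 2, W + 2))
    data[:, 0, 1:H + 1, 1:W + 1] = patch
    return DynamicSeries(data=data, geometry=geometry)
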