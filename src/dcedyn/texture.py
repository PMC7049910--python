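"""Texture descriptors: GLCM/Haralick, uniform LBP, local configuration patterns.

All three operate in-plane (2D, per slice) on the voxels of a region unit's
discs.  Grey-level co-occurrence uses 8-connected neighbour pairs restricted
to voxels of the same disc, accumulated symmetrically; local binary patterns
compare each in-disc voxel with its 8 in-image neighbours (which may lie
just outside the disc).

Conventions:

* Quantisation bounds span the unit's *full time series* (per-frame bounds
  would erase enhancement dynamics).
* LBP bit p is 1 iff neighbour p is strictly below the center, with
  neighbour order (E, NE, N, NW, W, SW, S, SE) and bit p contributing 2^p.
* Haralick entropies use the natural log with 0 log 0 := 0; the inverse
  difference moment uses the standard 1 + (a-b)^2 denominator by default
  (``idm_printed_form=True`` reproduces the 1 + (a+b)^2 variant instead).
* The LCP vector concatenates the occurrence frequencies of the 9 uniform
  rotation-invariant patterns with, per pattern, the 8 Fourier-transform
  magnitudes of the least-squares weights regressing each center on its 8
  neighbours: 9 + 9*8 = 81 features.
"""

from __future__ import annotations

import numpy as np

from .roi import RegionStack, RegionUnit, SamplingTemplate, extract_region_stack
from .series import DynamicSeries
from .trajectory import DescriptorTrajectory

__all__ = [
    "quantize", "glcm", "haralick", "HARALICK_NAMES", "lbp_codes",
    "ulbp_histogram", "lcp_features", "uniform_codes", "n_transitions",
    "glcm_trajectory", "ulbp_trajectory", "lcp_trajectory",
    "DegenerateMatrixError",
]

HARALICK_NAMES = ["contrast", "correlation", "energy", "variance", "entropy",
                  "idm", "sum_average", "sum_entropy", "sum_variance"]

# Neighbour offsets (drow, dcol) in order E, NE, N, NW, W, SW, S, SE with
# rows increasing downward; bit p of the LBP code corresponds to offset p.
NEIGHBOR_OFFSETS = np.array(
    [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)])

EIGHT_CONNECTED = NEIGHBOR_OFFSETS  # same structure for GLCM pairing


class DegenerateMatrixError(ValueError):
    """Region has too few adjacent voxel pairs to form a co-occurrence matrix."""


# ---------------------------------------------------------------------------
# quantisation

def quantize(values: np.ndarray, levels: int = 16
             ) -> tuple[np.ndarray, tuple[float, float]]:
    """Linear equal-width quantisation into ``levels`` grey levels.

    ``values`` is the full T x V stack (or any array); bounds are the global
    min/max so every frame shares the same grey scale.  The maximum maps to
    ``levels - 1``; a constant input maps everywhere to level 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot quantize an empty array")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros(values.shape, dtype=np.int64), (lo, hi)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1), (lo, hi)


# ---------------------------------------------------------------------------
# GLCM / Haralick

def _stack_neighbor_pairs(stack: RegionStack) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) of 8-connected same-slice voxels in the same disc."""
    index = {(int(s), int(r), int(c)): i
             for i, (s, r, c) in enumerate(stack.coords)}
    pairs_i, pairs_j = [], []
    for i, (z, r, c) in enumerate(stack.coords):
        for dr, dc in EIGHT_CONNECTED:
            j = index.get((int(z), int(r + dr), int(c + dc)))
            if j is not None and stack.sample_ids[j] == stack.sample_ids[i]:
                pairs_i.append(i)
                pairs_j.append(j)
    return np.array(pairs_i, dtype=int), np.array(pairs_j, dtype=int)


def glcm(levels_frame: np.ndarray, pairs: tuple[np.ndarray, np.ndarray],
         n_levels: int = 16, normalise: bool = True) -> np.ndarray:
    """Co-occurrence matrix over the given neighbour pairs.

    Each ordered pair contributes one count, so the symmetric partner of
    every pair is counted too and the matrix is symmetric by construction.
    """
    pi, pj = pairs
    if len(pi) == 0:
        raise DegenerateMatrixError("region has no adjacent voxel pairs")
    a = levels_frame[pi]
    b = levels_frame[pj]
    mat = np.zeros((n_levels, n_levels))
    np.add.at(mat, (a, b), 1.0)
    if normalise:
        mat /= mat.sum()
    return mat


def haralick(matrix: np.ndarray, idm_printed_form: bool = False) -> np.ndarray:
    """The nine co-occurrence features, in :data:`HARALICK_NAMES` order.

    Requires a normalised matrix.  Correlation is defined as 1 when either
    marginal is degenerate (zero standard deviation).
    """
    C = np.asarray(matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if not np.isclose(C.sum(), 1.0, atol=1e-8):
        raise ValueError("haralick() requires a normalised matrix (sum == 1)")
    L = C.shape[0]
    a = np.arange(L)
    pa = C.sum(axis=1)
    pb = C.sum(axis=0)
    mu_a = float(a @ pa)
    mu_b = float(a @ pb)
    sig_a = float(np.sqrt(((a - mu_a) ** 2) @ pa))
    sig_b = float(np.sqrt(((a - mu_b) ** 2) @ pb))
    A = a[:, None]
    B = a[None, :]

    contrast = float(np.sum((A - B) ** 2 * C))
    if sig_a * sig_b == 0:
        correlation = 1.0
    else:
        correlation = float(np.sum((A - mu_a) * (B - mu_b) * C) / (sig_a * sig_b))
    energy = float(np.sum(C ** 2))
    variance = float(((a - mu_a) ** 2) @ pa)
    entropy = float(-np.sum(C * _safe_log(C)))
    if idm_printed_form:
        idm = float(np.sum(C / (1.0 + (A + B) ** 2)))
    else:
        idm = float(np.sum(C / (1.0 + (A - B) ** 2)))

    # grey-level sum distribution C_{a+b}(k), k = 0 .. 2L-2
    k = np.arange(2 * L - 1)
    csum = np.zeros(2 * L - 1)
    np.add.at(csum, (A + B).ravel(), C.ravel())
    sum_average = float(k @ csum)
    sum_entropy = float(-np.sum(csum * _safe_log(csum)))
    sum_variance = float(((k - sum_average) ** 2) @ csum)

    return np.array([contrast, correlation, energy, variance, entropy, idm,
                     sum_average, sum_entropy, sum_variance])


def _safe_log(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = np.log(p[nz])
    return out


# ---------------------------------------------------------------------------
# LBP / ULBP

def lbp_codes(frame_volume: np.ndarray, coords: np.ndarray, radius: int = 1
              ) -> tuple[np.ndarray, int]:
    """8-bit LBP code per voxel; returns (codes, n_excluded_border_voxels).

    Bit p is set iff the neighbour at ``radius * NEIGHBOR_OFFSETS[p]`` is
    strictly below the center.  Voxels whose neighbourhood leaves the image
    are excluded and counted.
    """
    coords = np.asarray(coords, dtype=int)
    _, R, Cc = frame_volume.shape
    r = coords[:, 1]
    c = coords[:, 2]
    valid = ((r >= radius) & (r < R - radius) & (c >= radius) & (c < Cc - radius))
    n_excluded = int((~valid).sum())
    z, r, c = coords[valid, 0], coords[valid, 1], coords[valid, 2]
    center = frame_volume[z, r, c]
    codes = np.zeros(len(z), dtype=np.int64)
    for p, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neighbour = frame_volume[z, r + radius * dr, c + radius * dc]
        codes |= (neighbour < center).astype(np.int64) << p
    return codes, n_excluded


def n_transitions(code: int) -> int:
    """Number of circular 0<->1 transitions in the 8-bit code."""
    bits = [(code >> p) & 1 for p in range(8)]
    return sum(bits[p] != bits[(p + 1) % 8] for p in range(8))


def uniform_codes() -> np.ndarray:
    """The 58 uniform 8-bit codes (at most 2 circular transitions), ascending."""
    return np.array([c for c in range(256) if n_transitions(c) <= 2])


_UNIFORM = None


def _uniform_lookup() -> np.ndarray:
    """Map code -> bin: uniform codes get bins 0..57, the rest bin 58."""
    global _UNIFORM
    if _UNIFORM is None:
        lut = np.full(256, 58, dtype=np.int64)
        for i, c in enumerate(uniform_codes()):
            lut[c] = i
        _UNIFORM = lut
    return _UNIFORM


def ulbp_histogram(codes: np.ndarray) -> np.ndarray:
    """59-bin normalised histogram: 58 uniform codes + 1 pooled bin."""
    codes = np.asarray(codes, dtype=np.int64)
    if codes.size == 0:
        raise ValueError("cannot build a histogram from zero codes")
    bins = _uniform_lookup()[codes]
    hist = np.bincount(bins, minlength=59).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# LCP

def _riu2_class(codes: np.ndarray) -> np.ndarray:
    """Rotation-invariant uniform class: popcount for uniform codes, 9 else."""
    pop = np.array([bin(c).count("1") for c in range(256)])
    uni = np.array([n_transitions(c) <= 2 for c in range(256)])
    lut = np.where(uni, pop, 9)
    return lut[codes]


def _config_weights(neighbours: np.ndarray, centers: np.ndarray,
                    ridge: float = 1e-10) -> np.ndarray:
    """Least-squares weights a minimising ||centers - neighbours @ a||^2.

    Solved through the normal equations with a small ridge term scaled by
    the trace, so rank-deficient pattern groups (e.g. constant patches)
    still yield finite weights.
    """
    G = neighbours.T @ neighbours
    eps = ridge * max(np.trace(G) / G.shape[0], 1.0)
    return np.linalg.solve(G + eps * np.eye(G.shape[0]), neighbours.T @ centers)


def lcp_features(frame_volume: np.ndarray, coords: np.ndarray, radius: int = 1,
                 ridge: float = 1e-10) -> np.ndarray:
    """81-feature local configuration pattern vector.

    Features 0..8 are the occurrence frequencies of the nine uniform
    rotation-invariant LBP patterns (0..8 set bits) among the region's
    voxels; features 9..80 hold, per pattern, the 8 magnitudes of the
    discrete Fourier transform of the least-squares weights that best
    reconstruct each center from its 8 neighbours (zeros for patterns that
    do not occur).  The Fourier magnitudes remove the dependence on the
    neighbour ordering's rotation, making the configuration block rotation
    invariant.
    """
    coords = np.asarray(coords, dtype=int)
    _, R, Cc = frame_volume.shape
    r = coords[:, 1]
    c = coords[:, 2]
    valid = ((r >= radius) & (r < R - radius) & (c >= radius) & (c < Cc - radius))
    z, r, c = coords[valid, 0], coords[valid, 1], coords[valid, 2]
    if len(z) == 0:
        raise ValueError("no voxel has a complete neighbourhood")
    centers = frame_volume[z, r, c].astype(float)
    neigh = np.stack([frame_volume[z, r + radius * dr, c + radius * dc]
                      for dr, dc in NEIGHBOR_OFFSETS], axis=1).astype(float)
    codes = np.zeros(len(z), dtype=np.int64)
    for p in range(8):
        codes |= (neigh[:, p] < centers).astype(np.int64) << p
    classes = _riu2_class(codes)

    occurrence = np.zeros(9)
    config = np.zeros((9, 8))
    total = len(classes)
    for k in range(9):
        members = classes == k
        occurrence[k] = members.sum() / total
        if members.any():
            w = _config_weights(neigh[members], centers[members], ridge=ridge)
            config[k] = np.abs(np.fft.fft(w))
    return np.concatenate([occurrence, config.ravel()])


# ---------------------------------------------------------------------------
# trajectories

def glcm_trajectory(stack: RegionStack, grey_levels: int = 16,
                    idm_printed_form: bool = False) -> DescriptorTrajectory:
    """9 x T Haralick trajectory for one region unit."""
    levels, _ = quantize(stack.values, grey_levels)
    pairs = _stack_neighbor_pairs(stack)
    T = stack.values.shape[0]
    out = np.empty((9, T))
    for t in range(T):
        out[:, t] = haralick(glcm(levels[t], pairs, grey_levels),
                             idm_printed_form=idm_printed_form)
    return DescriptorTrajectory(descriptor="GLCM", unit=stack.unit, values=out,
                                frame_times_s=stack.frame_times_s,
                                feature_names=[f"glcm_{n}" for n in HARALICK_NAMES])


def ulbp_trajectory(series: DynamicSeries, stack: RegionStack,
                    radius: int = 1) -> DescriptorTrajectory:
    """59 x T uniform-LBP histogram trajectory."""
    T = stack.values.shape[0]
    out = np.empty((59, T))
    for t in range(T):
        codes, _ = lbp_codes(series.data[t], stack.coords, radius=radius)
        out[:, t] = ulbp_histogram(codes)
    return DescriptorTrajectory(descriptor="ULBP", unit=stack.unit, values=out,
                                frame_times_s=stack.frame_times_s,
                                feature_names=[f"ulbp_{i:02d}" for i in range(59)])


def lcp_trajectory(series: DynamicSeries, stack: RegionStack,
                   radius: int = 1) -> DescriptorTrajectory:
    """81 x T local-configuration-pattern trajectory."""
    T = stack.values.shape[0]
    out = np.empty((81, T))
    for t in range(T):
        out[:, t] = lcp_features(series.data[t], stack.coords, radius=radius)
    return DescriptorTrajectory(descriptor="LCP", unit=stack.unit, values=out,
                                frame_times_s=stack.frame_times_s,
                                feature_names=[f"lcp_{i:03d}" for i in range(81)])
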