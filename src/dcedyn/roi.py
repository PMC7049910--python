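"""Anatomical circular-sample template and region-stack extraction.

Brain regions are sampled with small non-overlapping circular discs of
~12 mm^2 in-plane, organised by slice tier (low, low-middle, middle-high,
high) and tissue (blood vessels BL, CSF, deep grey GMD, cortical grey GMC,
white matter WM).  A disc contains every voxel whose center lies within the
radius of the disc center, measured in millimetres with the in-plane
spacing.  Placement is automatic (seeded rejection sampling on a label
map), replacing manual expert placement; an exclusion mask can veto
regions such as lesions or partial-volume areas.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

from .phantom import TISSUE_CODES, TISSUES
from .series import AcquisitionGeometry, DynamicSeries

__all__ = [
    "TIERS", "DEFAULT_RADIUS_MM", "DEFAULT_PLAN", "CircularSample", "RegionUnit",
    "SamplingTemplate", "RegionStack", "PlacementError", "build_template",
    "extract_region_stack", "disc_voxels", "default_tier_slices",
]

TIERS = ("low", "low-middle", "middle-high", "high")

# pi r^2 = 12 mm^2  ->  r = 1.954 mm
DEFAULT_RADIUS_MM = math.sqrt(12.0 / math.pi)

# Per-tier, per-tissue sample counts of the study's sampling plan.  The low
# slice holds blood-vessel samples only (carotids x1, basilar x1, superior
# sagittal sinus x1); each higher tier adds one sinus sample plus the
# stated tissue counts.
DEFAULT_PLAN: dict[str, dict[str, int]] = {
    "low": {"BL": 3},
    "low-middle": {"BL": 1, "CSF": 12, "GMD": 12, "GMC": 12, "WM": 10},
    "middle-high": {"BL": 1, "CSF": 8, "GMC": 6, "WM": 28},
    "high": {"BL": 1, "GMC": 6, "WM": 28},
}


class PlacementError(RuntimeError):
    """Raised when a tier/tissue quota cannot be placed."""


@dataclass(frozen=True)
class CircularSample:
    tier: str
    slice_index: int
    center_row: int
    center_col: int
    radius_mm: float
    tissue: str

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")


@dataclass(frozen=True, order=True)
class RegionUnit:
    """A (tissue, slice tier) combination — the granularity of analysis."""
    tissue: str
    tier: str

    def __str__(self) -> str:
        return f"{self.tissue}@{self.tier}"

    @classmethod
    def parse(cls, text: str) -> "RegionUnit":
        tissue, tier = text.split("@")
        return cls(tissue=tissue, tier=tier)


def _disc_footprint(radius_mm: float, spacing: float) -> np.ndarray:
    """Boolean in-plane footprint of a disc centered on a voxel."""
    r_vox = int(math.floor(radius_mm / spacing))
    offs = np.arange(-r_vox, r_vox + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    return (dr * spacing) ** 2 + (dc * spacing) ** 2 <= radius_mm ** 2


def disc_voxels(sample: CircularSample, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of voxels whose centers fall inside the disc."""
    fp = _disc_footprint(sample.radius_mm, spacing)
    r_vox = fp.shape[0] // 2
    dr, dc = np.nonzero(fp)
    return sample.center_row + dr - r_vox, sample.center_col + dc - r_vox


@dataclass
class SamplingTemplate:
    samples: tuple[CircularSample, ...]
    geometry: AcquisitionGeometry

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for s in self.samples:
            out.setdefault(s.tier, {}).setdefault(s.tissue, 0)
            out[s.tier][s.tissue] += 1
        return out

    def region_units(self) -> list[RegionUnit]:
        """Distinct (tissue, tier) pairs, ordered by tier then tissue."""
        seen = {(s.tier, s.tissue) for s in self.samples}
        return [RegionUnit(tissue=t, tier=tier)
                for tier in TIERS for t in TISSUES if (tier, t) in seen]

    def samples_for(self, unit: RegionUnit) -> list[CircularSample]:
        found = [s for s in self.samples
                 if s.tier == unit.tier and s.tissue == unit.tissue]
        if not found:
            raise KeyError(f"unit {unit} not present in template")
        return found

    def to_mask(self) -> np.ndarray:
        """Render discs as an integer mask (tissue codes) for inspection."""
        mask = np.zeros(self.geometry.shape, dtype=np.int16)
        for s in self.samples:
            rr, cc = disc_voxels(s, self.geometry.in_plane_spacing)
            mask[s.slice_index, rr, cc] = TISSUE_CODES[s.tissue]
        return mask

    def to_json(self, path=None) -> str:
        payload = {
            "geometry": {
                "n_rows": self.geometry.n_rows, "n_cols": self.geometry.n_cols,
                "n_slices": self.geometry.n_slices,
                "in_plane_spacing": self.geometry.in_plane_spacing,
                "slice_thickness": self.geometry.slice_thickness,
                "n_frames": self.geometry.n_frames,
                "frame_interval": self.geometry.frame_interval,
            },
            "samples": [
                {"tier": s.tier, "slice_index": s.slice_index,
                 "center_row": s.center_row, "center_col": s.center_col,
                 "radius_mm": s.radius_mm, "tissue": s.tissue}
                for s in self.samples
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SamplingTemplate":
        from pathlib import Path
        if isinstance(source, (str, Path)) and str(source).lstrip().startswith("{"):
            payload = json.loads(str(source))
        else:
            payload = json.loads(Path(source).read_text())
        geom = AcquisitionGeometry(**payload["geometry"])
        samples = tuple(CircularSample(**s) for s in payload["samples"])
        return cls(samples=samples, geometry=geom)


@dataclass
class RegionStack:
    """Ordered voxel intensities of one region unit across all frames."""

    unit: RegionUnit
    values: np.ndarray        # T x V
    coords: np.ndarray        # V x 3 (slice, row, col)
    sample_ids: np.ndarray    # V, index of the disc each voxel belongs to
    frame_times_s: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def default_tier_slices(geometry: AcquisitionGeometry) -> dict[str, int]:
    """Spread the four tier slices across the volume, inferior to superior."""
    z = geometry.n_slices - 1
    idx = np.round(np.linspace(0.15, 0.85, 4) * z).astype(int)
    return dict(zip(TIERS, idx.tolist()))


def build_template(label_map: np.ndarray, geometry: AcquisitionGeometry,
                   plan: dict[str, dict[str, int]] | None = None,
                   tier_slices: dict[str, int] | None = None,
                   exclusion_mask: np.ndarray | None = None,
                   seed: int = 0, radius_mm: float = DEFAULT_RADIUS_MM,
                   max_restarts: int = 30) -> SamplingTemplate:
    """Place the plan's discs on the label map by seeded rejection sampling.

    Candidate centers are voxels whose whole disc lies inside the requested
    tissue (and outside the exclusion mask); a greedy pass over a seeded
    permutation accepts centers at least one diameter apart from every
    already-accepted center on the same slice.  The pass restarts with a
    fresh permutation up to ``max_restarts`` times before raising
    :class:`PlacementError` naming the tier and tissue.
    """
    plan = DEFAULT_PLAN if plan is None else plan
    tiers = tier_slices or default_tier_slices(geometry)
    if label_map.shape != geometry.shape:
        raise ValueError("label map shape does not match geometry")
    rng = np.random.default_rng(seed)
    fp = _disc_footprint(radius_mm, geometry.in_plane_spacing)
    min_d2 = (2.0 * radius_mm / geometry.in_plane_spacing) ** 2  # voxel units

    samples: list[CircularSample] = []
    for tier in TIERS:
        quota = {t: int(c) for t, c in plan.get(tier, {}).items() if c > 0}
        if any(c < 0 for c in plan.get(tier, {}).values()):
            raise ValueError("plan counts must be >= 0")
        if not quota:
            continue
        z = int(tiers[tier])
        sl = label_map[z]
        excl = exclusion_mask[z] if exclusion_mask is not None else None

        candidates: dict[str, np.ndarray] = {}
        for tissue in quota:
            allowed = sl == TISSUE_CODES[tissue]
            if excl is not None:
                allowed &= ~excl.astype(bool)
            ok = binary_erosion(allowed, structure=fp, border_value=0)
            cand = np.argwhere(ok)
            if len(cand) == 0:
                raise PlacementError(
                    f"no feasible center for tissue {tissue} in tier {tier}")
            candidates[tissue] = cand

        for attempt in range(max_restarts):
            placed: list[tuple[int, int, str]] = []
            failed = None
            for tissue in sorted(quota):
                order = rng.permutation(len(candidates[tissue]))
                need = quota[tissue]
                got = 0
                for k in order:
                    r, c = candidates[tissue][k]
                    if all((r - pr) ** 2 + (c - pc) ** 2 >= min_d2
                           for pr, pc, _ in placed):
                        placed.append((int(r), int(c), tissue))
                        got += 1
                        if got == need:
                            break
                if got < need:
                    failed = tissue
                    break
            if failed is None:
                samples.extend(
                    CircularSample(tier=tier, slice_index=z, center_row=r,
                                   center_col=c, radius_mm=radius_mm, tissue=t)
                    for r, c, t in placed)
                break
        else:
            raise PlacementError(
                f"could not place {quota[failed]} {failed} samples in tier {tier} "
                f"after {max_restarts} restarts")
    return SamplingTemplate(samples=tuple(samples), geometry=geometry)


def extract_region_stack(series: DynamicSeries, template: SamplingTemplate,
                         unit: RegionUnit) -> RegionStack:
    """Collect the unit's disc voxels into a T x V intensity stack.

    Voxel order is stable: samples in template order, voxels row-major
    within each disc.
    """
    if series.geometry.shape != template.geometry.shape:
        raise ValueError("template geometry does not match series")
    spacing = series.geometry.in_plane_spacing
    coords = []
    sample_ids = []
    for i, s in enumerate(template.samples_for(unit)):
        rr, cc = disc_voxels(s, spacing)
        for r, c in zip(rr, cc):
            coords.append((s.slice_index, int(r), int(c)))
            sample_ids.append(i)
    coords_arr = np.array(coords, dtype=int)
    values = series.data[:, coords_arr[:, 0], coords_arr[:, 1], coords_arr[:, 2]]
    return RegionStack(unit=unit, values=values, coords=coords_arr,
                       sample_ids=np.array(sample_ids),
                       frame_times_s=series.geometry.frame_times_s)
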