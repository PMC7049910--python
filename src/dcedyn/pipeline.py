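"""End-to-end orchestration: phantom/series in, score and result tables out.

Stage order follows the processing scheme: sample regions with the
template, describe each region unit at each frame (enhancement, radial
power spectrum, GLCM/Haralick, uniform LBP, local configuration
patterns), reduce each descriptor trajectory to a first-mode MFPCA score
per subject, append the scalar comparators (AUEC, post-peak slope), and
run the statistical validation.  All randomness flows from a single master
seed through named substreams; every output CSV carries the seed and a
config hash in comment headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enhancement, mfpca, phantom, roi, spectral, stats, texture
from .series import AcquisitionGeometry, DynamicSeries
from .trajectory import DescriptorTrajectory

__all__ = ["PipelineConfig", "PipelineResult", "run", "compute_subject_descriptors",
           "reduce_scores", "write_csv", "read_csv"]

log = logging.getLogger("dcedyn")

ALL_DESCRIPTORS = ("Enh", "RPS", "GLCM", "ULBP", "LCP")


@dataclass
class PipelineConfig:
    n_subjects: int = 5
    geometry: str = "small"            # "small" | "paper"
    n_frames: int | None = None
    seed: int = 0
    out_dir: str = "dcedyn_out"
    cube_side: int = 64
    grey_levels: int = 16
    lbp_radius: int = 1
    fpca_modes: int = 5
    descriptors: tuple = ALL_DESCRIPTORS
    enhancement_units: str = "ratio"
    kinetics: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def resolve_geometry(self) -> AcquisitionGeometry:
        if self.geometry == "small":
            geom = AcquisitionGeometry.small()
        elif self.geometry == "paper":
            geom = AcquisitionGeometry.paper()
        else:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_frames is not None:
            geom = dataclasses.replace(geom, n_frames=int(self.n_frames))
        return geom

    def resolve_kinetics(self) -> phantom.KineticsModel:
        return phantom.KineticsModel(**self.kinetics)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "descriptors" in payload:
            payload["descriptors"] = tuple(payload["descriptors"])
        return cls(**payload)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    covariates: pd.DataFrame
    scores: pd.DataFrame
    kw_results: pd.DataFrame
    regression_results: pd.DataFrame
    template: roi.SamplingTemplate
    out_dir: Path | None


def _substream_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)  # < 2**31


def write_csv(df: pd.DataFrame, path, seed: int, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n# config={config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def compute_subject_descriptors(series: DynamicSeries,
                                template: roi.SamplingTemplate,
                                cfg: PipelineConfig
                                ) -> tuple[dict, list[dict]]:
    """All descriptor trajectories and scalar comparators for one subject.

    Returns ``(trajectories, scalar_rows)`` where ``trajectories`` maps
    (unit string, descriptor) to a :class:`DescriptorTrajectory` and
    ``scalar_rows`` holds AUEC/Slope dictionaries.  A failure in one
    (unit, descriptor) cell is logged and skipped, not fatal.
    """
    trajectories: dict[tuple[str, str], DescriptorTrajectory] = {}
    scalars: list[dict] = []
    for unit in template.region_units():
        stack = roi.extract_region_stack(series, template, unit)
        ops = {
            "Enh": lambda: enhancement.enh_trajectory(
                stack, units=cfg.enhancement_units),
            "RPS": lambda: spectral.rps_trajectory(
                series, template, unit, cube_side=cfg.cube_side),
            "GLCM": lambda: texture.glcm_trajectory(
                stack, grey_levels=cfg.grey_levels),
            "ULBP": lambda: texture.ulbp_trajectory(
                series, stack, radius=cfg.lbp_radius),
            "LCP": lambda: texture.lcp_trajectory(
                series, stack, radius=cfg.lbp_radius),
        }
        for name in cfg.descriptors:
            try:
                trajectories[(str(unit), name)] = ops[name]()
            except Exception as exc:  # noqa: BLE001 — cell-level resilience
                log.warning("descriptor %s failed for unit %s: %s", name, unit, exc)

        try:
            curve = enhancement.enhancement_curve(stack, units=cfg.enhancement_units)
            scalars.append({"unit": str(unit), "descriptor": "AUEC",
                            "score": enhancement.auec(curve)})
            try:
                slope = enhancement.enhancement_slope(curve)
            except enhancement.InsufficientDataError as exc:
                log.warning("slope failed for unit %s: %s", unit, exc)
                slope = np.nan
            scalars.append({"unit": str(unit), "descriptor": "Slope",
                            "score": slope})
        except enhancement.DegenerateBaselineError as exc:
            log.warning("enhancement failed for unit %s: %s", unit, exc)
    return trajectories, scalars


def reduce_scores(traj_store: dict, frame_times_s: np.ndarray,
                  subject_ids: list[str], M: int = 5) -> pd.DataFrame:
    """MFPCA first-mode score per (unit, descriptor) cell.

    ``traj_store`` maps (unit string, descriptor) to a P x D x T array in
    ``subject_ids`` order.
    """
    rows = []
    times_min = np.asarray(frame_times_s, dtype=float) / 60.0
    for (unit, desc) in sorted(traj_store):
        arr = np.asarray(traj_store[(unit, desc)], dtype=float)
        try:
            scores, explained = mfpca.mfpca_first_mode(arr, times_min, M=M)
        except ValueError as exc:
            log.warning("MFPCA failed for (%s, %s): %s", unit, desc, exc)
            continue
        for sid, sc in zip(subject_ids, scores):
            rows.append({"subject_id": sid, "unit": unit, "descriptor": desc,
                         "score": float(sc), "explained_var": explained})
    return pd.DataFrame(rows)


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full phantom-to-statistics pipeline."""
    logging.basicConfig(level=config.log_level)
    geometry = config.resolve_geometry()
    kinetics = config.resolve_kinetics()
    master = np.random.SeedSequence(config.seed)
    cov_ss, tpl_ss, series_parent = master.spawn(3)

    covariates = phantom.generate_covariates(config.n_subjects,
                                             seed=_substream_seed(cov_ss))
    label_map = phantom.make_label_map(geometry)
    template = roi.build_template(label_map, geometry,
                                  seed=_substream_seed(tpl_ss))

    traj_store: dict[tuple[str, str], list] = {}
    scalar_rows: list[dict] = []
    subject_ids = list(covariates["subject_id"])
    for (_, row), sub_ss in zip(covariates.iterrows(),
                                series_parent.spawn(config.n_subjects)):
        truth = phantom.truth_from_covariates(row, kinetics)
        series, _ = phantom.generate_series(truth, geometry, kinetics,
                                            seed=_substream_seed(sub_ss))
        trajectories, scalars = compute_subject_descriptors(series, template, config)
        for key, traj in trajectories.items():
            traj_store.setdefault(key, []).append(traj.values)
        for s in scalars:
            scalar_rows.append({"subject_id": row["subject_id"], **s,
                                "explained_var": np.nan})

    scores = reduce_scores(traj_store, geometry.frame_times_s, subject_ids,
                           M=config.fpca_modes)
    scores = pd.concat([scores, pd.DataFrame(scalar_rows)], ignore_index=True)
    scores = scores.sort_values(["unit", "descriptor", "subject_id"],
                                ignore_index=True)

    valid = scores.dropna(subset=["score"])
    kw_df, reg_df = stats.run_validation(valid, covariates)

    out_dir = None
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        h = config.config_hash()
        write_csv(covariates, out_dir / "covariates.csv", config.seed, h)
        write_csv(scores, out_dir / "scores.csv", config.seed, h)
        write_csv(kw_df, out_dir / "kw_results.csv", config.seed, h)
        write_csv(reg_df, out_dir / "regression_results.csv", config.seed, h)
        template.to_json(out_dir / "template.json")
        (out_dir / "config.json").write_text(
            json.dumps({"seed": config.seed, "hash": h,
                        **dataclasses.asdict(config)}, indent=2, default=str))
    return PipelineResult(covariates=covariates, scores=scores, kw_results=kw_df,
                          regression_results=reg_df, template=template,
                          out_dir=out_dir)
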