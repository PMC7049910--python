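"""Synthetic DCE-MRI cohorts for end-to-end testing of the pipeline.

The phantom emulates the study conditions rather than MR physics: a
per-tissue baseline T1w signal, multiplicative enhancement driven by a
gamma-variate vascular input function plus a leakage term proportional to
its running integral, stationary correlated Gaussian texture whose variance
scales with a per-tissue heterogeneity parameter, and additive Gaussian
noise.  Covariates are drawn from the cohort's published marginal
distributions, with white-matter-hyperintensity (WMH) burden coupled to the
total small-vessel-disease score through a Gaussian copula and, by
configurable linear links, to leakage rate and texture heterogeneity.
There is no k-space, coil, relaxometry or motion simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

from .series import AcquisitionGeometry, DynamicSeries, save_label_map

__all__ = [
    "TISSUES", "TISSUE_CODES", "CovariateConfig", "KineticsModel", "SubjectTruth",
    "generate_covariates", "truth_from_covariates", "make_label_map",
    "generate_series", "vif", "write_subject",
]

TISSUES = ("BL", "CSF", "GMD", "GMC", "WM")
TISSUE_CODES = {"BL": 1, "CSF": 2, "GMD": 3, "GMC": 4, "WM": 5}

# Fraction of image columns assigned to each tissue stripe in the label map.
# WM gets the widest stripe because the sampling plan places most discs there.
_STRIPE_FRACTIONS = {"BL": 0.10, "CSF": 0.20, "GMD": 0.15, "GMC": 0.20, "WM": 0.35}

# Approximate T1w baseline signal per tissue (arbitrary units): CSF dark,
# white matter bright, grey matter intermediate, blood in between.
_BASELINES = {"BL": 260.0, "CSF": 150.0, "GMD": 300.0, "GMC": 320.0, "WM": 400.0}


@dataclass(frozen=True)
class CovariateConfig:
    """Marginal distributions of the clinical covariates.

    Defaults reproduce the cohort's published distribution: n=42 recent mild
    stroke patients, 30 male (71%), 33 hypertensive (79%), 19 lacunar index
    strokes, WMH burden 0.07-8.73% of intracranial volume, total SVD score
    0-4.  ``wmh_svd_corr`` is the latent (copula) correlation tying SVD
    score to WMH burden.
    """

    age_bins: tuple = ((39, 49), (49, 59), (59, 69), (69, 79), (79, 89))
    age_probs: tuple = (2 / 42, 11 / 42, 15 / 42, 11 / 42, 3 / 42)
    p_male: float = 30 / 42
    p_hypertensive: float = 33 / 42
    p_lacunar: float = 19 / 42
    wmh_bins: tuple = ((0.07, 1.80), (1.80, 3.53), (3.53, 5.26),
                       (5.26, 6.99), (6.99, 8.73))
    wmh_probs: tuple = (23 / 42, 6 / 42, 7 / 42, 2 / 42, 4 / 42)
    svd_probs: tuple = (8 / 42, 10 / 42, 12 / 42, 7 / 42, 5 / 42)
    wmh_svd_corr: float = 0.6


@dataclass(frozen=True)
class KineticsModel:
    """Gamma-variate bolus kinetics and per-tissue enhancement parameters.

    The vascular input function is
    ``VIF(t) = A ((t-t0)/tp)^a exp(a (1 - (t-t0)/tp))`` for t > t0, zero
    before onset, peaking at value A at t0 + tp.  Tissue enhancement is
    ``gain * VIF(t) + leakage_rate * int_0^t VIF dtau`` (time in minutes),
    applied multiplicatively to the baseline signal.  ``leakage_link`` maps
    WMH burden (% ICV) linearly to leakage rate (1/min per %);
    ``heterogeneity_link`` does the same for texture SD.
    """

    vif_amplitude: float = 1.0
    vif_onset_s: float = 73.0
    vif_shape: float = 3.0
    vif_time_to_peak_s: float = 120.0
    tissue_gain: dict = field(default_factory=lambda: {
        "BL": 0.60, "CSF": 0.02, "GMD": 0.15, "GMC": 0.15, "WM": 0.08})
    leakage_link: dict = field(default_factory=lambda: {
        "BL": 0.001, "CSF": 0.003, "GMD": 0.002, "GMC": 0.002, "WM": 0.004})
    heterogeneity_base: dict = field(default_factory=lambda: {
        "BL": 0.02, "CSF": 0.02, "GMD": 0.03, "GMC": 0.03, "WM": 0.03})
    heterogeneity_link: dict = field(default_factory=lambda: {
        "BL": 0.0, "CSF": 0.004, "GMD": 0.0, "GMC": 0.0, "WM": 0.004})
    correlation_length_vox: float = 1.5
    noise_sd: float = 0.02  # fraction of the tissue baseline

    def __post_init__(self) -> None:
        if self.vif_amplitude < 0:
            raise ValueError("vif_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SubjectTruth:
    """Ground-truth record for one simulated subject."""

    subject_id: str
    age: float
    sex: str                      # "male" | "female"
    hypertensive: bool
    wmh_fraction: float           # % of intracranial volume
    svd_score: int                # 0..4
    lacunar: bool
    leakage_rate: dict            # tissue -> 1/min
    texture_heterogeneity: dict   # tissue -> dimensionless SD fraction

    def __post_init__(self) -> None:
        if not 0.0 <= self.wmh_fraction <= 10.0:
            raise ValueError("wmh_fraction must lie in [0, 10]")
        if self.svd_score not in (0, 1, 2, 3, 4):
            raise ValueError("svd_score must be an integer 0..4")
        if any(v < 0 for v in self.leakage_rate.values()):
            raise ValueError("leakage_rate must be >= 0")


def generate_covariates(n_subjects: int, seed: int,
                        config: CovariateConfig | None = None) -> pd.DataFrame:
    """Draw a cohort covariate table.

    WMH fraction and SVD score are coupled through a Gaussian copula at the
    configured latent correlation; all other covariates are independent.
    Reproducible: the same seed yields an identical table.
    """
    if n_subjects < 0:
        raise ValueError(f"n_subjects must be >= 0, got {n_subjects}")
    cfg = config or CovariateConfig()
    rng = np.random.default_rng(seed)
    n = int(n_subjects)

    rho = cfg.wmh_svd_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n) if n else np.empty((0, 2))
    u_wmh = sstats.norm.cdf(z[:, 0]) if n else np.empty(0)
    u_svd = sstats.norm.cdf(z[:, 1]) if n else np.empty(0)

    wmh = _piecewise_uniform(u_wmh, cfg.wmh_bins, cfg.wmh_probs)
    svd = np.searchsorted(np.cumsum(cfg.svd_probs)[:-1], u_svd, side="right")

    u_age = rng.random(n)
    age = _piecewise_uniform(u_age, cfg.age_bins, cfg.age_probs)
    sex = np.where(rng.random(n) < cfg.p_male, "male", "female")
    hyp = rng.random(n) < cfg.p_hypertensive
    lac = rng.random(n) < cfg.p_lacunar

    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age": np.round(age, 1),
        "sex": sex,
        "hypertensive": hyp,
        "wmh_fraction": np.round(wmh, 4),
        "svd_score": svd.astype(int),
        "lacunar": lac,
    })


def _piecewise_uniform(u: np.ndarray, bins, probs) -> np.ndarray:
    """Map uniform variates through a histogram CDF (linear within bins)."""
    edges_lo = np.array([b[0] for b in bins])
    edges_hi = np.array([b[1] for b in bins])
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    cum[-1] = 1.0
    idx = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(bins) - 1)
    frac = (u - cum[idx]) / (cum[idx + 1] - cum[idx])
    return edges_lo[idx] + frac * (edges_hi[idx] - edges_lo[idx])


def truth_from_covariates(row, kinetics: KineticsModel | None = None) -> SubjectTruth:
    """Derive the per-tissue ground truth from one covariate row."""
    k = kinetics or KineticsModel()
    wmh = float(row["wmh_fraction"])
    leak = {t: k.leakage_link[t] * wmh for t in TISSUES}
    het = {t: k.heterogeneity_base[t] + k.heterogeneity_link[t] * wmh for t in TISSUES}
    return SubjectTruth(
        subject_id=str(row["subject_id"]), age=float(row["age"]), sex=str(row["sex"]),
        hypertensive=bool(row["hypertensive"]), wmh_fraction=wmh,
        svd_score=int(row["svd_score"]), lacunar=bool(row["lacunar"]),
        leakage_rate=leak, texture_heterogeneity=het)


def vif(t_s: np.ndarray, kinetics: KineticsModel) -> np.ndarray:
    """Gamma-variate vascular input function sampled at times in seconds."""
    t = np.asarray(t_s, dtype=float)
    x = (t - kinetics.vif_onset_s) / kinetics.vif_time_to_peak_s
    a = kinetics.vif_shape
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = kinetics.vif_amplitude * x[pos] ** a * np.exp(a * (1.0 - x[pos]))
    return out


def tissue_enhancement(tissue: str, truth: SubjectTruth, geometry: AcquisitionGeometry,
                       kinetics: KineticsModel) -> np.ndarray:
    """Programmed fractional enhancement e(t) for one tissue (length T)."""
    t_s = geometry.frame_times_s
    v = vif(t_s, kinetics)
    cum = cumulative_trapezoid(v, t_s / 60.0, initial=0.0)
    return kinetics.tissue_gain[tissue] * v + truth.leakage_rate[tissue] * cum


def make_label_map(geometry: AcquisitionGeometry) -> np.ndarray:
    """Deterministic tissue label map: vertical stripes, one per tissue.

    Every slice contains every tissue, so any slice can serve any sampling
    tier.  Stripe widths are proportional to how many discs the sampling
    plan needs in each tissue.
    """
    labels = np.zeros(geometry.shape, dtype=np.int16)
    edges = np.cumsum([0.0] + [_STRIPE_FRACTIONS[t] for t in TISSUES])
    cols = np.round(edges * geometry.n_cols).astype(int)
    cols[-1] = geometry.n_cols
    for i, t in enumerate(TISSUES):
        labels[:, :, cols[i]:cols[i + 1]] = TISSUE_CODES[t]
    return labels


def generate_series(truth: SubjectTruth, geometry: AcquisitionGeometry,
                    kinetics: KineticsModel, seed: int
                    ) -> tuple[DynamicSeries, np.ndarray]:
    """Simulate one subject's 4D series and its tissue label map.

    Frame 0 (t=0, before bolus onset) is the pre-contrast baseline.  The
    per-tissue spatial baseline is ``mean * (1 + heterogeneity * G)`` with G
    a unit-SD correlated Gaussian field; enhancement multiplies it; noise is
    additive with SD ``noise_sd * tissue baseline``.
    """
    label_map = make_label_map(geometry)
    rng = np.random.default_rng(seed)
    shape = geometry.shape
    T = geometry.n_frames

    base_map = np.zeros(shape)
    noise_scale = np.zeros(shape)
    tissue_idx = np.zeros(shape, dtype=np.int8)
    enh = np.zeros((T, len(TISSUES)))
    for i, tissue in enumerate(TISSUES):
        mask = label_map == TISSUE_CODES[tissue]
        g = rng.standard_normal(shape)
        g = gaussian_filter(g, sigma=kinetics.correlation_length_vox)
        sd = g.std()
        if sd > 0:
            g /= sd
        het = truth.texture_heterogeneity[tissue]
        base = _BASELINES[tissue] * (1.0 + het * g)
        base = np.clip(base, 0.05 * _BASELINES[tissue], None)
        base_map[mask] = base[mask]
        noise_scale[mask] = kinetics.noise_sd * _BASELINES[tissue]
        tissue_idx[mask] = i
        enh[:, i] = tissue_enhancement(tissue, truth, geometry, kinetics)

    # frame-by-frame assembly keeps the peak footprint near one 4D array
    data = np.empty((T,) + shape)
    for t in range(T):
        data[t] = base_map * (1.0 + enh[t][tissue_idx])
        if kinetics.noise_sd > 0:
            data[t] += rng.standard_normal(shape) * noise_scale
    return DynamicSeries(data=data, geometry=geometry), label_map


def write_subject(outdir, truth: SubjectTruth, series: DynamicSeries,
                  label_map: np.ndarray, seed: int,
                  kinetics: KineticsModel | None = None) -> None:
    """Write one subject as NIfTI-1 plus a JSON sidecar echoing the config."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    series.to_nifti(out / f"{truth.subject_id}_dce.nii")
    save_label_map(label_map, series.geometry, out / f"{truth.subject_id}_labels.nii")
    sidecar = {
        "subject_id": truth.subject_id,
        "seed": int(seed),
        "geometry": dataclasses.asdict(series.geometry),
        "kinetics": dataclasses.asdict(kinetics) if kinetics else None,
        "truth": {
            "wmh_fraction": truth.wmh_fraction,
            "svd_score": truth.svd_score,
            "leakage_rate": truth.leakage_rate,
            "texture_heterogeneity": truth.texture_heterogeneity,
        },
    }
    (out / f"{truth.subject_id}_sidecar.json").write_text(json.dumps(sidecar, indent=2))
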