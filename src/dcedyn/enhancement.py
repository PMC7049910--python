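"""Signal-enhancement curve and its two scalar surrogates (AUEC, slope).

Enhancement is the fractional signal increase of the region mean over the
pre-contrast frame: E(t) = (mean_t - mean_0) / mean_0 (ratio by default,
percent selectable).  AUEC is the trapezoidal area under E over the frame
times in minutes; the slope is the ordinary least-squares slope of E
against time over the frames strictly after the bolus peak, the peak being
the maximum of E within the first third of frames (bolus arrival is early
in a ~24 min protocol, and a late leakage maximum must not truncate the
fit window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .roi import RegionStack
from .trajectory import DescriptorTrajectory

__all__ = ["EnhancementCurve", "enhancement_curve", "auec", "enhancement_slope",
           "DegenerateBaselineError", "InsufficientDataError", "enh_trajectory"]


class DegenerateBaselineError(ValueError):
    """Pre-contrast region mean is zero or negative."""


class InsufficientDataError(ValueError):
    """Too few post-peak frames for a slope fit."""


@dataclass
class EnhancementCurve:
    values: np.ndarray       # E(t), dimensionless (or %, see units)
    times_min: np.ndarray
    units: str = "ratio"     # "ratio" | "percent"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.values.shape != self.times_min.shape:
            raise ValueError("values and times must have the same length")


def enhancement_curve(stack: RegionStack, units: str = "ratio") -> EnhancementCurve:
    """Region-mean enhancement relative to the pre-contrast frame."""
    means = stack.values.mean(axis=1)
    if means[0] <= 0:
        raise DegenerateBaselineError(
            f"baseline mean must be positive, got {means[0]}")
    e = (means - means[0]) / means[0]
    if units == "percent":
        e = e * 100.0
    elif units != "ratio":
        raise ValueError(f"unknown enhancement units {units!r}")
    return EnhancementCurve(values=e, times_min=stack.frame_times_s / 60.0,
                            units=units)


def auec(curve: EnhancementCurve) -> float:
    """Trapezoidal area under the enhancement curve (units of E * minutes)."""
    if len(curve.values) < 2:
        raise ValueError("AUEC requires at least 2 frames")
    return float(np.trapezoid(curve.values, curve.times_min))


def peak_frame(curve: EnhancementCurve) -> int:
    """Bolus peak: argmax of E restricted to the first third of frames."""
    T = len(curve.values)
    window = max(1, int(np.ceil(T / 3)))
    return int(np.argmax(curve.values[:window]))


def enhancement_slope(curve: EnhancementCurve) -> float:
    """OLS slope of E vs time (per minute) over frames strictly after the peak."""
    p = peak_frame(curve)
    post = np.arange(p + 1, len(curve.values))
    if len(post) < 3:
        raise InsufficientDataError(
            f"only {len(post)} frames after the peak (frame {p}); need >= 3")
    res = sstats.linregress(curve.times_min[post], curve.values[post])
    return float(res.slope)


def enh_trajectory(stack: RegionStack, units: str = "ratio") -> DescriptorTrajectory:
    """The 1 x T enhancement trajectory fed to the functional PCA."""
    curve = enhancement_curve(stack, units=units)
    return DescriptorTrajectory(descriptor="Enh", unit=stack.unit,
                                values=curve.values[None, :],
                                frame_times_s=stack.frame_times_s,
                                feature_names=["enh"])
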