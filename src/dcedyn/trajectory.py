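"""Descriptor trajectories: a feature vector per frame for one region unit."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roi import RegionUnit

__all__ = ["DescriptorTrajectory"]


@dataclass
class DescriptorTrajectory:
    """One descriptor's time course: ``values[d, t]`` (D features x T frames)."""

    descriptor: str
    unit: RegionUnit
    values: np.ndarray
    frame_times_s: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.frame_times_s):
            raise ValueError("values and frame_times_s disagree on frame count")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{d:03d}" for d in range(self.n_features)]
        df = pd.DataFrame(self.values, index=pd.Index(names, name="feature"))
        df.columns = [f"t{t:02d}" for t in range(self.values.shape[1])]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, descriptor: str, unit: RegionUnit,
                 frame_times_s: np.ndarray) -> "DescriptorTrajectory":
        df = pd.read_csv(path, index_col=0)
        return cls(descriptor=descriptor, unit=unit, values=df.to_numpy(),
                   frame_times_s=frame_times_s,
                   feature_names=list(df.index))
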