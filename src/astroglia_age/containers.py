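"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


@dataclass
class ImageStack3D:
    """A calibrated voxel grid.

    ``data`` is (z, y, x); ``spacing`` is (dz, dy, dx) in µm.  ``calibration``
    holds (gain, offset) once the stack has been converted to photon counts.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 0.2, 0.2)
    calibration: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("ImageStack3D expects a (z, y, x) array")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")
        if self.calibration is not None and np.any(self.data < 0):
            raise ValueError("calibrated stacks must be non-negative")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class Image2D:
    """A single 2D field (y, x) with an isotropic pixel size in µm."""

    data: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("Image2D expects a (y, x) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def fov_area(self) -> float:
        """Field-of-view area in µm²."""
        return self.data.size * self.pixel_size ** 2


@dataclass
class CaMovie:
    """Time-lapse Ca2+ recording: frames (t, y, x) plus optional dark frames."""

    frames: np.ndarray
    pixel_size: float
    frame_interval: float = 1.0
    dark_frames: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise ValueError("CaMovie expects a (t, y, x) array")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def fov_area(self) -> float:
        return self.frames.shape[1] * self.frames.shape[2] * self.pixel_size ** 2


@dataclass
class SweepSet:
    """Uniformly sampled current sweeps with stimulus annotations.

    ``sweeps`` maps a sweep name (e.g. "stim1", "stim5", "tboa5", "step") to a
    1D trace in pA; ``stim_times`` maps the same names to stimulus times (s).
    """

    time: np.ndarray                       # seconds
    sweeps: dict[str, np.ndarray]
    sampling_rate: float
    stim_times: dict[str, np.ndarray] = field(default_factory=dict)
    holding_mv: float = -80.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        n = self.time.size
        for name, tr in self.sweeps.items():
            if tr.size != n:
                raise ValueError(f"sweep {name!r} length mismatch")
        for name, st in self.stim_times.items():
            st = np.asarray(st, dtype=float)
            if st.size and (st.min() < self.time[0] or st.max() > self.time[-1]):
                raise ValueError(f"stimulus annotation of {name!r} outside trace span")


@dataclass
class FepspTimecourse:
    """fEPSP amplitude timecourse; HFS at t = 0 min."""

    t_min: np.ndarray       # minutes relative to HFS
    amplitude: np.ndarray   # mV

    def __post_init__(self):
        if self.t_min.size != self.amplitude.size:
            raise ValueError("time / amplitude length mismatch")
        if not np.any(self.t_min < 0):
            raise ValueError("baseline period (t < 0) is empty")


class GroundTruth(dict):
    """Record of every planted quantity emitted by a generator.

    A thin dict subclass: keys are quantity names, values are numbers, lists
    or nested dicts.  Serializable to JSON so downstream recovery tests can
    consume emitted files without touching generator internals.
    """

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self, indent=2, default=_json_default))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(json.loads(Path(path).read_text()))
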