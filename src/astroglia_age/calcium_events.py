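"""Spatiotemporal Ca2+ event detection in x-y-t movies.

Transients are detected per pixel as ΔF/F0 excursions above ``k_sigma``
noise standard deviations, with F0 a rolling low-percentile baseline; runs
not longer than 4 s are erased (astrocytic events outlast neuronal ones).
Surviving active voxels are combined into 26-connected components in
(t, y, x) -- the spatiotemporal events -- and each event is measured for
duration, area (maximal projection onto the x-y plane), volume and its
initiation spot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .containers import CaMovie
from .imaging_core import FULL_CONNECTIVITY

_TIME_ONLY = np.zeros((3, 3, 3), dtype=bool)
_TIME_ONLY[:, 1, 1] = True


@dataclass
class CaEvent:
    """One spatiotemporal Ca2+ event and its metrics."""

    label: int
    voxels: np.ndarray            # (n, 3) int indices (t, y, x)
    duration: float               # s
    area: float                   # µm², distinct (y, x) pixels
    volume: float                 # s·µm²
    onset_frame: int
    initiation_pixel: tuple[int, int]

    def __post_init__(self):
        # area * frame_interval <= volume <= area * duration by construction;
        # violated only by a bookkeeping bug, so assert cheaply
        assert self.volume <= self.area * self.duration + 1e-9


@dataclass
class CaEventSet:
    events: list[CaEvent]
    labels: np.ndarray            # labelled (t, y, x) volume
    pixel_size: float
    frame_interval: float

    def __len__(self):
        return len(self.events)

    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events])

    def areas(self) -> np.ndarray:
        return np.array([e.area for e in self.events])

    def volumes(self) -> np.ndarray:
        return np.array([e.volume for e in self.events])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"id": e.label, "onset_frame": e.onset_frame,
              "duration_s": e.duration, "area_um2": e.area,
              "volume_s_um2": e.volume,
              "init_y": e.initiation_pixel[0],
              "init_x": e.initiation_pixel[1]} for e in self.events])


@dataclass
class InitiationMap:
    """Per-pixel counts of initiated events plus the events-per-spot
    histogram; the counts always sum to the number of events."""

    counts: np.ndarray
    histogram: dict[int, int]
    binning: int = 1


def pixel_noise_sigma(movie: CaMovie) -> np.ndarray:
    """Per-pixel noise sigma: dark-frame sample SD when dark frames exist,
    otherwise a temporal MAD estimate from the movie itself."""
    if movie.dark_frames is not None:
        return movie.dark_frames.std(axis=0, ddof=1)
    med = np.median(movie.frames, axis=0)
    return 1.4826 * np.median(np.abs(movie.frames - med), axis=0)


def rolling_percentile_baseline(frames: np.ndarray, window: int = 121,
                                percentile: float = 20.0,
                                stride: int = 10,
                                chunk: int = 600) -> np.ndarray:
    """Rolling per-pixel percentile of the fluorescence trace.

    The percentile is evaluated on window centres every ``stride`` frames
    and linearly interpolated in between -- the baseline varies on a much
    slower timescale than single frames.  Edges are reflect-padded;
    computed in pixel chunks to bound memory.
    """
    T, H, W = frames.shape
    if T < window:
        raise ValueError(f"movie of {T} frames shorter than the "
                         f"baseline window ({window})")
    half = window // 2
    flat = frames.reshape(T, -1)
    padded = np.pad(flat, ((half, half), (0, 0)), mode="reflect")
    centres = np.arange(0, T, max(1, stride))
    if centres[-1] != T - 1:
        centres = np.append(centres, T - 1)
    coarse = np.empty((centres.size, flat.shape[1]), dtype=np.float32)
    for j0 in range(0, flat.shape[1], chunk):
        j1 = min(j0 + chunk, flat.shape[1])
        win = np.lib.stride_tricks.sliding_window_view(
            padded[:, j0:j1], window, axis=0)      # (T, px, window)
        coarse[:, j0:j1] = np.percentile(win[centres], percentile, axis=-1)
    if centres.size == T:
        return coarse.reshape(T, H, W)
    out = np.empty_like(flat, dtype=np.float32)
    # vectorized linear interpolation between consecutive centres
    idx = np.searchsorted(centres, np.arange(T), side="right") - 1
    idx = np.clip(idx, 0, centres.size - 2)
    t0, t1 = centres[idx], centres[idx + 1]
    wgt = ((np.arange(T) - t0) / np.maximum(t1 - t0, 1))[:, None]
    out = coarse[idx] * (1 - wgt) + coarse[idx + 1] * wgt
    return out.astype(np.float32).reshape(T, H, W)


def detect_pixel_transients(movie: CaMovie, k_sigma: float = 3.0,
                            min_duration: float = 4.0,
                            baseline_window: int = 121,
                            baseline_percentile: float = 20.0,
                            correct_baseline_bias: bool = True
                            ) -> np.ndarray:
    """Per-pixel transient detection; returns the active (t, y, x) mask.

    F0 is a rolling ``baseline_percentile`` of each pixel trace.  For pure
    Gaussian noise that percentile sits ``z_p * sigma`` below the mean, so
    by default F0 is shifted back up by that amount -- the ΔF threshold then
    has the nominal Gaussian false-positive rate.  Active runs lasting
    ``min_duration`` or less (strictly: not longer than 4 s) are erased.
    """
    sigma = pixel_noise_sigma(movie)
    f0 = rolling_percentile_baseline(movie.frames, baseline_window,
                                     baseline_percentile)
    if correct_baseline_bias:
        f0 = f0 - norm.ppf(baseline_percentile / 100.0) * sigma
    active = (movie.frames - f0) > k_sigma * sigma

    # erase per-pixel runs with duration <= min_duration
    runs, n = ndimage.label(active, structure=_TIME_ONLY)
    if n:
        sizes = np.bincount(runs.ravel())
        min_frames = int(np.floor(min_duration / movie.frame_interval)) + 1
        keep = sizes >= min_frames
        keep[0] = False
        active = keep[runs]
    return active


def label_events(mask: np.ndarray, pixel_size: float = 1.0,
                 frame_interval: float = 1.0,
                 min_voxels: int = 4,
                 dF: Optional[np.ndarray] = None) -> CaEventSet:
    """Combine active voxels into 26-connected x-y-t events and measure them.

    Components smaller than ``min_voxels`` voxels are discarded.  ``dF``
    (e.g. the baseline-subtracted movie) weights the initiation centroid;
    uniform weights are used when omitted.
    """
    labels, n = ndimage.label(mask, structure=FULL_CONNECTIVITY)
    events = []
    if n:
        objects = ndimage.find_objects(labels)
        new_label = 0
        for lab, sl in enumerate(objects, start=1):
            coords = np.argwhere(labels[sl] == lab)
            if len(coords) < min_voxels:
                labels[sl][labels[sl] == lab] = 0
                continue
            coords += [s.start for s in sl]
            new_label += 1
            w = dF[tuple(coords.T)] if dF is not None else None
            events.append(event_metrics(coords, pixel_size, frame_interval,
                                        label=new_label, weights=w))
    return CaEventSet(events=events, labels=labels, pixel_size=pixel_size,
                      frame_interval=frame_interval)


def event_metrics(coords: np.ndarray, pixel_size: float,
                  frame_interval: float, label: int = 0,
                  weights: Optional[np.ndarray] = None) -> CaEvent:
    """Metrics of one event given its (t, y, x) voxel coordinates.

    duration = (last - first frame + 1) x frame_interval;
    area = distinct (y, x) pixels x pixel_size²;
    volume = voxel count x pixel_size² x frame_interval;
    initiation pixel = (weighted) centroid of the first active frame.
    """
    t = coords[:, 0]
    t0 = int(t.min())
    duration = (int(t.max()) - t0 + 1) * frame_interval
    area = len(np.unique(coords[:, 1:] @ np.array([1 << 20, 1]))) \
        * pixel_size ** 2
    volume = len(coords) * pixel_size ** 2 * frame_interval
    first = coords[t == t0][:, 1:]
    if weights is not None:
        w = np.clip(np.asarray(weights, dtype=float)[t == t0], 1e-9, None)
    else:
        w = np.ones(len(first))
    cy, cx = (first * w[:, None]).sum(axis=0) / w.sum()
    return CaEvent(label=label, voxels=coords, duration=float(duration),
                   area=float(area), volume=float(volume), onset_frame=t0,
                   initiation_pixel=(int(round(cy)), int(round(cx))))


def frequency_density(events: CaEventSet, fov_area: float,
                      record_duration: float) -> float:
    """Event frequency density: n_events / (field area x recording time),
    in s⁻¹ µm⁻²."""
    return len(events) / (fov_area * record_duration)


def initiation_statistics(events: CaEventSet, shape: tuple[int, int],
                          binning: int = 2) -> InitiationMap:
    """Counts of events initiated per (binned) pixel plus the
    events-per-spot histogram."""
    H, W = shape
    hb, wb = -(-H // binning), -(-W // binning)
    counts = np.zeros((hb, wb), dtype=int)
    for e in events.events:
        y, x = e.initiation_pixel
        counts[min(y // binning, hb - 1), min(x // binning, wb - 1)] += 1
    vals, freqs = np.unique(counts[counts > 0], return_counts=True)
    return InitiationMap(counts=counts,
                         histogram={int(v): int(f)
                                    for v, f in zip(vals, freqs)},
                         binning=binning)
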