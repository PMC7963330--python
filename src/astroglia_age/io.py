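"""File formats: TIFF stacks/movies, tabular traces, SWC graphs, JSON.

Images and movies travel as multi-page TIFF with the physical spacing in the
ImageJ-style metadata plus a JSON sidecar; traces as plain-text TSV with one
header line (time + one column per sweep) and a JSON sidecar for sampling
rate / stimulus annotations; branch graphs as SWC-style text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import CaMovie, FepspTimecourse, ImageStack3D, SweepSet


def write_stack(path: str | Path, stack: ImageStack3D) -> None:
    path = Path(path)
    dz, dy, dx = stack.spacing
    tifffile.imwrite(path, stack.data, imagej=True,
                     resolution=(1.0 / dx, 1.0 / dy),
                     metadata={"spacing": dz, "unit": "um", "axes": "ZYX"})
    sidecar = {"spacing_um": list(stack.spacing),
               "calibration": list(stack.calibration)
               if stack.calibration else None}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> ImageStack3D:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    spacing = (1.0, 0.2, 0.2)
    calibration = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = tuple(meta.get("spacing_um", spacing))
        cal = meta.get("calibration")
        calibration = tuple(cal) if cal else None
    return ImageStack3D(np.asarray(data), spacing, calibration)


def write_movie(path: str | Path, movie: CaMovie) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.frames, imagej=True,
                     metadata={"axes": "TYX", "finterval": movie.frame_interval})
    if movie.dark_frames is not None:
        tifffile.imwrite(path.with_name(path.stem + "_dark.tif"),
                         movie.dark_frames)
    path.with_suffix(".json").write_text(json.dumps(
        {"pixel_size_um": movie.pixel_size,
         "frame_interval_s": movie.frame_interval}, indent=2))


def read_movie(path: str | Path) -> CaMovie:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path))
    meta = {}
    if path.with_suffix(".json").exists():
        meta = json.loads(path.with_suffix(".json").read_text())
    dark_path = path.with_name(path.stem + "_dark.tif")
    dark = np.asarray(tifffile.imread(dark_path)) if dark_path.exists() else None
    return CaMovie(frames, pixel_size=meta.get("pixel_size_um", 1.0),
                   frame_interval=meta.get("frame_interval_s", 1.0),
                   dark_frames=dark)


def write_sweeps(path: str | Path, sweeps: SweepSet) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": sweeps.time})
    for name, tr in sweeps.sweeps.items():
        df[name] = tr
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = {"sampling_rate_hz": sweeps.sampling_rate,
               "holding_mv": sweeps.holding_mv,
               "stim_times_s": {k: np.asarray(v).tolist()
                                for k, v in sweeps.stim_times.items()},
               "meta": sweeps.meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_sweeps(path: str | Path) -> SweepSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    time = df["time_s"].to_numpy()
    sweeps = {c: df[c].to_numpy() for c in df.columns if c != "time_s"}
    return SweepSet(time=time, sweeps=sweeps,
                    sampling_rate=meta["sampling_rate_hz"],
                    stim_times={k: np.asarray(v)
                                for k, v in meta["stim_times_s"].items()},
                    holding_mv=meta.get("holding_mv", -80.0),
                    meta=meta.get("meta", {}))


def write_timecourse(path: str | Path, tc: FepspTimecourse) -> None:
    pd.DataFrame({"t_min": tc.t_min, "amplitude_mv": tc.amplitude}
                 ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_timecourse(path: str | Path) -> FepspTimecourse:
    df = pd.read_csv(path, sep="\t")
    return FepspTimecourse(t_min=df["t_min"].to_numpy(),
                           amplitude=df["amplitude_mv"].to_numpy())


def write_swc(path: str | Path, branch_graph) -> None:
    """SWC-style export: id, type, x, y, z, radius, parent (µm).

    The soma centre is the root; each edge polyline becomes a chain of slab
    points.  Type codes: 1 soma, 5 branch point, 6 end point, 7 slab.
    """
    lines = ["# id type x y z radius parent"]
    g = branch_graph.graph
    idx = 1
    zc, yc, xc = branch_graph.soma_center
    lines.append(f"1 1 {xc:.3f} {yc:.3f} {zc:.3f} 1.0 -1")
    idx = 2
    for u, v, d in g.edges(data=True):
        parent = 1
        for p in d["path"]:
            lines.append(f"{idx} 7 {p[2]:.3f} {p[1]:.3f} {p[0]:.3f} 0.5 "
                         f"{parent}")
            parent = idx
            idx += 1
    Path(path).write_text("\n".join(lines) + "\n")
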