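"""End-to-end parameter-recovery experiments.

Each function generates synthetic data with a named age-group preset and
runs the corresponding analysis stage from scratch, returning the measured
quantity.  These are the building blocks of the report pipeline and of the
benchmark that checks recovery of the planted (published) group values.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from . import calcium_events as ca
from . import ephys, imaging_core, morphometry, synthgen, volume_fraction
from .presets import (ASTROCYTE_PRESETS, CA_MOVIE_PRESETS, COUPLING_PRESETS,
                      EPHYS_PRESETS, LTP_PRESETS, SR101_PRESETS)

# sub-seeds are derived per replicate from (seed, index) via a small
# SeedSequence spawn so replicates are independent but reproducible
def _sub_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0]
               % (2 ** 31))


def calibrated_stack(stack, seed: int = 0):
    """Photon-transfer calibration + conversion to photon counts."""
    cal = imaging_core.estimate_pmt_gain_offset(stack, n_patches=500,
                                                seed=seed)
    return imaging_core.to_photon_counts(stack, cal), cal


def vf_per_cell(group: str, n_stacks: int, seed: int) -> list[float]:
    """Per-cell mean VF (%) on calibrated synthetic stacks."""
    preset = ASTROCYTE_PRESETS[group]
    out = []
    for i in range(n_stacks):
        stack, _ = synthgen.gen_astrocyte_stack(preset, _sub_seed(seed, i),
                                                domain_truth=False)
        photons, _ = calibrated_stack(stack, seed=_sub_seed(seed, i))
        res = volume_fraction.estimate_vf(photons)
        out.append(res.mean_vf)
    return out


def segment_cell(stack, seed: int = 0):
    """Shared imaging front end on a raw stack: calibrate to photon counts,
    estimate the noise sigma and residual background from a corner box,
    enhance, binarize at 1x/3x sigma, prune sub-100-voxel structures.

    Returns (mask, photon stack, enhanced stack, noise_sigma).
    """
    photons, cal = calibrated_stack(stack, seed=seed)
    # sigma and residual background from the raw corner box: the zero-clip
    # of the photon conversion distorts a MAD taken on converted counts
    sigma = imaging_core.estimate_noise_sigma(stack) / cal.gain
    box = tuple(slice(0, max(2, s // 4)) for s in stack.data.shape)
    background = max(
        (float(np.median(stack.data[box])) - cal.offset) / cal.gain, 0.0)
    enhanced = imaging_core.enhance_tubular(photons)
    mask = imaging_core.binarize_hysteresis(enhanced, sigma,
                                            background=background)
    return imaging_core.prune_small(mask), photons, enhanced, sigma


def soma_mask_from_stack(stack) -> np.ndarray:
    """Largest connected region above half the smoothed maximum."""
    from scipy import ndimage
    sm = ndimage.gaussian_filter(stack.data.astype(np.float32), (0, 2, 2))
    mask = sm >= 0.5 * sm.max()
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel()); sizes[0] = 0
        mask = labels == sizes.argmax()
    return mask


def morphometry_per_cell(group: str, n_stacks: int, seed: int,
                         with_gt: bool = False,
                         domain_truth: bool = False) -> list[dict]:
    """Full morphometry stage per synthetic cell.

    Returns one dict per cell with n_primary, max_intersections,
    mean_branch_length, domain_area (and the ground truth when requested;
    the expensive ground-truth footprint is skipped unless asked for).
    """
    preset = ASTROCYTE_PRESETS[group]
    out = []
    for i in range(n_stacks):
        s = _sub_seed(seed, i)
        stack, gt = synthgen.gen_astrocyte_stack(preset, s,
                                                 domain_truth=domain_truth)
        mask, photons, enhanced, _ = segment_cell(stack, seed=s)
        soma = soma_mask_from_stack(stack)
        trace_mask = morphometry.tracing_mask(enhanced, mask)
        bg = morphometry.extract_branch_graph(
            trace_mask | soma, soma, spacing=stack.spacing,
            support_mask=mask)
        profile = morphometry.sholl_3d(bg)
        summ = morphometry.summarize_morphometry(bg, profile, mask)
        rec = {"n_primary": summ.n_primary,
               "max_intersections": summ.max_intersections,
               "mean_branch_length": summ.mean_branch_length,
               "domain_area": summ.domain_area}
        if with_gt:
            rec["gt"] = gt
        out.append(rec)
    return out


def domain_areas(group: str, n_stacks: int, seed: int) -> list[float]:
    """Domain area (µm²) per cell from the binarized-mask projection, the
    lighter path used when the branch graph is not needed."""
    preset = ASTROCYTE_PRESETS[group]
    out = []
    for i in range(n_stacks):
        s = _sub_seed(seed, i)
        stack, _ = synthgen.gen_astrocyte_stack(preset, s)
        mask, _, _, _ = segment_cell(stack, seed=s)
        out.append(morphometry.projected_footprint_area(mask, stack.spacing))
    return out


def sr101_densities(group: str, n_fields: int, seed: int) -> list[float]:
    preset = SR101_PRESETS[group]
    out = []
    for i in range(n_fields):
        img, _ = synthgen.gen_sr101_field(preset, _sub_seed(seed, i))
        out.append(morphometry.count_somata(img, soma_sigma=preset.soma_sigma))
    return out


def coupled_count(group: str, seed: int) -> int:
    preset = COUPLING_PRESETS[group]
    img, _ = synthgen.gen_coupling_image(preset, _sub_seed(seed, 0))
    return morphometry.count_coupled(img, soma_sigma=preset.soma_sigma)


def detect_movie_events(movie) -> ca.CaEventSet:
    mask = ca.detect_pixel_transients(movie)
    f0 = ca.rolling_percentile_baseline(movie.frames)
    return ca.label_events(mask, pixel_size=movie.pixel_size,
                           frame_interval=movie.frame_interval,
                           dF=movie.frames - f0)


def ca_event_table(group: str, n_movies: int, seed: int,
                   n_events_total: Optional[int] = None) -> pd.DataFrame:
    """Detected-event table across seeded movies.

    ``n_events_total`` distributes a fixed total number of planted events
    across the movies (remainder on the first ones); otherwise every movie
    uses the preset's event count.
    """
    preset = CA_MOVIE_PRESETS[group]
    counts = [preset.n_events] * n_movies
    if n_events_total is not None:
        base, rem = divmod(n_events_total, n_movies)
        counts = [base + (1 if i < rem else 0) for i in range(n_movies)]
    frames = []
    for i, n_ev in enumerate(counts):
        p = replace(preset, n_events=n_ev)
        movie, _ = synthgen.gen_ca_movie(p, _sub_seed(seed, i))
        evs = detect_movie_events(movie)
        df = evs.to_frame()
        df["movie"] = i
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def input_resistance_once(group: str, seed: int) -> float:
    preset = EPHYS_PRESETS[group]
    sweeps, _ = synthgen.gen_vclamp_sweeps(preset, [-5.0], _sub_seed(seed, 0))
    return ephys.input_resistance(sweeps, dv=-5.0)


def ik_tau_ratio_once(group: str, seed: int) -> float:
    """tau(I_K(5)) / tau(I_K(1)) from mono-exponential decay fits on the
    single-stimulus sweep and the burst-subtracted 5th response."""
    preset = EPHYS_PRESETS[group]
    sweeps, _ = synthgen.gen_synaptic_sweeps(preset, _sub_seed(seed, 0))
    t = sweeps.time
    s1 = sweeps.sweeps["stim1"].astype(np.float64)
    s5 = ephys.isolate_fifth(sweeps.sweeps["stim5"].astype(np.float64),
                             sweeps.sweeps["stim4"].astype(np.float64))
    tau1 = ephys.fit_monoexp(t, s1,
                             fit_start=float(sweeps.stim_times["stim1"][0])
                             + 0.2).tau
    tau5 = ephys.fit_monoexp(t, s5,
                             fit_start=float(sweeps.stim_times["stim5"][-1])
                             + 0.2).tau
    return tau5 / tau1


def ltp_once(group: str, seed: int) -> float:
    preset = LTP_PRESETS[group]
    tc, _ = synthgen.gen_fepsp_timecourse(preset, _sub_seed(seed, 0))
    return ephys.ltp_magnitude(tc)
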