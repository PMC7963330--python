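"""Synthetic-data generators with machine-readable ground truth.

Every generator is a pure function of ``(preset, seed)``: identical inputs
give bit-identical outputs, and every planted quantity is echoed in the
returned :class:`~astroglia_age.containers.GroundTruth` so downstream
parameter-recovery tests need no other information.

The image model throughout is: expected photon rate per voxel -> Gaussian
PSF blur -> Poisson photon noise -> ``gain * counts + offset`` -> additive
Gaussian read noise, matching the variance-vs-mean detector calibration the
imaging stage performs.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .containers import (CaMovie, FepspTimecourse, GroundTruth, Image2D,
                         ImageStack3D, SweepSet)
from .presets import (AstrocytePreset, CaMoviePreset, CouplingPreset,
                      EphysPreset, LtpPreset, PresetError, Sr101Preset)

__all__ = [
    "gen_astrocyte_stack", "gen_sr101_field", "gen_coupling_image",
    "gen_ca_movie", "gen_vclamp_sweeps", "gen_synaptic_sweeps",
    "gen_fepsp_timecourse", "ik_waveform", "glut_waveform",
    "iv_step_protocol",
]


# ---------------------------------------------------------------------------
# dye-filled astrocyte z-stack
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _primary_directions(n: int, z_flatten: float, rng: np.random.Generator):
    """Quasi-even azimuthal directions with jitter, compressed along z."""
    dirs = []
    for k in range(n):
        phi = 2 * math.pi * (k + rng.uniform(-0.25, 0.25)) / n
        # polar angle near the equator so trees stay in the imaged z-range
        theta = math.pi / 2 + rng.uniform(-0.5, 0.5)
        d = np.array([math.cos(theta) * z_flatten,
                      math.sin(theta) * math.sin(phi),
                      math.sin(theta) * math.cos(phi)])
        dirs.append(_unit(d))
    return dirs


def _grow_tree(preset: AstrocytePreset, rng: np.random.Generator):
    """Recursive persistent random walk; returns list of segment dicts.

    Each segment is a polyline of (z, y, x) points in µm relative to the soma
    centre, with its branching order and drawn length.  Segments stop at the
    domain ellipsoid; a segment is recorded only if at least 1.5 µm survives.
    """
    step = 0.4
    jitter = preset.walk_jitter    # direction noise per step (radians-ish)
    z_flat = preset.domain_z_radius / preset.domain_radius
    segments = []
    stack = []             # (start point, direction, order)
    for d in _primary_directions(preset.n_primary, z_flat, rng):
        start = d * preset.soma_radius * 0.9
        stack.append((start, d, 1))

    max_segments = 400     # guard against runaway growth
    while stack and len(segments) < max_segments:
        start, direction, order = stack.pop()
        draw_mean = preset.length_draw_mean or preset.branch_length_mean
        target_len = max(1.5, rng.normal(draw_mean, preset.branch_length_sd))
        pts = [start.copy()]
        p = start.copy()
        d = direction.copy()
        walked = 0.0
        hit_boundary = False
        while walked < target_len:
            d = _unit(d + rng.normal(0.0, jitter, 3) * step)
            # keep walks inside the flattened domain ellipsoid
            q = p + d * step
            rho = math.hypot(q[1], q[2]) / preset.domain_radius
            zr = abs(q[0]) / preset.domain_z_radius
            if rho * rho + zr * zr >= 1.0:
                hit_boundary = True
                break
            p = q
            pts.append(p.copy())
            walked += step
        if walked >= 1.5:
            pts_arr = np.asarray(pts)
            segments.append({"points": pts_arr, "order": order,
                             "length": walked})
            if not hit_boundary and order < preset.branch_order_depth \
                    and rng.uniform() < preset.bifurcation_prob:
                # daughters diverge widely, as real branchlets do; slow
                # divergence would fuse their blurred tubes for several µm
                # and hide the junction from any tracer
                axis = _unit(rng.normal(0, 1, 3))
                for sign in (+1.0, -1.0):
                    ang = sign * rng.uniform(0.55, 1.1)
                    child = _rotate(d, axis, ang)
                    stack.append((p.copy(), child, order + 1))
    return segments


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about axis."""
    c, s = math.cos(angle), math.sin(angle)
    return _unit(v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c))


def _paint_spheres(vol: np.ndarray, centers_vox: np.ndarray, radius_um: float,
                   spacing: Sequence[float], value: float) -> None:
    """Set voxels within radius_um of any centre to at least ``value``."""
    rz, ry, rx = (max(1, int(math.ceil(radius_um / s))) for s in spacing)
    zz, yy, xx = np.mgrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    dist2 = ((zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2
             + (xx * spacing[2]) ** 2)
    offs = np.argwhere(dist2 <= radius_um ** 2) - np.array([rz, ry, rx])
    shape = np.array(vol.shape)
    for c in centers_vox:
        idx = offs + c
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        flat = np.ravel_multi_index(idx.T, vol.shape)
        np.maximum.at(vol.reshape(-1), flat, value)


def gen_astrocyte_stack(preset: AstrocytePreset, seed: int,
                        return_noiseless: bool = False,
                        domain_truth: bool = True):
    """Generate a dye-filled astrocyte z-stack and its ground truth.

    The stack contains a spherical soma, a recursively branched tree grown by
    persistent random walks, and a sub-resolution leaflet "haze" that fills a
    soft-edged sleeve around every planted structure.  The haze brightness is
    calibrated per stack so that the noiseless soma-plane annulus 10-20 µm
    outside the soma border (branch cores excluded) averages exactly
    ``preset.leaflet_vf`` of the soma photon rate -- i.e. the planted volume
    fraction is exact by construction, whatever the sleeve coverage.

    Returns ``(ImageStack3D, GroundTruth)``; with ``return_noiseless=True``
    a third element holds the blurred noiseless photon-rate volume.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = preset.shape
    dz, dy, dx = preset.spacing
    center = np.array([(nz - 1) / 2 * dz, (ny - 1) / 2 * dy, (nx - 1) / 2 * dx])

    segments = _grow_tree(preset, rng)

    lam = np.zeros(preset.shape, dtype=np.float32)
    lam_soma = preset.photon_rate_soma
    lam_branch = preset.branch_intensity_frac * lam_soma

    # soma sphere
    zc, yc, xc = (center / np.array([dz, dy, dx])).round().astype(int)
    _paint_spheres(lam, np.array([[zc, yc, xc]]), preset.soma_radius,
                   preset.spacing, lam_soma)

    # branch tubes: resample polylines at 0.2 µm and stamp spheres
    sample_pts = []
    for seg in segments:
        pts = seg["points"] + center
        d = np.diff(pts, axis=0)
        seglen = np.linalg.norm(d, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = np.arange(0.0, cum[-1], 0.2)
        for ax in range(3):
            sample_pts.append(np.interp(s, cum, pts[:, ax]))
    if sample_pts:
        pts_um = np.stack([np.concatenate(sample_pts[0::3]),
                           np.concatenate(sample_pts[1::3]),
                           np.concatenate(sample_pts[2::3])], axis=1)
        pts_vox = np.round(pts_um / np.array([dz, dy, dx])).astype(int)
        _paint_spheres(lam, pts_vox, preset.branch_radius, preset.spacing,
                       lam_branch)

    structure = lam > 0

    # leaflet haze: soft-edged sleeve around all structure
    dist = ndimage.distance_transform_edt(~structure,
                                          sampling=preset.spacing)
    taper = preset.haze_taper
    w = np.clip((preset.haze_sleeve_radius + taper - dist) / taper, 0.0, 1.0)
    if preset.haze_sleeve_radius <= 0:
        w[:] = 0.0

    if preset.leaflet_blob_count:
        # discrete leaflet clusters near the soma plane (dystrophic cells)
        r_lo, r_hi = preset.leaflet_blob_r_range
        r_hi = min(r_hi, preset.domain_radius - 1.0)
        zz3, yy3, xx3 = np.ogrid[0:nz, 0:ny, 0:nx]
        blob_w = np.zeros(preset.shape, dtype=np.float32)
        for _ in range(preset.leaflet_blob_count):
            rr = math.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2))
            phi = rng.uniform(0, 2 * math.pi)
            bz = center[0] + rng.normal(0.0, preset.leaflet_blob_z_sd)
            by = center[1] + rr * math.sin(phi)
            bx = center[2] + rr * math.cos(phi)
            d2 = (((zz3 * dz - bz)) ** 2 + ((yy3 * dy - by)) ** 2
                  + ((xx3 * dx - bx)) ** 2)
            r_b = preset.leaflet_blob_radius
            np.maximum(blob_w,
                       np.clip((r_b + taper - np.sqrt(d2)) / taper, 0.0, 1.0),
                       out=blob_w)
        w = np.maximum(w, blob_w)
    w[structure] = 0.0
    w = w.astype(np.float32)

    # Calibrate haze brightness so the *blurred* noiseless soma-plane
    # annulus 10-20 µm outside the soma border averages leaflet_vf x soma.
    # Structure and haze have disjoint supports, so the blurred stack is
    # blur(structure) + h * blur(w) and h can be solved for directly.
    # Pixels whose structure leakage alone exceeds the branch-excision
    # amplitude threshold are excluded: the VF estimator will cut them out.
    sigma_vox = (preset.psf_sigma_z / dz, preset.psf_sigma_xy / dy,
                 preset.psf_sigma_xy / dx)
    struct_blur = ndimage.gaussian_filter(lam, sigma_vox)
    w_blur = ndimage.gaussian_filter(w, sigma_vox)

    yy, xx = np.mgrid[0:ny, 0:nx]
    r_lat = np.hypot((yy - yc) * dy, (xx - xc) * dx)
    border = preset.soma_radius
    ring = (r_lat >= border + 10.0) & (r_lat <= border + 20.0)
    survive = ring & (struct_blur[zc] <= 0.10 * lam_soma)
    lam_bg = preset.background_rate
    peak = lam_soma + lam_bg          # what the soma plateau reads
    target = preset.leaflet_vf * peak - lam_bg
    if survive.any() and float(w_blur[zc][survive].mean()) > 1e-3:
        haze_level = max(
            (target - float(struct_blur[zc][survive].mean()))
            / float(w_blur[zc][survive].mean()), 0.0)
    else:
        haze_level = max(target, 0.0)
    mean_w = float(w_blur[zc][survive].mean()) if survive.any() else 0.0

    lam_blur = struct_blur + haze_level * w_blur + lam_bg

    # detector
    counts = rng.poisson(lam_blur).astype(np.float32)
    data = (preset.pmt_gain * counts + preset.pmt_offset
            + rng.normal(0.0, preset.read_noise, lam_blur.shape)).astype(np.float32)
    stack = ImageStack3D(data, preset.spacing)

    # Ground-truth footprint area: the noiseless photon-rate volume pushed
    # through the same deterministic measurement front end the pipeline
    # applies (coherence-enhancing diffusion, threshold at background + one
    # nominal noise sigma, z-projection, closing, hole fill).  Enhancement
    # widens contours slightly, so thresholding the raw rates would define
    # a systematically smaller footprint than any measurement can return.
    # Optional because the diffusion pass dominates generation time and the
    # VF stages never consume the area.
    true_area = None
    if domain_truth:
        from .imaging_core import enhance_tubular
        from .morphometry import projected_footprint_area
        nominal_sigma = math.sqrt(
            lam_bg + (preset.read_noise / preset.pmt_gain) ** 2)
        enhanced = enhance_tubular(
            ImageStack3D(lam_blur.astype(np.float32), preset.spacing))
        gt_mask = enhanced.data >= lam_bg + nominal_sigma
        true_area = projected_footprint_area(gt_mask, preset.spacing)

    seg_lengths = [seg["length"] for seg in segments]
    gt = GroundTruth(
        seed=seed,
        n_primary=preset.n_primary,
        mean_segment_length=float(np.mean(seg_lengths)) if seg_lengths else 0.0,
        segment_lengths=seg_lengths,
        segments=[{"points": seg["points"] + center, "order": seg["order"]}
                  for seg in segments],
        soma_center_um=center,
        soma_radius=preset.soma_radius,
        soma_plane=int(zc),
        true_vf=preset.leaflet_vf,
        haze_level_photons=haze_level,
        haze_annulus_coverage=mean_w,
        domain_area_um2=true_area,
        pmt_gain=preset.pmt_gain,
        pmt_offset=preset.pmt_offset,
        read_noise=preset.read_noise,
        photon_rate_soma=lam_soma,
    )
    if return_noiseless:
        return stack, gt, lam_blur
    return stack, gt


# ---------------------------------------------------------------------------
# SR101 field and dye-coupling image
# ---------------------------------------------------------------------------

def _place_poisson_disc(n: int, fov: tuple[float, float], min_spacing: float,
                        margin: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sampled point process with a hard exclusion radius (µm)."""
    pts: list[np.ndarray] = []
    tries = 0
    max_tries = 4000 * max(n, 1)
    while len(pts) < n:
        cand = np.array([rng.uniform(margin, fov[0] - margin),
                         rng.uniform(margin, fov[1] - margin)])
        if all(np.linalg.norm(cand - p) >= min_spacing for p in pts):
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"cannot place {n} somata with min spacing {min_spacing} µm "
                f"in a {fov[0]:g}x{fov[1]:g} µm field")
    return np.array(pts).reshape(-1, 2)


def _paint_gaussians(shape, coords_px, sigma_px, amp):
    img = np.zeros(shape, dtype=np.float32)
    for (cy, cx) in coords_px:
        img[int(round(cy)), int(round(cx))] += 1.0
    img = ndimage.gaussian_filter(img, sigma_px)
    if coords_px.size:
        img *= amp / img.max()
    return img


def gen_sr101_field(preset: Sr101Preset, seed: int):
    """SR101-stained field: Poisson-disc somata on a noisy background.

    The number of somata is Poisson-distributed with mean
    ``density x fov_area / (100x100 µm²)``.
    """
    rng = np.random.default_rng(seed)
    fov = preset.fov_um
    expected = preset.density * (fov[0] * fov[1]) / 1e4
    n = int(rng.poisson(expected))
    coords = _place_poisson_disc(n, fov, preset.min_spacing,
                                 margin=2 * preset.soma_sigma, rng=rng)
    shape = (int(round(fov[0] / preset.pixel_size)),
             int(round(fov[1] / preset.pixel_size)))
    coords_px = coords / preset.pixel_size
    img = _paint_gaussians(shape, coords_px, preset.soma_sigma / preset.pixel_size,
                           preset.soma_amp)
    img += preset.background
    img += rng.normal(0.0, preset.noise_sigma, shape).astype(np.float32)
    gt = GroundTruth(seed=seed, n_somata=n, coords_um=coords,
                     density=n / (fov[0] * fov[1] / 1e4),
                     expected_count=expected)
    return Image2D(img.astype(np.float32), preset.pixel_size), gt


def gen_coupling_image(preset: CouplingPreset, seed: int):
    """Dye-coupling image: one bright patched soma plus dimmer neighbours."""
    rng = np.random.default_rng(seed)
    fov = preset.fov_um
    coords = _place_poisson_disc(preset.n_coupled + 1, fov,
                                 preset.min_spacing,
                                 margin=2 * preset.soma_sigma, rng=rng)
    # patched cell sits nearest the centre
    centre = np.array(fov) / 2
    order = np.argsort(np.linalg.norm(coords - centre, axis=1))
    coords = coords[order]
    shape = (int(round(fov[0] / preset.pixel_size)),
             int(round(fov[1] / preset.pixel_size)))
    sig_px = preset.soma_sigma / preset.pixel_size
    img = _paint_gaussians(shape, coords[:1] / preset.pixel_size, sig_px,
                           preset.patched_amp)
    if preset.n_coupled:
        img = img + _paint_gaussians(shape, coords[1:] / preset.pixel_size,
                                     sig_px, preset.coupled_amp)
    img += preset.background
    img += rng.normal(0.0, preset.noise_sigma, shape).astype(np.float32)
    gt = GroundTruth(seed=seed, n_coupled=preset.n_coupled,
                     patched_um=coords[0], coupled_um=coords[1:])
    return Image2D(img.astype(np.float32), preset.pixel_size), gt


# ---------------------------------------------------------------------------
# Ca2+ movie with planted x-y-t events
# ---------------------------------------------------------------------------

def _grow_blob(seed_px: tuple[int, int], k: int, shape, rng) -> np.ndarray:
    """Connected, roughly round blob of exactly k pixels around seed_px."""
    taken = {seed_px}
    frontier = set()
    H, W = shape

    def neighbours(p):
        y, x = p
        for dy_, dx_ in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            q = (y + dy_, x + dx_)
            if 0 <= q[0] < H and 0 <= q[1] < W and q not in taken:
                yield q

    frontier.update(neighbours(seed_px))
    cy, cx = float(seed_px[0]), float(seed_px[1])
    while len(taken) < k and frontier:
        cand = sorted(frontier)
        d2 = np.array([(p[0] - cy) ** 2 + (p[1] - cx) ** 2 for p in cand])
        wgt = np.exp(-0.8 * (d2 - d2.min()))
        p = cand[rng.choice(len(cand), p=wgt / wgt.sum())]
        taken.add(p)
        frontier.discard(p)
        frontier.update(neighbours(p))
        n = len(taken)
        cy += (p[0] - cy) / n
        cx += (p[1] - cx) / n
    return np.array(sorted(taken))


def gen_ca_movie(preset: CaMoviePreset, seed: int):
    """Time-lapse movie with planted x-y-t events plus dark-noise frames.

    Events have a trapezoidal temporal profile (edge frames at 75 % of the
    plateau, zero outside) over a connected pixel footprint of exactly the
    drawn area, so the planted duration / area / volume are crisp targets
    for the detector.  Placement rejects spatiotemporal overlap; an event
    that cannot be placed conflict-free is flagged ``merge_expected``.
    """
    rng = np.random.default_rng(seed)
    H, W = preset.fov_px
    T = preset.n_frames
    dt = preset.frame_interval
    ps = preset.pixel_size
    min_frames = int(preset.min_duration_s / dt) + 1

    signal = np.zeros((T, H, W), dtype=np.float32)
    occupancy = np.zeros((T, H, W), dtype=bool)
    amp = preset.amplitude_snr * preset.noise_sigma
    margin = 5
    events = []
    spots: list[tuple[int, int]] = []
    footprints: dict[tuple[int, int], np.ndarray] = {}

    for _ in range(preset.n_events):
        dur = int(round(preset.duration_median
                        * math.exp(rng.normal(0.0, preset.duration_log_sd)) / dt))
        dur = max(min_frames, min(dur, T // 8))
        area_um2 = preset.area_median * math.exp(rng.normal(0.0, preset.area_log_sd))
        k = max(4, int(round(area_um2 / ps ** 2)))

        merge_expected = True
        placed = None
        for _try in range(60):
            if spots and rng.uniform() < preset.reuse_prob:
                # a re-initiated event reuses the spot's footprint, so its
                # initiation pixel is reproduced exactly
                spot = spots[rng.integers(len(spots))]
                pix = footprints[spot]
            else:
                spot = (int(rng.integers(margin, H - margin)),
                        int(rng.integers(margin, W - margin)))
                pix = _grow_blob(spot, k, (H, W), rng)
            t0 = int(rng.integers(10, T - dur - 10))
            # dilated spatiotemporal conflict check (26-connectivity margin)
            sl = slice(max(0, t0 - 2), min(T, t0 + dur + 2))
            region = np.zeros((H, W), dtype=bool)
            region[pix[:, 0], pix[:, 1]] = True
            region = ndimage.binary_dilation(region, np.ones((3, 3), bool))
            if not occupancy[sl][:, region].any():
                merge_expected = False
                placed = (spot, t0, pix)
                break
        if placed is None:
            placed = (spot, t0, pix)
        spot, t0, pix = placed
        spots.append(spot)
        footprints.setdefault(spot, pix)

        prof = np.full(dur, amp, dtype=np.float32)
        if dur >= 2:
            prof[0] = prof[-1] = 0.75 * amp
        for i, a in enumerate(prof):
            signal[t0 + i, pix[:, 0], pix[:, 1]] += a
        occupancy[t0:t0 + dur, pix[:, 0], pix[:, 1]] = True

        events.append({
            "onset_frame": t0,
            "duration_s": dur * dt,
            "n_pixels": int(len(pix)),
            "area_um2": len(pix) * ps ** 2,
            "volume": len(pix) * dur * ps ** 2 * dt,
            "pixels": pix,
            "initiation_pixel": [int(round(pix[:, 0].mean())),
                                 int(round(pix[:, 1].mean()))],
            "spot": list(spot),
            "merge_expected": merge_expected,
        })

    frames = (preset.baseline + signal
              + rng.normal(0.0, preset.noise_sigma, (T, H, W))).astype(np.float32)
    dark = (preset.dark_offset
            + rng.normal(0.0, preset.noise_sigma,
                         (preset.n_dark_frames, H, W))).astype(np.float32)
    movie = CaMovie(frames, pixel_size=ps, frame_interval=dt, dark_frames=dark)
    gt = GroundTruth(
        seed=seed, n_events=preset.n_events, events=events,
        noise_sigma=preset.noise_sigma, baseline=preset.baseline,
        durations_s=[e["duration_s"] for e in events],
        areas_um2=[e["area_um2"] for e in events],
    )
    return movie, gt


# ---------------------------------------------------------------------------
# voltage-clamp and field-potential generators
# ---------------------------------------------------------------------------

def iv_step_protocol(holding_mv: float = -80.0) -> list[float]:
    """Voltage-step increments (mV, relative to holding) of the I-V protocol:
    absolute steps from -140 to +80 mV in 20-mV increments."""
    return [v - holding_mv for v in range(-140, 81, 20)]


def gen_vclamp_sweeps(preset: EphysPreset, protocol: Sequence[float],
                      seed: int) -> tuple[SweepSet, GroundTruth]:
    """Ohmic current responses to voltage steps.

    ``protocol`` lists step amplitudes in mV relative to holding.  Each sweep
    is 0.8 s: 0.1 s pre-step baseline, 0.5 s step, 0.2 s recovery.  The
    response is ``dV / r_input`` (1 mV / 1 MOhm = 1000 pA) plus capacitive
    transients at the step edges and Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    fs = preset.sampling_rate
    t = np.arange(0.0, 0.8, 1.0 / fs)
    on, off = 0.1, 0.6
    sweeps = {}
    for dv in protocol:
        plateau = 1000.0 * dv / preset.r_input     # pA
        i = np.zeros_like(t)
        i[(t >= on) & (t < off)] = plateau
        tau = preset.cap_transient_tau / 1000.0
        sgn = math.copysign(1.0, dv) if dv != 0 else 0.0
        i += sgn * preset.cap_transient_amp * np.exp(-(t - on) / tau) * (t >= on)
        i -= sgn * preset.cap_transient_amp * np.exp(-(t - off) / tau) * (t >= off)
        i += rng.normal(0.0, preset.noise_sigma, t.size)
        sweeps[f"dv{dv:+g}"] = i.astype(np.float32)
    ss = SweepSet(time=t, sweeps=sweeps, sampling_rate=fs,
                  meta={"step_onset": on, "step_offset": off,
                        "protocol_mv": list(protocol)})
    gt = GroundTruth(seed=seed, r_input=preset.r_input,
                     plateau_pa={f"dv{dv:+g}": 1000.0 * dv / preset.r_input
                                 for dv in protocol})
    return ss, gt


def ik_waveform(t: np.ndarray, amp_at_200ms: float, tau_ms: float,
                rise_ms: float) -> np.ndarray:
    """Slow K+ uptake current (inward, negative), zero for t < 0.

    Parametrized by its magnitude 200 ms after the stimulus -- the time point
    at which I_K is conventionally measured -- with a mono-exponential decay
    of constant ``tau_ms`` beyond the rise.
    """
    tm = np.clip(t, 0.0, None) * 1000.0
    shape = (1.0 - np.exp(-tm / rise_ms)) * np.exp(-tm / tau_ms)
    ref = (1.0 - math.exp(-200.0 / rise_ms)) * math.exp(-200.0 / tau_ms)
    return np.where(t >= 0, -amp_at_200ms * shape / ref, 0.0)


def glut_waveform(t: np.ndarray, peak_amp: float, tau_ms: float,
                  rise_ms: float) -> np.ndarray:
    """Fast glutamate-transporter current (inward, negative), peak-normalized."""
    tm = np.clip(t, 0.0, None) * 1000.0
    shape = (1.0 - np.exp(-tm / rise_ms)) * np.exp(-tm / tau_ms)
    tpk = rise_ms * math.log1p(tau_ms / rise_ms)
    ref = (1.0 - math.exp(-tpk / rise_ms)) * math.exp(-tpk / tau_ms)
    return np.where(t >= 0, -peak_amp * shape / ref, 0.0)


def gen_synaptic_sweeps(preset: EphysPreset, seed: int,
                        duration: float = 1.8,
                        first_stim: float = 0.2) -> tuple[SweepSet, GroundTruth]:
    """Astrocytic currents for 1-, 4- and 5-stimulus bursts at 50 Hz.

    Sweeps are built component-wise: the 4-stimulus sweep is the exact sum of
    components 1-4 and the 5-stimulus sweep adds the planted 5th component,
    so burst subtraction recovers it by construction.  Components 1-4 carry
    the single-stimulus parameters; the 5th carries the ``*_5`` parameters.
    A ``tboaN`` sweep per burst holds ``residual_ik_scale`` x the I_K part
    only (the transporter-blocked template used to isolate I_GluT).
    """
    rng = np.random.default_rng(seed)
    fs = preset.sampling_rate
    t = np.arange(0.0, duration, 1.0 / fs)
    isi = 1.0 / 50.0
    stim_times = {n: first_stim + isi * np.arange(k)
                  for n, k in (("stim1", 1), ("stim4", 4), ("stim5", 5))}

    def component(ts: float, fifth: bool):
        ik = ik_waveform(t - ts,
                         preset.ik_amp_5 if fifth else preset.ik_amp_1,
                         preset.ik_tau_5 if fifth else preset.ik_tau_1,
                         preset.ik_rise_tau)
        gl = glut_waveform(t - ts,
                           preset.iglut_amp_5 if fifth else preset.iglut_amp_1,
                           preset.iglut_tau_5 if fifth else preset.iglut_tau_1,
                           preset.iglut_rise_tau)
        return ik, gl

    comps = [component(ts, fifth=(j == 4))
             for j, ts in enumerate(stim_times["stim5"])]
    ik_sum = {k: sum(c[0] for c in comps[:k]) for k in (1, 4, 5)}
    full_sum = {k: sum(c[0] + c[1] for c in comps[:k]) for k in (1, 4, 5)}

    sweeps, clean = {}, {}
    for k in (1, 4, 5):
        clean[f"stim{k}"] = full_sum[k]
        clean[f"tboa{k}"] = preset.residual_ik_scale * ik_sum[k]
    for name, tr in clean.items():
        sweeps[name] = (tr + rng.normal(0.0, preset.noise_sigma, t.size)
                        ).astype(np.float32)
    stim_times["tboa1"] = stim_times["stim1"]
    stim_times["tboa4"] = stim_times["stim4"]
    stim_times["tboa5"] = stim_times["stim5"]

    ss = SweepSet(time=t, sweeps=sweeps, sampling_rate=fs,
                  stim_times=stim_times,
                  meta={"first_stim": first_stim, "isi": isi})
    gt = GroundTruth(
        seed=seed,
        ik_amp_1=preset.ik_amp_1, ik_amp_5=preset.ik_amp_5,
        ik_tau_1=preset.ik_tau_1, ik_tau_5=preset.ik_tau_5,
        iglut_amp_1=preset.iglut_amp_1, iglut_amp_5=preset.iglut_amp_5,
        iglut_tau_1=preset.iglut_tau_1, iglut_tau_5=preset.iglut_tau_5,
        residual_ik_scale=preset.residual_ik_scale,
        amp_ratio_ik=preset.ik_amp_5 / preset.ik_amp_1,
        tau_ratio_ik=preset.ik_tau_5 / preset.ik_tau_1,
        amp_ratio_iglut=preset.iglut_amp_5 / preset.iglut_amp_1,
        tau_ratio_iglut=preset.iglut_tau_5 / preset.iglut_tau_1,
    )
    return ss, gt


def gen_fepsp_timecourse(preset: LtpPreset, seed: int
                         ) -> tuple[FepspTimecourse, GroundTruth]:
    """fEPSP amplitude series at ``inter_stimulus`` intervals around HFS.

    Pre-HFS amplitudes average ``baseline_amp``; after HFS the series decays
    from a brief post-tetanic overshoot to a plateau at
    ``potentiation_factor x baseline_amp``, with multiplicative noise.
    """
    rng = np.random.default_rng(seed)
    step_min = preset.inter_stimulus / 60.0
    t = np.arange(-preset.baseline_duration, preset.post_duration + 1e-9,
                  step_min)
    amp = np.full(t.size, preset.baseline_amp)
    post = t >= 0
    amp[post] = preset.baseline_amp * (
        preset.potentiation_factor
        + preset.ptp_extra * np.exp(-t[post] / preset.ptp_tau))
    if preset.noise_cv > 0:
        amp = amp * (1.0 + rng.normal(0.0, preset.noise_cv, t.size))
    tc = FepspTimecourse(t_min=t, amplitude=amp.astype(np.float64))
    gt = GroundTruth(seed=seed, potentiation_factor=preset.potentiation_factor,
                     baseline_amp=preset.baseline_amp)
    return tc, gt
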