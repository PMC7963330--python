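"""Photon calibration, noise estimation, tubular enhancement, binarization.

These operations are shared by every image-based stage.  The detector model
is ``intensity = gain * Poisson(photons) + offset + read noise``; gain and
offset are recovered from the linear dependence of per-patch variance on
per-patch mean (photon-transfer calibration), after which stacks are
expressed in photon counts.

Masks use 26-connectivity throughout: thin diagonal astrocytic processes
survive only under the full 3D neighbourhood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .containers import ImageStack3D

FULL_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


class CalibrationError(RuntimeError):
    """Variance-mean fit cannot yield a positive gain (e.g. structure- or
    noise-free data dominating the sampled patches)."""


@dataclass
class PmtCalibration:
    """Detector gain/offset with fit diagnostics."""

    gain: float                 # intensity units / photon
    offset: float               # intensity units (x-axis intercept)
    slope_se: float
    intercept_se: float
    n_patches: int

    def __post_init__(self):
        if self.gain <= 0:
            raise CalibrationError("gain must be positive")


def estimate_pmt_gain_offset(stack: ImageStack3D, n_patches: int = 500,
                             patch_size: int | tuple[int, int, int] = (1, 7, 7),
                             seed: int = 0, trim_iterations: int = 3,
                             trim_k: float = 2.0) -> PmtCalibration:
    """Photon-transfer calibration from randomly sampled small patches.

    Ordinary least squares of per-patch sample variance on per-patch sample
    mean: the slope is the PMT gain and the x-axis intercept the offset.

    Three refinements make the estimate usable on structured stacks.
    Patches straddling structure edges are rejected by a homogeneity test
    (box-averaging a noise-only patch cuts its variance by the box size,
    a gradient-dominated patch keeps most of it).  Surviving patches are
    sampled stratified across the intensity range, because a sparse cell
    otherwise yields an uninformative cluster of background patches.  The
    fit is initialized with the Theil-Sen median-of-slopes line and
    iteratively re-fit discarding patches whose *relative* residual (the
    sampling spread of a variance estimate scales with its value) exceeds
    ``trim_k`` robust standard deviations.  The default patch is a thin
    single-plane square: on an anisotropic voxel grid a geometric cube of
    voxels spans several µm axially and would straddle every thin process.

    Raises
    ------
    CalibrationError
        if the fitted slope is not positive (structure-dominated variance or
        a constant stack).
    ValueError
        if fewer than 10 patches are requested or patches do not fit.
    """
    if n_patches < 10:
        raise ValueError("need at least 10 patches for a stable fit")
    if isinstance(patch_size, int):
        patch_size = (patch_size,) * 3
    data = stack.data
    if any(s < p for s, p in zip(data.shape, patch_size)):
        raise ValueError(f"patch_size {patch_size} does not fit in stack "
                         f"of shape {data.shape}")
    rng = np.random.default_rng(seed)
    n_cand = 10 * n_patches
    pz, py, px = patch_size
    z0 = rng.integers(0, data.shape[0] - pz + 1, n_cand)
    y0 = rng.integers(0, data.shape[1] - py + 1, n_cand)
    x0 = rng.integers(0, data.shape[2] - px + 1, n_cand)
    offs = np.mgrid[0:pz, 0:py, 0:px].reshape(3, -1)
    patches = data[z0[:, None] + offs[0],
                   y0[:, None] + offs[1],
                   x0[:, None] + offs[2]].astype(np.float64)
    cand_means = patches.mean(axis=1)
    # noise variance from lateral pixel-pair differences: the difference of
    # adjacent pixels cancels smooth structure to first order, so residual
    # gradients bias this estimator about an order of magnitude less than
    # the raw patch variance
    cube = patches.reshape(n_cand, pz, py, px)
    dy_ = np.diff(cube, axis=2).reshape(n_cand, -1)
    dx_ = np.diff(cube, axis=3).reshape(n_cand, -1)
    cand_vars = 0.25 * (dy_.var(axis=1, ddof=1) + dx_.var(axis=1, ddof=1))

    if np.ptp(cand_means) < 1e-12:
        raise CalibrationError("constant stack: variance-mean fit degenerate")

    # homogeneity: variance of the 3x3 box-filtered patch interior stays
    # high only when a structure gradient, not noise, dominates
    cube = patches.reshape(n_cand, pz, py, px)
    sm = ndimage.uniform_filter(cube, size=(1, 1, 3, 3))[
        :, :, 1:py - 1, 1:px - 1]
    sm_var = sm.reshape(n_cand, -1).var(axis=1, ddof=1)
    # noise-only patches land near 0.08 with a 99th percentile of ~0.21
    smooth = sm_var <= 0.22 * np.maximum(cand_vars, 1e-30)
    if smooth.sum() >= 50:
        cand_means, cand_vars = cand_means[smooth], cand_vars[smooth]

    # stratify: half the patches from the background cluster (which anchors
    # the x-intercept), half spread over the elevated-intensity strata
    # (which carry the slope leverage)
    bg_thresh = np.percentile(cand_means, 60)
    bg_idx = np.flatnonzero(cand_means <= bg_thresh)
    el_idx = np.flatnonzero(cand_means > bg_thresh)
    rng.shuffle(bg_idx)
    sel = list(bg_idx[:n_patches // 2])
    if el_idx.size:
        n_bins = 8
        qedges = np.quantile(cand_means[el_idx],
                             np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.digitize(cand_means[el_idx], qedges)
        by_bin = [el_idx[bins == b] for b in range(n_bins)]
        for idx in by_bin:
            rng.shuffle(idx)
        depth = 0
        while len(sel) < n_patches and depth < el_idx.size:
            for idx in by_bin:
                if depth < idx.size and len(sel) < n_patches:
                    sel.append(idx[depth])
            depth += 1
    sel = np.asarray(sel[:n_patches])
    means, variances = cand_means[sel], cand_vars[sel]

    floor = max(np.percentile(variances, 5), 1e-12)

    def wls(m, v, coef0):
        """WLS with 1/variance² weights: the sampling error of a sample
        variance is proportional to its value, and the heavy weight of the
        low-variance background cluster pins down the x-intercept."""
        w = 1.0 / np.maximum(coef0[0] * m + coef0[1], floor) ** 2
        X = np.column_stack([m, np.ones_like(m)])
        XtW = X.T * w
        cov = np.linalg.inv(XtW @ X)
        coef = cov @ (XtW @ v)
        return coef, cov

    from scipy.stats import theilslopes
    ts = theilslopes(variances, means)
    coef = np.array([ts.slope, ts.intercept])
    keep = np.ones(means.size, dtype=bool)
    for _ in range(trim_iterations):
        pred = coef[0] * means + coef[1]
        rel = (variances - pred) / np.maximum(np.abs(pred), floor)
        r = rel[keep]
        sig = 1.4826 * np.median(np.abs(r - np.median(r)))
        if sig <= 0:
            break
        new_keep = np.abs(rel) <= trim_k * sig
        if new_keep.sum() < 10 or \
                np.ptp(means[new_keep]) < 0.3 * np.ptp(means):
            break
        new_coef, _ = wls(means[new_keep], variances[new_keep], coef)
        if new_coef[0] <= 0:
            # over-trimming collapsed the leverage; keep the previous fit
            break
        keep, coef = new_keep, new_coef

    m, v = means[keep], variances[keep]
    coef, cov_u = wls(m, v, coef)
    slope, intercept = coef
    resid = v - (slope * m + intercept)
    w = 1.0 / np.maximum(slope * m + intercept, floor) ** 2
    dof = max(m.size - 2, 1)
    s2 = float((w * resid ** 2).sum()) / dof
    cov = s2 * cov_u
    if slope <= 0:
        raise CalibrationError(
            f"non-positive variance-mean slope ({slope:.3g}); "
            "structure-dominated variance or noise-free data")
    return PmtCalibration(gain=float(slope),
                          offset=float(-intercept / slope),
                          slope_se=float(math.sqrt(cov[0, 0])),
                          intercept_se=float(math.sqrt(cov[1, 1])),
                          n_patches=int(m.size))


def to_photon_counts(stack: ImageStack3D, cal: PmtCalibration) -> ImageStack3D:
    """Convert detector units to photon-count estimates, clipped at zero."""
    if cal.gain <= 0:
        raise CalibrationError("gain must be positive")
    photons = np.clip((stack.data - cal.offset) / cal.gain, 0.0, None)
    return ImageStack3D(photons.astype(np.float32), stack.spacing,
                        calibration=(cal.gain, cal.offset))


def estimate_noise_sigma(stack: Optional[ImageStack3D] = None,
                         dark_frames: Optional[np.ndarray] = None,
                         background_box: Optional[tuple[slice, ...]] = None
                         ) -> float:
    """Robust noise sigma via the median absolute deviation (x1.4826).

    Dark frames are preferred when provided; otherwise a named background
    box of the stack is used (default: a corner block of 1/4 linear size).
    The whole stack is never used -- structure inflates sigma.
    """
    if dark_frames is not None:
        sample = np.asarray(dark_frames, dtype=np.float64).ravel()
    elif stack is not None:
        if background_box is None:
            background_box = tuple(slice(0, max(2, s // 4))
                                   for s in stack.data.shape)
        sample = stack.data[background_box].astype(np.float64).ravel()
    else:
        raise ValueError("provide a stack or dark frames")
    med = np.median(sample)
    return float(1.4826 * np.median(np.abs(sample - med)))


# ---------------------------------------------------------------------------
# coherence-enhancing diffusion
# ---------------------------------------------------------------------------

def _ced_2d_batch(planes: np.ndarray, n_iter: int, dt: float, alpha: float,
                  sigma_grad: float, rho: float, coh_scale: float
                  ) -> np.ndarray:
    """Weickert-type coherence-enhancing diffusion on a batch of 2D planes.

    ``planes`` is (n, h, w); the diffusion acts in the (h, w) plane of every
    slice simultaneously.  The diffusion tensor aligns with the local
    structure-tensor orientation: diffusivity ``alpha`` across structures and
    ``alpha + (1-alpha) * exp(-coh_scale / coherence)`` along them.
    """
    u = planes.astype(np.float32, copy=True)
    scale = float(u.std()) or 1.0
    u /= scale
    smooth = lambda a, s: ndimage.gaussian_filter(a, (0.0, s, s))
    for _ in range(n_iter):
        us = smooth(u, sigma_grad)
        gy, gx = np.gradient(us, axis=(1, 2))
        j11 = smooth(gx * gx, rho)
        j12 = smooth(gx * gy, rho)
        j22 = smooth(gy * gy, rho)
        # eigen-decomposition of the 2x2 structure tensor
        tr2 = 0.5 * (j11 + j22)
        root = np.sqrt(np.maximum(0.25 * (j11 - j22) ** 2 + j12 ** 2, 0.0))
        coherence = (2.0 * root) ** 2          # (mu1 - mu2)^2
        lam2 = alpha + (1.0 - alpha) * np.exp(
            -coh_scale / np.maximum(coherence, 1e-12))
        theta = 0.5 * np.arctan2(2.0 * j12, j11 - j22)
        c, s = np.cos(theta), np.sin(theta)
        # D = alpha v1 v1^T + lam2 v2 v2^T, v1 = gradient direction (c, s)
        d11 = alpha * c * c + lam2 * s * s
        d12 = (alpha - lam2) * c * s
        d22 = alpha * s * s + lam2 * c * c
        # staggered forward/backward differences for the diagonal flux terms
        # (a central-difference divergence would leave the Nyquist noise
        # mode undamped); mixed terms use central differences
        ux_f = np.roll(u, -1, axis=2) - u
        uy_f = np.roll(u, -1, axis=1) - u
        ux_f[:, :, -1] = 0.0
        uy_f[:, -1, :] = 0.0
        uy_c, ux_c = np.gradient(u, axis=(1, 2))
        jx = d11 * ux_f + d12 * uy_c
        jy = d22 * uy_f + d12 * ux_c
        jx[:, :, -1] = 0.0
        jy[:, -1, :] = 0.0
        # wrapped rolls read the zeroed edge fluxes, giving no-flux borders
        div = (jx - np.roll(jx, 1, axis=2)) + (jy - np.roll(jy, 1, axis=1))
        u += dt * div
    return u * scale


def enhance_tubular(stack: ImageStack3D, n_iter: int = 18, dt: float = 0.2,
                    alpha: float = 0.25, sigma_grad: float = 1.0,
                    rho: float = 4.0, coh_scale: float = 1e-2
                    ) -> ImageStack3D:
    """Emphasize elongated structures before binarization.

    2D coherence-enhancing diffusion is run plane-wise along each of the
    three axes and the three filtered volumes averaged voxel-wise; averaging
    makes the result independent of axis ordering.
    """
    data = stack.data
    if not np.all(np.isfinite(data)):
        raise ValueError("stack contains non-finite voxels")
    if min(data.shape) < 3:
        raise ValueError("need at least 3 planes per axis")
    acc = np.zeros_like(data, dtype=np.float32)
    for axis in range(3):
        planes = np.moveaxis(data, axis, 0)
        out = _ced_2d_batch(planes, n_iter, dt, alpha, sigma_grad, rho,
                            coh_scale)
        acc += np.moveaxis(out, 0, axis)
    acc /= 3.0
    if stack.calibration is not None:
        # diffusion can overshoot marginally below zero at sharp edges;
        # photon-count stacks stay non-negative by contract
        np.clip(acc, 0.0, None, out=acc)
    return ImageStack3D(acc, stack.spacing, calibration=stack.calibration)


def binarize_hysteresis(stack: ImageStack3D, noise_sigma: float,
                        low_k: float = 1.0, high_k: float = 3.0,
                        background: float = 0.0) -> np.ndarray:
    """Hysteresis binarization at ``low_k`` / ``high_k`` noise sigmas.

    Voxels >= ``background + high_k * sigma`` seed regions that are grown
    through all 26-connected voxels >= ``background + low_k * sigma``.
    ``background`` is the residual baseline of the calibrated stack (ideally
    zero; in practice the small x-intercept bias of the photon-transfer
    calibration), so the thresholds stay referenced to true background.
    """
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive")
    data = stack.data
    low = data >= background + low_k * noise_sigma
    high = data >= background + high_k * noise_sigma
    if not high.any():
        return np.zeros_like(low)
    labels, _ = ndimage.label(low, structure=FULL_CONNECTIVITY)
    seeded = np.unique(labels[high])
    keep = np.zeros(labels.max() + 1, dtype=bool)
    keep[seeded] = True
    keep[0] = False
    return keep[labels]


def prune_small(mask: np.ndarray, min_voxels: int = 100) -> np.ndarray:
    """Remove 26-connected components with fewer than ``min_voxels`` voxels.

    Components of exactly ``min_voxels`` are kept ("less than" is strict).
    Idempotent by construction.
    """
    labels, n = ndimage.label(mask, structure=FULL_CONNECTIVITY)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]
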