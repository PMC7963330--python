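"""Calibration, noise estimation, diffusion filtering and binarization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from astroglia_age import imaging_core as ic
from astroglia_age.containers import ImageStack3D


def _poisson_stack(gain, offset, seed, read=0.0, shape=(24, 96, 96)):
    """Detector model over a terraced photon-rate landscape (10..200):
    flat plateaus give honest variance-mean patches, terrace edges exercise
    the outlier handling."""
    rng = np.random.default_rng(seed)
    z, y, x = np.indices(shape, dtype=float)
    lam = 10.0 + 20.0 * np.floor(10.0 * (x + y + 4 * z)
                                 / (shape[1] + shape[2] + 4 * shape[0]))
    data = gain * rng.poisson(lam) + offset
    if read:
        data = data + rng.normal(0, read, shape)
    return ImageStack3D(data.astype(np.float32), (1.0, 0.2, 0.2))


def test_calibration_recovers_gain_offset():
    """Planted gain 2 / offset 100 from 500 patches, via the variance-mean
    line; cross-checked against an independent straight-line fit on
    noise-free per-patch statistics."""
    stack = _poisson_stack(2.0, 100.0, seed=0)
    cal = ic.estimate_pmt_gain_offset(stack, n_patches=500, seed=1)
    assert cal.gain == pytest.approx(2.0, rel=0.05)
    assert cal.offset == pytest.approx(100.0, abs=10.0)
    # independent oracle: regress true variance (gain^2 lam) on true mean
    # (gain lam + offset) -> slope gain, x-intercept offset, exactly
    lam = np.linspace(10, 200, 50)
    slope, intercept = np.polyfit(2.0 * lam + 100.0, 4.0 * lam, 1)
    assert slope == pytest.approx(2.0)
    assert -intercept / slope == pytest.approx(100.0)


def test_calibration_pure_poisson_unit_gain():
    stack = _poisson_stack(1.0, 0.0, seed=2)
    cal = ic.estimate_pmt_gain_offset(stack, n_patches=400, seed=0)
    assert cal.gain == pytest.approx(1.0, rel=0.1)
    assert abs(cal.offset) < 8.0


def test_calibration_median_gain_over_replicates():
    """Median recovered gain within 5% over seeded replicates."""
    gains = []
    for s in range(10):
        stack = _poisson_stack(2.0, 100.0, seed=100 + s)
        gains.append(ic.estimate_pmt_gain_offset(stack, 400, seed=s).gain)
    assert np.median(gains) == pytest.approx(2.0, rel=0.05)


def test_calibration_errors():
    const = ImageStack3D(np.full((10, 20, 20), 7.0, np.float32))
    with pytest.raises(ic.CalibrationError):
        ic.estimate_pmt_gain_offset(const, 100)
    stack = _poisson_stack(2.0, 100.0, seed=0)
    with pytest.raises(ValueError, match="10 patches"):
        ic.estimate_pmt_gain_offset(stack, n_patches=5)
    small = ImageStack3D(np.zeros((2, 3, 3), np.float32))
    with pytest.raises(ValueError, match="fit"):
        ic.estimate_pmt_gain_offset(small, 100, patch_size=(1, 7, 7))


def test_to_photon_counts_linear_points():
    cal = ic.PmtCalibration(gain=2.0, offset=100.0, slope_se=0, intercept_se=0,
                            n_patches=10)
    stack = ImageStack3D(np.array([[[100.0, 106.0, 90.0]]], dtype=np.float32))
    out = ic.to_photon_counts(stack, cal)
    assert out.data[0, 0, 0] == 0.0          # value = offset
    assert out.data[0, 0, 1] == 3.0          # offset + 3*gain
    assert out.data[0, 0, 2] == 0.0          # clipped at zero
    assert out.calibration == (2.0, 100.0)


def test_photon_roundtrip_with_exact_calibration():
    """With the planted gain/offset, conversion recovers the photon image
    up to shot noise."""
    rng = np.random.default_rng(3)
    lam = np.full((8, 40, 40), 50.0)
    counts = rng.poisson(lam)
    stack = ImageStack3D((2.0 * counts + 100.0).astype(np.float32))
    cal = ic.PmtCalibration(2.0, 100.0, 0, 0, 1)
    out = ic.to_photon_counts(stack, cal)
    assert np.array_equal(out.data, counts)


def test_noise_sigma_mad_oracle():
    rng = np.random.default_rng(0)
    stack = ImageStack3D(rng.normal(0, 5.0, (20, 60, 60)).astype(np.float32))
    est = ic.estimate_noise_sigma(stack)
    # MAD x 1.4826 oracle on the same corner box
    box = stack.data[:5, :15, :15]
    oracle = 1.4826 * np.median(np.abs(box - np.median(box)))
    assert est == pytest.approx(oracle)
    assert est == pytest.approx(5.0, rel=0.05)


def test_noise_sigma_prefers_dark_frames():
    stack = ImageStack3D(np.random.default_rng(0).normal(0, 50.0, (8, 20, 20))
                         .astype(np.float32))
    dark = np.random.default_rng(1).normal(0, 3.0, (30, 20, 20))
    assert ic.estimate_noise_sigma(stack, dark_frames=dark) == \
        pytest.approx(3.0, rel=0.1)
    assert ic.estimate_noise_sigma(ImageStack3D(np.zeros((5, 8, 8)))) == 0.0


def test_enhance_constant_stack_fixed_point():
    stack = ImageStack3D(np.full((6, 20, 20), 3.0, dtype=np.float32))
    out = ic.enhance_tubular(stack, n_iter=5)
    assert np.allclose(out.data, 3.0, atol=1e-4)


def test_enhance_rejects_nonfinite_and_thin():
    bad = ImageStack3D(np.full((6, 10, 10), np.nan, dtype=np.float32))
    with pytest.raises(ValueError, match="finite"):
        ic.enhance_tubular(bad)
    with pytest.raises(ValueError, match="3 planes"):
        ic.enhance_tubular(ImageStack3D(np.zeros((2, 10, 10), np.float32)))


def _tube_stack(seed, noise=5.0):
    rng = np.random.default_rng(seed)
    vol = np.zeros((16, 60, 60), dtype=np.float32)
    vol[8, 28:32, 5:55] = 40.0                    # straight lateral tube
    vol = ndimage.gaussian_filter(vol, (1.0, 1.2, 1.2))
    noisy = vol + rng.normal(0, noise, vol.shape)
    return ImageStack3D(noisy.astype(np.float32)), vol > 8.0


def test_enhance_improves_tube_cnr():
    stack, tube = _tube_stack(0)
    out = ic.enhance_tubular(stack)

    def cnr(img):
        bg = img[:4, :20, :20]
        return (img[tube].mean() - bg.mean()) / bg.std()

    assert cnr(out.data) > 1.5 * cnr(stack.data)


def test_enhance_axis_order_invariance():
    """Averaging the three plane-wise passes makes the filter commute with
    axis transposition."""
    stack, _ = _tube_stack(1)
    out = ic.enhance_tubular(stack, n_iter=4).data
    perm = (1, 2, 0)
    transposed = ImageStack3D(np.ascontiguousarray(
        stack.data.transpose(perm)))
    out_t = ic.enhance_tubular(transposed, n_iter=4).data
    inv = np.argsort(perm)
    assert np.allclose(out, out_t.transpose(tuple(inv)), atol=1e-3)


def _hysteresis_oracle(data, low, high):
    """Flood fill from every >=high voxel through >=low voxels (26-conn)."""
    from collections import deque
    low_mask = data >= low
    out = np.zeros_like(low_mask)
    seeds = np.argwhere(data >= high)
    q = deque(map(tuple, seeds))
    for s in q:
        out[s] = True
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
            for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offs:
            p = (z + dz, y + dy, x + dx)
            if all(0 <= p[i] < data.shape[i] for i in range(3)) \
                    and low_mask[p] and not out[p]:
                out[p] = True
                q.append(p)
    return out


def test_hysteresis_matches_flood_fill_oracle(rng):
    data = np.zeros((10, 16, 16), dtype=np.float32)
    data[5, 8, 8] = 5.0
    data[5, 8:11, 9] = 2.0          # skirt grown from the 5-sigma seed
    data[2, 2, 2] = 2.0             # isolated 2-sigma voxel: no seed
    # sprinkle sub-threshold clutter that must stay excluded
    data += np.abs(rng.normal(0, 0.3, data.shape)).astype(np.float32)
    mask = ic.binarize_hysteresis(ImageStack3D(data), 1.0)
    oracle = _hysteresis_oracle(data, 1.0, 3.0)
    assert np.array_equal(mask, oracle)
    assert mask[5, 8, 8] and mask[5, 10, 9]
    assert not mask[2, 2, 2]


def test_hysteresis_background_reference():
    data = np.full((6, 8, 8), 10.0, dtype=np.float32)
    data[3, 4, 4] = 20.0
    mask = ic.binarize_hysteresis(ImageStack3D(data), 1.0, background=10.0)
    assert mask.sum() == 1
    with pytest.raises(ValueError):
        ic.binarize_hysteresis(ImageStack3D(data), 0.0)


def test_hysteresis_all_background_empty():
    data = np.zeros((5, 6, 6), dtype=np.float32)
    assert not ic.binarize_hysteresis(ImageStack3D(data), 1.0).any()


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10 ** 6), st.integers(0, 5 * 6 * 6 - 1))
def test_hysteresis_monotone_in_input(seed, idx):
    """Raising any single voxel never removes mask voxels."""
    r = np.random.default_rng(seed)
    data = r.normal(0, 1, (5, 6, 6)).astype(np.float32)
    base = ic.binarize_hysteresis(ImageStack3D(data), 1.0)
    bumped = data.copy()
    bumped.reshape(-1)[idx] += r.uniform(0.5, 5.0)
    new = ic.binarize_hysteresis(ImageStack3D(bumped), 1.0)
    assert np.all(new[base])


def test_prune_small_boundary_and_idempotence():
    # a 99-voxel and a 100-voxel component, on well-separated z-planes
    mask2 = np.zeros((10, 30, 30), dtype=bool)
    mask2[0].reshape(-1)[:99] = True               # 99 voxels, one component
    mask2[5].reshape(-1)[:100] = True              # 100 voxels
    out = ic.prune_small(mask2, min_voxels=100)
    assert out[5].sum() == 100 and out[0].sum() == 0
    assert np.array_equal(ic.prune_small(out, 100), out)
    empty = np.zeros((3, 3, 3), dtype=bool)
    assert not ic.prune_small(empty).any()
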