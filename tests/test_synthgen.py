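"""Generator contracts: determinism, ground-truth echo, planted physics."""

import dataclasses

import numpy as np
import pytest

from astroglia_age import synthgen
from astroglia_age.presets import (CA_MOVIE_PRESETS, COUPLING_PRESETS,
                                   EPHYS_PRESETS, LTP_PRESETS, SR101_PRESETS,
                                   AstrocytePreset, CouplingPreset,
                                   PresetError, Sr101Preset)


def _astro(**kw):
    base = dict(n_primary=7, branch_length_mean=6.0, branch_length_sd=1.2,
                length_draw_mean=None, branch_order_depth=2,
                bifurcation_prob=0.3, domain_radius=12.0, domain_z_radius=5.0,
                soma_radius=3.5, leaflet_vf=0.045, haze_sleeve_radius=3.0,
                shape=(14, 144, 144))
    base.update(kw)
    return AstrocytePreset(**base)


# ---------------------------------------------------------------------------
# determinism: every generator is a pure function of (preset, seed)
# ---------------------------------------------------------------------------

def test_astrocyte_stack_deterministic():
    p = _astro()
    a, gta = synthgen.gen_astrocyte_stack(p, 3, domain_truth=False)
    b, gtb = synthgen.gen_astrocyte_stack(p, 3, domain_truth=False)
    assert np.array_equal(a.data, b.data)
    assert gta["mean_segment_length"] == gtb["mean_segment_length"]
    c, _ = synthgen.gen_astrocyte_stack(p, 4, domain_truth=False)
    assert not np.array_equal(a.data, c.data)


@pytest.mark.parametrize("gen,args", [
    (synthgen.gen_sr101_field, (SR101_PRESETS["adult"],)),
    (synthgen.gen_coupling_image, (COUPLING_PRESETS["old"],)),
])
def test_2d_generators_deterministic(gen, args):
    a, _ = gen(*args, 7)
    b, _ = gen(*args, 7)
    assert np.array_equal(a.data, b.data)


def test_ca_movie_deterministic():
    p = dataclasses.replace(CA_MOVIE_PRESETS["adult"], fov_px=(30, 30),
                            n_frames=200, n_events=5)
    a, _ = synthgen.gen_ca_movie(p, 9)
    b, _ = synthgen.gen_ca_movie(p, 9)
    assert np.array_equal(a.frames, b.frames)
    assert np.array_equal(a.dark_frames, b.dark_frames)


def test_trace_generators_deterministic():
    p = EPHYS_PRESETS["adult"]
    a, _ = synthgen.gen_vclamp_sweeps(p, [-5.0], 5)
    b, _ = synthgen.gen_vclamp_sweeps(p, [-5.0], 5)
    assert np.array_equal(a.sweeps["dv-5"], b.sweeps["dv-5"])
    c, _ = synthgen.gen_synaptic_sweeps(p, 5)
    d, _ = synthgen.gen_synaptic_sweeps(p, 5)
    assert all(np.array_equal(c.sweeps[k], d.sweeps[k]) for k in c.sweeps)
    e, _ = synthgen.gen_fepsp_timecourse(LTP_PRESETS["adult"], 5)
    f, _ = synthgen.gen_fepsp_timecourse(LTP_PRESETS["adult"], 5)
    assert np.array_equal(e.amplitude, f.amplitude)


# ---------------------------------------------------------------------------
# astrocyte stack ground truth
# ---------------------------------------------------------------------------

def test_stack_gt_echoes_primary_count():
    _, gt = synthgen.gen_astrocyte_stack(_astro(n_primary=7), 0,
                                         domain_truth=False)
    assert gt["n_primary"] == 7


def test_planted_haze_ratio_in_noiseless_image():
    """The noiseless soma-plane annulus (branch leakage excluded) must read
    leaflet_vf of the soma plateau -- the generator's core calibration."""
    p = _astro(leaflet_vf=0.045, domain_radius=16.0, haze_sleeve_radius=6.0,
               branch_order_depth=3, bifurcation_prob=0.6,
               shape=(14, 200, 200))
    vals = []
    for s in (1, 2, 3):
        _, gt, lam = synthgen.gen_astrocyte_stack(p, s, return_noiseless=True,
                                                  domain_truth=False)
        zc = gt["soma_plane"]
        ny, nx = lam.shape[1:]
        yy, xx = np.mgrid[0:ny, 0:nx]
        r = np.hypot((yy - (ny - 1) / 2) * 0.2, (xx - (nx - 1) / 2) * 0.2)
        ring = (r >= p.soma_radius + 10) & (r <= p.soma_radius + 20)
        # exclude bright branch cores; the surviving ring carries haze only
        peak = p.photon_rate_soma + p.background_rate
        ok = ring & (lam[zc] <= 0.25 * peak)
        vals.append(lam[zc][ok].mean() / peak)
    assert np.mean(vals) == pytest.approx(0.045, rel=0.1)


def test_stack_invariants_and_errors():
    with pytest.raises(PresetError, match="domain_radius"):
        _astro(domain_radius=20.0, shape=(14, 100, 100))
    with pytest.raises(PresetError):
        _astro(leaflet_vf=0.0)
    with pytest.raises(PresetError):
        _astro(n_primary=0)


def test_segment_lengths_recorded_and_positive():
    _, gt = synthgen.gen_astrocyte_stack(_astro(), 2, domain_truth=False)
    lengths = np.array(gt["segment_lengths"])
    assert lengths.size >= 7
    assert np.all(lengths >= 1.5)
    assert gt["mean_segment_length"] == pytest.approx(lengths.mean())


# ---------------------------------------------------------------------------
# SR101 / coupling
# ---------------------------------------------------------------------------

def test_sr101_zero_density_blank():
    p = dataclasses.replace(SR101_PRESETS["adult"], density=0.0)
    img, gt = synthgen.gen_sr101_field(p, 0)
    assert gt["n_somata"] == 0
    assert img.data.std() < 2 * p.noise_sigma


def test_sr101_poisson_rounded_count():
    """density 0.59 over a 300x300 µm² field: expected count 5.31, the
    realized count is its Poisson draw and is echoed exactly."""
    counts = []
    for s in range(40):
        _, gt = synthgen.gen_sr101_field(SR101_PRESETS["adult"], s)
        assert gt["n_somata"] == len(gt["coords_um"])
        assert gt["expected_count"] == pytest.approx(5.31)
        counts.append(gt["n_somata"])
    assert np.mean(counts) == pytest.approx(5.31, rel=0.25)


def test_sr101_infeasible_spacing_errors():
    p = dataclasses.replace(SR101_PRESETS["adult"], density=50.0,
                            min_spacing=40.0)
    with pytest.raises(ValueError, match="spacing"):
        synthgen.gen_sr101_field(p, 0)


def test_coupling_counts_and_errors():
    img, gt = synthgen.gen_coupling_image(
        dataclasses.replace(COUPLING_PRESETS["old"], n_coupled=0), 0)
    assert gt["n_coupled"] == 0
    img3, gt3 = synthgen.gen_coupling_image(COUPLING_PRESETS["old"], 0)
    assert gt3["n_coupled"] == 3 and len(gt3["coupled_um"]) == 3
    with pytest.raises(PresetError):
        CouplingPreset(n_coupled=-1)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def test_vclamp_noiseless_plateau_follows_ohm(quiet_ephys_preset):
    sweeps, gt = synthgen.gen_vclamp_sweeps(quiet_ephys_preset, [-5.0, 20.0], 0)
    t = sweeps.time
    mid = (t >= 0.3) & (t < 0.5)
    assert sweeps.sweeps["dv-5"][mid].mean() == pytest.approx(-232.558, abs=1e-3)
    assert sweeps.sweeps["dv+20"][mid].mean() == pytest.approx(930.23, abs=0.01)
    assert gt["r_input"] == 21.5


def test_infinite_r_input_rejected():
    with pytest.raises(PresetError):
        dataclasses.replace(EPHYS_PRESETS["adult"], r_input=float("inf"))


def test_synaptic_amp_ratio_planted():
    p = dataclasses.replace(EPHYS_PRESETS["adult"], ik_amp_1=40.0,
                            ik_amp_5=40.0)
    _, gt = synthgen.gen_synaptic_sweeps(p, 0)
    assert gt["amp_ratio_ik"] == 1.0


def test_fepsp_flat_when_factor_one():
    p = dataclasses.replace(LTP_PRESETS["adult"], potentiation_factor=1.0,
                            noise_cv=0.0, ptp_extra=0.0)
    tc, _ = synthgen.gen_fepsp_timecourse(p, 0)
    assert np.allclose(tc.amplitude, tc.amplitude[0])


def test_fepsp_noiseless_plateau_exact():
    p = dataclasses.replace(LTP_PRESETS["adult"], noise_cv=0.0)
    tc, gt = synthgen.gen_fepsp_timecourse(p, 0)
    plateau = tc.amplitude[(tc.t_min >= 50) & (tc.t_min <= 60)]
    assert np.allclose(plateau / p.baseline_amp, 1.53, atol=1e-6)
    assert gt["potentiation_factor"] == 1.53
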