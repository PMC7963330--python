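"""Voltage-clamp and fEPSP analytics against closed forms and construction."""

import dataclasses

import numpy as np
import pytest

from astroglia_age import ephys, synthgen
from astroglia_age.containers import FepspTimecourse
from astroglia_age.presets import EPHYS_PRESETS, LTP_PRESETS, LtpPreset


def test_input_resistance_ohms_law(quiet_ephys_preset):
    """-5 mV / 21.5 MOhm gives -232.6 pA; the division must invert exactly."""
    sweeps, _ = synthgen.gen_vclamp_sweeps(quiet_ephys_preset, [-5.0], 0)
    di = sweeps.sweeps["dv-5"]
    plateau = di[(sweeps.time >= 0.5) & (sweeps.time < 0.6)].mean()
    assert plateau == pytest.approx(-232.558, abs=0.01)
    assert ephys.input_resistance(sweeps) == pytest.approx(21.5, rel=1e-6)


def test_input_resistance_noisy_unbiased():
    """<2 % error at preset noise, median over 50 seeds."""
    preset = EPHYS_PRESETS["adult"]
    vals = []
    for s in range(50):
        sweeps, _ = synthgen.gen_vclamp_sweeps(preset, [-5.0], s)
        vals.append(ephys.input_resistance(sweeps))
    assert np.median(vals) == pytest.approx(21.5, rel=0.02)


def test_input_resistance_open_circuit(quiet_ephys_preset):
    sweeps, _ = synthgen.gen_vclamp_sweeps(quiet_ephys_preset, [-5.0], 0)
    sweeps.sweeps["dv-5"][:] = 0.0
    with pytest.raises(ValueError, match="noise floor"):
        ephys.input_resistance(sweeps)


def test_iv_curve_linear():
    preset = EPHYS_PRESETS["adult"]
    sweeps, _ = synthgen.gen_vclamp_sweeps(preset, synthgen.iv_step_protocol(), 1)
    iv = ephys.build_iv(sweeps)
    assert iv.dv.size == 12              # -140..+80 mV in 20-mV steps
    assert iv.r_squared > 0.999
    assert iv.slope == pytest.approx(1000.0 / preset.r_input, rel=0.01)


def test_iv_missing_step_listed():
    preset = EPHYS_PRESETS["adult"]
    sweeps, _ = synthgen.gen_vclamp_sweeps(preset, [20.0, 40.0], 1)
    sweeps.meta["protocol_mv"] = [20.0, 40.0, 60.0]
    with pytest.raises(ValueError, match="60"):
        ephys.build_iv(sweeps)


def test_isolate_fifth_recovers_planted_component(quiet_ephys_preset):
    """Noiseless (5-stim) - (4-stim) equals the planted 5th component."""
    p = quiet_ephys_preset
    sweeps, _ = synthgen.gen_synaptic_sweeps(p, 0)
    t = sweeps.time
    fifth = ephys.isolate_fifth(sweeps.sweeps["stim5"], sweeps.sweeps["stim4"])
    t5 = sweeps.stim_times["stim5"][-1]
    expected = (synthgen.ik_waveform(t - t5, p.ik_amp_5, p.ik_tau_5,
                                     p.ik_rise_tau)
                + synthgen.glut_waveform(t - t5, p.iglut_amp_5, p.iglut_tau_5,
                                         p.iglut_rise_tau))
    assert np.allclose(fifth, expected, atol=1e-4)


def test_isolate_fifth_shape_mismatch():
    with pytest.raises(ValueError):
        ephys.isolate_fifth(np.zeros(10), np.zeros(11))


def test_ik_amplitude_at_200ms(quiet_ephys_preset):
    """The I_K readout 200 ms post-stimulus returns the planted amplitude:
    the transporter current (tau ~10 ms) has fully decayed there."""
    p = quiet_ephys_preset
    sweeps, _ = synthgen.gen_synaptic_sweeps(p, 0)
    amp = ephys.ik_amplitude(sweeps.time, sweeps.sweeps["stim1"],
                             float(sweeps.stim_times["stim1"][0]))
    assert amp == pytest.approx(p.ik_amp_1, rel=0.01)
    flat = np.zeros_like(sweeps.time)
    assert ephys.ik_amplitude(sweeps.time, flat, 0.2) == 0.0


def test_fit_monoexp_closed_form():
    t = np.arange(0, 1.0, 1e-3)
    trace = 100.0 * np.exp(-t / 0.150) + 7.0
    fit = ephys.fit_monoexp(t, trace, fit_start=0.0)
    assert fit.tau == pytest.approx(150.0, rel=1e-6)
    assert fit.amplitude == pytest.approx(100.0, rel=1e-5)
    assert fit.offset == pytest.approx(7.0, abs=1e-3)


def test_fit_monoexp_noisy_tau_recovery(rng):
    t = np.arange(0, 1.2, 2e-4)
    taus = []
    for s in range(20):
        r = np.random.default_rng(s)
        trace = -80 * np.exp(-t / 0.2) + r.normal(0, 4.0, t.size)
        taus.append(ephys.fit_monoexp(t, trace, 0.0).tau)
    assert np.median(taus) == pytest.approx(200.0, rel=0.1)


def test_fit_monoexp_rejects_rising_trace():
    t = np.arange(0, 1.0, 1e-3)
    with pytest.raises(ephys.FitError):
        ephys.fit_monoexp(t, 50.0 * t, fit_start=0.0)


def test_fit_monoexp_rejects_flat_trace():
    t = np.arange(0, 1.0, 1e-3)
    with pytest.raises(ephys.FitError):
        ephys.fit_monoexp(t, np.full_like(t, 3.0), fit_start=0.0)


def test_isolate_iglut_exact_scale():
    """trace = glut + 0.7 x template -> recovers glut exactly, scale 0.7."""
    t = np.arange(0, 1.5, 2e-4)
    glut = synthgen.glut_waveform(t - 0.2, 200.0, 10.0, 1.0)
    template = synthgen.ik_waveform(t - 0.2, 50.0, 200.0, 30.0)
    trace = glut + 0.7 * template
    out, scale = ephys.isolate_iglut(trace, template, t, tail_start=0.5)
    assert scale == pytest.approx(0.7, rel=1e-6)
    assert np.allclose(out, glut, atol=1e-8)
    # template-free trace is left unchanged
    out2, scale2 = ephys.isolate_iglut(glut, template, t, tail_start=0.5)
    assert abs(scale2) < 1e-6
    # tail is annihilated by construction (least-squares residual property)
    assert np.abs(out[t >= 0.5]).max() < 1e-8


def test_isolate_iglut_dead_template():
    t = np.arange(0, 1.0, 1e-3)
    with pytest.raises(ValueError, match="energy"):
        ephys.isolate_iglut(np.ones_like(t), np.zeros_like(t), t, 0.5)


def test_decomposition_recovers_planted_parameters(quiet_ephys_preset):
    p = quiet_ephys_preset
    sweeps, gt = synthgen.gen_synaptic_sweeps(p, 0)
    dec = ephys.decompose_currents(sweeps)
    assert dec.ik_amp_1 == pytest.approx(gt["ik_amp_1"], rel=0.02)
    assert dec.ik_tau_1 == pytest.approx(gt["ik_tau_1"], rel=0.03)
    assert dec.ik_tau_5 == pytest.approx(gt["ik_tau_5"], rel=0.03)
    assert dec.iglut_amp_1 == pytest.approx(gt["iglut_amp_1"], rel=0.05)
    ratios = ephys.decomposition_ratios(dec)
    assert ratios["ik_tau_5_over_1"] == pytest.approx(gt["tau_ratio_ik"],
                                                      rel=0.05)
    assert ratios["ik_tau_1_over_5"] == pytest.approx(
        1.0 / ratios["ik_tau_5_over_1"])


def test_decomposition_ratios_identity():
    dec = ephys.CurrentDecomposition(*([10.0] * 4 + [20.0] * 4))
    r = ephys.decomposition_ratios(dec)
    assert r["ik_amp_5_over_1"] == 1.0 and r["iglut_tau_5_over_1"] == 1.0


def test_ltp_magnitude_flat_and_planted():
    flat = LtpPreset(potentiation_factor=1.0, noise_cv=0.0, ptp_extra=0.0)
    tc, _ = synthgen.gen_fepsp_timecourse(flat, 0)
    assert ephys.ltp_magnitude(tc) == pytest.approx(100.0)
    planted = LtpPreset(potentiation_factor=1.53, noise_cv=0.0)
    tc2, _ = synthgen.gen_fepsp_timecourse(planted, 0)
    assert ephys.ltp_magnitude(tc2) == pytest.approx(153.0, abs=0.05)


def test_ltp_magnitude_noisy_within_2pct():
    vals = [ephys.ltp_magnitude(synthgen.gen_fepsp_timecourse(
        LTP_PRESETS["adult"], s)[0]) for s in range(20)]
    assert np.mean(vals) == pytest.approx(153.0, rel=0.02)


def test_ltp_requires_baseline_and_post_window():
    tc, _ = synthgen.gen_fepsp_timecourse(LTP_PRESETS["adult"], 0)
    with pytest.raises(ValueError, match="baseline"):
        ephys.ltp_magnitude(tc, baseline_window=(-5.0, 0.0))
    short = FepspTimecourse(t_min=tc.t_min[tc.t_min < 40],
                            amplitude=tc.amplitude[tc.t_min < 40])
    with pytest.raises(ValueError, match="post window"):
        ephys.ltp_magnitude(short)
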