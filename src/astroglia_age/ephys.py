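"""Voltage-clamp and field-potential analytics.

Covers the passive-membrane readouts (I-V curve, input resistance by Ohm's
law on a -5 mV test step), the decomposition of synaptically evoked
astrocytic currents into the fast glutamate-transporter component (I_GluT)
and the slow K+ uptake current (I_K), burst subtraction isolating the
response to the 5th stimulus, mono-exponential decay fits, and LTP magnitude
from fEPSP amplitude timecourses.

Sign convention: inward currents are negative; amplitudes reported by the
measurement functions are magnitudes of the deflection from baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .containers import FepspTimecourse, SweepSet


class FitError(RuntimeError):
    pass


@dataclass
class IvCurve:
    dv: np.ndarray          # mV, strictly increasing
    di: np.ndarray          # pA
    slope: float            # pA/mV (nS)
    r_squared: float

    def __post_init__(self):
        if self.dv.size != self.di.size:
            raise ValueError("dv / di length mismatch")
        if np.any(np.diff(self.dv) <= 0):
            raise ValueError("dv must be strictly increasing")


@dataclass
class ExpFit:
    amplitude: float        # pA (signed, at fit start)
    tau: float              # ms
    offset: float           # pA
    rmse: float


@dataclass
class CurrentDecomposition:
    """Amplitudes (pA) and decay constants (ms) of I_K and I_GluT for the
    single-stimulus response and the isolated 5th response."""

    ik_amp_1: float
    ik_amp_5: float
    ik_tau_1: float
    ik_tau_5: float
    iglut_amp_1: float
    iglut_amp_5: float
    iglut_tau_1: float
    iglut_tau_5: float


def _plateau_minus_baseline(t: np.ndarray, trace: np.ndarray, on: float,
                            off: float, plateau_win: float = 0.1,
                            baseline_win: float = 0.05) -> float:
    base = trace[(t >= on - baseline_win) & (t < on)].mean()
    plat = trace[(t >= off - plateau_win) & (t < off)].mean()
    return float(plat - base)


def build_iv(sweeps: SweepSet) -> IvCurve:
    """I-V relationship from voltage-step sweeps.

    ΔI is the plateau mean (last 100 ms of the 500-ms step) minus the
    pre-step baseline; the slope is the least-squares conductance and
    linearity is reported as R².
    """
    on = sweeps.meta.get("step_onset", 0.1)
    off = sweeps.meta.get("step_offset", 0.6)
    protocol = sweeps.meta.get("protocol_mv")
    if protocol is None:
        raise ValueError("sweep set lacks a step protocol annotation")
    missing = [dv for dv in protocol if f"dv{dv:+g}" not in sweeps.sweeps]
    if missing:
        raise ValueError(f"missing voltage steps: {missing}")
    dv = np.array(sorted(protocol), dtype=float)
    di = np.array([_plateau_minus_baseline(sweeps.time,
                                           sweeps.sweeps[f"dv{v:+g}"], on, off)
                   for v in dv])
    slope, intercept = np.polyfit(dv, di, 1)
    pred = slope * dv + intercept
    ss_res = float(((di - pred) ** 2).sum())
    ss_tot = float(((di - di.mean()) ** 2).sum()) or 1e-30
    return IvCurve(dv=dv, di=di, slope=float(slope),
                   r_squared=1.0 - ss_res / ss_tot)


def input_resistance(sweeps: SweepSet, dv: float = -5.0,
                     noise_floor: float = 1.0) -> float:
    """Input resistance (MOhm) by Ohm's law: the -5 mV test step divided by
    its plateau-minus-baseline current response."""
    key = f"dv{dv:+g}"
    if key not in sweeps.sweeps:
        raise ValueError(f"no sweep for test step {dv} mV")
    on = sweeps.meta.get("step_onset", 0.1)
    off = sweeps.meta.get("step_offset", 0.6)
    di = _plateau_minus_baseline(sweeps.time, sweeps.sweeps[key], on, off)
    if abs(di) < noise_floor:
        raise ValueError("current response below noise floor (open circuit?)")
    return 1000.0 * dv / di        # mV / pA -> GOhm*1e3 = MOhm


def isolate_fifth(resp5: np.ndarray, resp4: np.ndarray) -> np.ndarray:
    """Response to the 5th stimulus: pointwise (5-stim) - (4-stim) burst
    subtraction of aligned, baseline-subtracted traces."""
    if resp5.shape != resp4.shape:
        raise ValueError("traces must be equally long and aligned")
    return resp5 - resp4


def ik_amplitude(t: np.ndarray, trace: np.ndarray, last_stim: float,
                 window: float = 0.004, baseline_until: float = None) -> float:
    """|I_K| amplitude: the trace 200 ms after the last stimulus (mean over
    a short window centred there), baseline-subtracted.

    At +200 ms the fast transporter current has fully decayed, so the value
    isolates the slow K+ component even on the compound trace.
    """
    t200 = last_stim + 0.2
    if t200 > t[-1]:
        raise ValueError("trace ends before the +200 ms time point")
    sel = (t >= t200 - window / 2) & (t <= t200 + window / 2)
    base_end = last_stim if baseline_until is None else baseline_until
    base = trace[t < min(base_end, t[0] + 0.05)]
    base_val = base.mean() if base.size else 0.0
    return float(abs(trace[sel].mean() - base_val))


def fit_monoexp(t: np.ndarray, trace: np.ndarray, fit_start: float,
                fit_end: Optional[float] = None) -> ExpFit:
    """Least-squares fit of ``A * exp(-t/tau) + C`` from ``fit_start`` (s).

    ``tau`` is returned in ms.  Raises :class:`FitError` when the segment
    does not decay toward the offset or the optimizer fails.
    """
    sel = t >= fit_start
    if fit_end is not None:
        sel &= t <= fit_end
    ts = t[sel] - fit_start
    ys = trace[sel]
    if ts.size < 10:
        raise FitError("too few samples beyond fit_start")
    y0, y1 = ys[:ts.size // 10 + 1].mean(), ys[-ts.size // 10:].mean()
    if abs(ys - ys.mean()).max() < 1e-12:
        raise FitError("flat segment: nothing to fit")
    tau0 = max((ts[-1] - ts[0]) / 5.0, 1e-4)
    try:
        popt, _ = curve_fit(lambda x, a, tau, c: a * np.exp(-x / tau) + c,
                            ts, ys, p0=(y0 - y1, tau0, y1),
                            maxfev=20000)
    except RuntimeError as e:
        raise FitError(f"mono-exponential fit failed: {e}") from e
    a, tau, c = popt
    span = ts[-1] - ts[0]
    if tau <= 0 or tau > 5.0 * span:
        raise FitError(f"no decay resolved within the window "
                       f"(tau {tau * 1000:.3g} ms)")
    n4 = max(1, ts.size // 4)
    if abs(ys[-n4:].mean() - c) > 0.8 * abs(ys[:n4].mean() - c):
        raise FitError("segment does not decay toward its asymptote")
    resid = ys - (a * np.exp(-ts / tau) + c)
    return ExpFit(amplitude=float(a), tau=float(tau * 1000.0),
                  offset=float(c), rmse=float(np.sqrt((resid ** 2).mean())))


def isolate_iglut(trace: np.ndarray, residual_ik_template: np.ndarray,
                  t: np.ndarray, tail_start: float) -> tuple[np.ndarray, float]:
    """Subtract the scaled transporter-blocked residual I_K template.

    The template (recorded under TBOA) is least-squares matched to the trace
    over the tail window (``t >= tail_start``) where I_GluT has decayed;
    the scaled template is subtracted from the whole trace, leaving pure
    I_GluT.  Returns (I_GluT trace, scale factor).
    """
    sel = t >= tail_start
    x = residual_ik_template[sel]
    y = trace[sel]
    energy = float(x @ x)
    if energy < 1e-12:
        raise ValueError("template carries no energy in the tail window")
    scale = float(x @ y) / energy
    return trace - scale * residual_ik_template, scale


def decompose_currents(sweeps: SweepSet,
                       tail_offset: float = 0.1) -> CurrentDecomposition:
    """Full I_K / I_GluT decomposition of a 1/4/5-stimulus sweep family.

    For each of the single-stimulus response and the isolated 5th response:
    |I_K| is measured 200 ms after the relevant stimulus and its decay
    fitted mono-exponentially from there; the TBOA residual template is
    scaled to the tail and subtracted to isolate I_GluT, whose peak
    amplitude and decay are then measured on the early segment.
    """
    t = sweeps.time
    s1 = sweeps.sweeps["stim1"].astype(np.float64)
    s5th = isolate_fifth(sweeps.sweeps["stim5"].astype(np.float64),
                         sweeps.sweeps["stim4"].astype(np.float64))
    stim1 = float(sweeps.stim_times["stim1"][0])
    stim5 = float(sweeps.stim_times["stim5"][-1])
    tb1 = sweeps.sweeps["tboa1"].astype(np.float64)
    tb5th = isolate_fifth(sweeps.sweeps["tboa5"].astype(np.float64),
                          sweeps.sweeps["tboa4"].astype(np.float64))

    out = {}
    for tag, tr, tb, ts in (("1", s1, tb1, stim1), ("5", s5th, tb5th, stim5)):
        out[f"ik_amp_{tag}"] = ik_amplitude(t, tr, ts)
        fit = fit_monoexp(t, tr, fit_start=ts + 0.2)
        out[f"ik_tau_{tag}"] = fit.tau
        glut, _ = isolate_iglut(tr, tb, t, tail_start=stim5 + tail_offset)
        early = (t >= ts) & (t <= ts + 0.015)
        pk_idx = np.argmax(np.abs(glut[early]))
        pk_t = t[early][pk_idx]
        out[f"iglut_amp_{tag}"] = float(np.abs(glut[early]).max())
        gfit = fit_monoexp(t, glut, fit_start=pk_t,
                           fit_end=ts + 0.08)
        out[f"iglut_tau_{tag}"] = gfit.tau
    return CurrentDecomposition(**out)


def decomposition_ratios(dec: CurrentDecomposition) -> dict[str, float]:
    """Activity-dependence ratios, emitted in both orientations."""
    r = {
        "ik_amp_5_over_1": dec.ik_amp_5 / dec.ik_amp_1,
        "ik_tau_5_over_1": dec.ik_tau_5 / dec.ik_tau_1,
        "iglut_amp_5_over_1": dec.iglut_amp_5 / dec.iglut_amp_1,
        "iglut_tau_5_over_1": dec.iglut_tau_5 / dec.iglut_tau_1,
    }
    r.update({k.replace("5_over_1", "1_over_5"): 1.0 / v
              for k, v in list(r.items())})
    return r


def ltp_magnitude(tc: FepspTimecourse,
                  baseline_window: Optional[tuple[float, float]] = None,
                  post_window: tuple[float, float] = (50.0, 60.0),
                  min_baseline: float = 15.0,
                  stability_cv: float = 0.15) -> float:
    """LTP magnitude: mean fEPSP amplitude in ``post_window`` (min after
    HFS) as a percentage of the mean baseline amplitude.

    Requires at least ``min_baseline`` minutes of baseline whose coefficient
    of variation stays below ``stability_cv``.
    """
    t, a = tc.t_min, tc.amplitude
    if baseline_window is None:
        baseline_window = (float(t.min()), 0.0)
    bsel = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not bsel.any() or \
            (baseline_window[1] - baseline_window[0]) < min_baseline - 1e-6:
        raise ValueError(f"baseline shorter than {min_baseline} min")
    base = a[bsel]
    if base.std() / abs(base.mean()) > stability_cv:
        raise ValueError("baseline unstable")
    psel = (t >= post_window[0]) & (t <= post_window[1])
    if not psel.any():
        raise ValueError(f"no samples in post window {post_window}")
    return float(100.0 * a[psel].mean() / base.mean())
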