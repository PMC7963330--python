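"""Preset parameter sets for the synthetic data generators.

Each preset bundle describes one age group (young / adult / old) of
hippocampal CA1 *stratum radiatum* astrocytes.  The numeric defaults are the
published group means this package is benchmarked against: the generators
plant them as ground truth and the analysis stages must recover them.

Presets are plain frozen dataclasses so that a (preset, seed) pair fully
determines a generated dataset.  They can be serialized to / loaded from JSON
for use with the command-line interface.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


class PresetError(ValueError):
    """Raised when a preset violates one of its invariants."""


@dataclass(frozen=True)
class AstrocytePreset:
    """Geometry, optics and noise model of a dye-filled astrocyte z-stack.

    Spatial units are micrometres; intensities are detector units unless a
    field name says photons.  The voxel grid is (z, y, x) with ``spacing``
    (dz, dy, dx); the nominal acquisition geometry is 0.2 µm/px laterally and
    1 µm z-steps.

    Morphology fields
    -----------------
    n_primary:
        number of primary branches leaving the soma surface.
    branch_length_mean, branch_length_sd:
        mean / spread of planted branch & branchlet segment lengths (µm).
    length_draw_mean:
        raw mean of the segment-length draw before walks are truncated at
        the domain boundary; calibrated per preset so the realized mean of
        planted segment lengths equals ``branch_length_mean`` (``None``
        falls back to ``branch_length_mean``).
    branch_order_depth:
        maximum branching order (primary = 1).
    bifurcation_prob:
        probability that a finished segment bifurcates (vs terminates) while
        below ``branch_order_depth`` and inside the domain.
    domain_radius:
        lateral extent (µm) the branch tree may reach from the soma centre.
    domain_z_radius:
        axial extent of the tree (astrocytes in slices are imaged over a
        flattened z-range).
    soma_radius:
        soma sphere radius (µm).

    Leaflet haze
    ------------
    leaflet_vf:
        target volume fraction of optically unresolved processes, as a
        fraction of peak soma intensity (0-1).  The generator calibrates the
        haze brightness so the noiseless soma-plane annulus 10-20 µm outside
        the soma border averages exactly this value (branch cores excluded).
    haze_sleeve_radius:
        leaflets cluster around branches: haze fills a sleeve of this radius
        (µm) around every branch and the soma, with a soft edge.
    leaflet_blob_count, leaflet_blob_radius, leaflet_blob_z_sd,
    leaflet_blob_r_range:
        optional discrete leaflet clusters: soft spheres scattered in the
        lateral annulus ``r_range`` (µm from the soma centre), with axial
        positions drawn near the soma plane (sd ``leaflet_blob_z_sd`` µm).
        They model the patchy residual leaflet coverage of dystrophic cells,
        whose haze no longer forms a contiguous cloud.

    Detector model
    --------------
    photon_rate_soma:
        expected photons/voxel at the soma plateau.
    background_rate:
        uniform tissue background photon rate (autofluorescence / stray
        dye).  Its shot noise is what the 1x/3x-sigma binarization
        thresholds ride on, and its uniform level is part of the unresolved
        fluorescence the VF estimator measures (no background subtraction
        exists in the cross-section procedure).
    branch_intensity_frac:
        branch photon rate relative to soma (thin processes carry less dye
        per voxel column).
    pmt_gain, pmt_offset:
        detector units per photon and baseline offset.
    read_noise:
        Gaussian read noise sigma in detector units.
    psf_sigma_xy, psf_sigma_z:
        Gaussian approximation of the two-photon PSF (µm).
    """

    n_primary: int = 8
    branch_length_mean: float = 8.4
    branch_length_sd: float = 2.2
    length_draw_mean: Optional[float] = 9.95
    branch_order_depth: int = 5
    bifurcation_prob: float = 0.55
    walk_jitter: float = 0.28
    domain_radius: float = 26.0
    domain_z_radius: float = 9.0
    soma_radius: float = 4.0
    leaflet_vf: float = 0.045
    haze_sleeve_radius: float = 6.0
    haze_taper: float = 1.5
    leaflet_blob_count: int = 0
    leaflet_blob_radius: float = 2.6
    leaflet_blob_z_sd: float = 1.5
    leaflet_blob_r_range: tuple[float, float] = (8.0, 24.0)
    branch_radius: float = 0.7
    photon_rate_soma: float = 300.0
    branch_intensity_frac: float = 0.6
    background_rate: float = 4.0
    pmt_gain: float = 2.0
    pmt_offset: float = 100.0
    read_noise: float = 0.6
    psf_sigma_xy: float = 0.25
    psf_sigma_z: float = 1.0
    shape: tuple[int, int, int] = (24, 288, 288)
    spacing: tuple[float, float, float] = (1.0, 0.2, 0.2)

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise PresetError("n_primary must be >= 1")
        if not 0.0 < self.leaflet_vf < 1.0:
            raise PresetError("leaflet_vf must lie strictly between 0 and 1")
        if not self.domain_radius > self.soma_radius > 0.0:
            raise PresetError("require domain_radius > soma_radius > 0")
        if self.pmt_gain <= 0:
            raise PresetError("pmt_gain must be positive")
        if min(self.spacing) <= 0:
            raise PresetError("voxel spacing must be strictly positive")
        half_fov = 0.5 * min(self.shape[1] * self.spacing[1],
                             self.shape[2] * self.spacing[2])
        if self.domain_radius >= half_fov:
            raise PresetError(
                f"domain_radius={self.domain_radius} µm exceeds the half "
                f"field of view ({half_fov:.1f} µm); enlarge `shape` or "
                f"shrink `domain_radius`")


@dataclass(frozen=True)
class CaMoviePreset:
    """Planted-event model of an x-y-t Ca2+ recording (1 frame/s default).

    ``duration_dist`` / ``area_dist`` are (median, log-sd) of log-normal
    distributions; durations are rounded to whole frames and clipped to stay
    above the 4-s astrocyte filter, areas converted to whole-pixel counts.
    ``reuse_prob`` is the probability that an event re-initiates at a
    previously used initiation spot rather than a fresh one.
    """

    fov_px: tuple[int, int] = (60, 60)
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    n_frames: int = 600
    n_events: int = 33
    duration_median: float = 6.0
    duration_log_sd: float = 0.35
    area_median: float = 20.2
    area_log_sd: float = 0.40
    reuse_prob: float = 0.10
    amplitude_snr: float = 8.0
    baseline: float = 100.0
    noise_sigma: float = 10.0
    dark_offset: float = 20.0
    n_dark_frames: int = 30
    min_duration_s: float = 4.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise PresetError("frame_interval must be positive")
        if self.n_events < 0:
            raise PresetError("n_events must be >= 0")
        if self.noise_sigma < 0:
            raise PresetError("noise_sigma must be >= 0")
        min_frames = int(self.min_duration_s / self.frame_interval) + 1
        if self.n_events and round(self.duration_median / self.frame_interval) < min_frames:
            raise PresetError(
                "duration_median falls at or below the minimum-duration "
                "filter; planted events would be rejected by design")


@dataclass(frozen=True)
class EphysPreset:
    """Membrane and synaptic-current parameters of a voltage-clamped astrocyte.

    Amplitudes are positive magnitudes in pA (currents are emitted as inward,
    negative, deflections); `ik_amp_*` is the I_K level read 200 ms after the
    relevant stimulus, `*_tau_*` are mono-exponential decay constants in ms.
    ``residual_ik_scale`` is the fraction of I_K that survives transporter
    block (the TBOA template used to isolate I_GluT).
    """

    r_input: float = 21.5
    ik_amp_1: float = 50.0
    ik_amp_5: float = 52.5
    ik_tau_1: float = 200.0
    ik_tau_5: float = 162.0
    ik_rise_tau: float = 30.0
    iglut_amp_1: float = 200.0
    iglut_amp_5: float = 230.0
    iglut_tau_1: float = 10.0
    iglut_tau_5: float = 8.1
    iglut_rise_tau: float = 1.0
    residual_ik_scale: float = 0.2
    sampling_rate: float = 5000.0
    noise_sigma: float = 4.0
    cap_transient_amp: float = 400.0
    cap_transient_tau: float = 1.5

    def __post_init__(self) -> None:
        import math
        if self.r_input <= 0 or not math.isfinite(self.r_input):
            raise PresetError("r_input must be positive and finite")
        for name in ("ik_tau_1", "ik_tau_5", "iglut_tau_1", "iglut_tau_5"):
            if getattr(self, name) <= 0:
                raise PresetError(f"{name} must be positive")
        if self.sampling_rate <= 0:
            raise PresetError("sampling_rate must be positive")


@dataclass(frozen=True)
class LtpPreset:
    """fEPSP timecourse around high-frequency stimulation (HFS at t = 0)."""

    baseline_amp: float = 0.5           # mV
    potentiation_factor: float = 1.53   # post-plateau / baseline
    baseline_duration: float = 15.0     # min
    post_duration: float = 60.0         # min
    inter_stimulus: float = 20.0        # s
    noise_cv: float = 0.02              # multiplicative noise
    ptp_extra: float = 0.35             # extra post-tetanic potentiation at t=0
    ptp_tau: float = 4.0                # min, decay of the PTP overshoot

    def __post_init__(self) -> None:
        if self.potentiation_factor <= 0:
            raise PresetError("potentiation_factor must be positive")
        if self.post_duration < 60.0:
            raise PresetError("post_duration must cover at least 60 min")
        if self.inter_stimulus <= 0:
            raise PresetError("inter_stimulus must be positive")


@dataclass(frozen=True)
class Sr101Preset:
    """SR101 bulk-stained field of somata."""

    density: float = 0.59          # somata per 100x100 µm^2
    fov_um: tuple[float, float] = (300.0, 300.0)
    pixel_size: float = 1.0        # µm
    soma_sigma: float = 3.0        # µm, Gaussian soma profile
    soma_amp: float = 120.0
    background: float = 20.0
    noise_sigma: float = 6.0
    min_spacing: float = 15.0      # µm, Poisson-disc exclusion radius

    def __post_init__(self) -> None:
        if self.density < 0:
            raise PresetError("density must be >= 0")


@dataclass(frozen=True)
class CouplingPreset:
    """Dye-coupling image: one patched soma plus dimmer coupled neighbours."""

    n_coupled: int = 3
    fov_um: tuple[float, float] = (200.0, 200.0)
    pixel_size: float = 1.0
    soma_sigma: float = 3.0
    patched_amp: float = 255.0
    coupled_amp: float = 80.0
    background: float = 15.0
    noise_sigma: float = 5.0
    min_spacing: float = 18.0

    def __post_init__(self) -> None:
        if self.n_coupled < 0:
            raise PresetError("n_coupled must be >= 0")


# ---------------------------------------------------------------------------
# Built-in age-group presets.
#
# Group means published for CA1 str. radiatum astrocytes: primaries
# 7.2/8.2/7.5, mean branch length 6.3/8.4/5.4 µm, domain area
# 1959/2206/757 µm², VF 4.5/2.1 %, SR101 density 0.59/0.61, coupled cells
# 6.8/3.0, R_i 21.5/35.8 MOhm, I_K tau ratio 0.81/1.15, I_GluT tau ratio
# 0.81/1.11, Ca2+ event medians 6/7 s and 20.2/16.2 µm², LTP 153/128 %.
# Geometry values without a published counterpart (sleeve radii, bifurcation
# rates, z-extent) were fixed once by calibrating the noiseless planted
# footprint / annulus against the published domain area and VF.
# ---------------------------------------------------------------------------

ASTROCYTE_PRESETS: dict[str, AstrocytePreset] = {
    "young": AstrocytePreset(
        n_primary=7, branch_length_mean=6.3, branch_length_sd=1.8,
        bifurcation_prob=0.52, domain_radius=25.0, leaflet_vf=0.040,
        haze_sleeve_radius=5.5),
    # thinner tubes keep neighbouring branchlets optically separable, which
    # the branch-length recovery benchmark depends on
    "adult": AstrocytePreset(branch_radius=0.6),
    "old": AstrocytePreset(
        n_primary=7, branch_length_mean=5.4, branch_length_sd=1.6,
        length_draw_mean=5.9,
        branch_order_depth=4, bifurcation_prob=0.25, domain_radius=25.0,
        leaflet_vf=0.021, haze_sleeve_radius=0.0, haze_taper=0.4,
        leaflet_blob_count=26, leaflet_blob_radius=2.4,
        leaflet_blob_z_sd=0.8, leaflet_blob_r_range=(13.0, 23.5),
        shape=(24, 280, 280)),
}

CA_MOVIE_PRESETS: dict[str, CaMoviePreset] = {
    "adult": CaMoviePreset(),
    "old": CaMoviePreset(n_events=41, duration_median=7.0,
                         area_median=16.2, reuse_prob=0.5),
}

EPHYS_PRESETS: dict[str, EphysPreset] = {
    "adult": EphysPreset(),
    "old": EphysPreset(
        r_input=35.8,
        ik_amp_1=50.0, ik_amp_5=38.5, ik_tau_1=200.0, ik_tau_5=230.0,
        iglut_amp_1=160.0, iglut_amp_5=180.8,
        iglut_tau_1=10.0, iglut_tau_5=11.1),
}

LTP_PRESETS: dict[str, LtpPreset] = {
    "adult": LtpPreset(potentiation_factor=1.53),
    "old": LtpPreset(potentiation_factor=1.28),
    "adult_tboa": LtpPreset(potentiation_factor=1.29),
    "old_tboa": LtpPreset(potentiation_factor=1.24),
}

SR101_PRESETS: dict[str, Sr101Preset] = {
    "adult": Sr101Preset(density=0.59),
    "old": Sr101Preset(density=0.61),
}

COUPLING_PRESETS: dict[str, CouplingPreset] = {
    "adult": CouplingPreset(n_coupled=7),
    "old": CouplingPreset(n_coupled=3),
}

_REGISTRY = {
    "astrocyte": (AstrocytePreset, ASTROCYTE_PRESETS),
    "camovie": (CaMoviePreset, CA_MOVIE_PRESETS),
    "ephys": (EphysPreset, EPHYS_PRESETS),
    "ltp": (LtpPreset, LTP_PRESETS),
    "sr101": (Sr101Preset, SR101_PRESETS),
    "coupling": (CouplingPreset, COUPLING_PRESETS),
}


def get_preset(kind: str, group: str):
    """Return the built-in preset of the given kind for an age group."""
    try:
        _, table = _REGISTRY[kind]
    except KeyError:
        raise KeyError(f"unknown preset kind {kind!r}; "
                       f"choose from {sorted(_REGISTRY)}") from None
    try:
        return table[group]
    except KeyError:
        raise KeyError(f"no {kind!r} preset for group {group!r}; "
                       f"choose from {sorted(table)}") from None


def preset_to_json(preset, path: str | Path) -> None:
    d = dataclasses.asdict(preset)
    d["__kind__"] = next(k for k, (cls, _) in _REGISTRY.items()
                         if isinstance(preset, cls))
    Path(path).write_text(json.dumps(d, indent=2))


def preset_from_json(path: str | Path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("__kind__")
    cls, _ = _REGISTRY[kind]
    # JSON round-trips tuples as lists
    for f in dataclasses.fields(cls):
        if f.name in d and isinstance(d[f.name], list):
            d[f.name] = tuple(d[f.name])
    return cls(**d)
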