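"""Coupled acoustic + 4D-CT scenario generator with known ground truth.

Emulates the porcine surfactant-washout experiment: per subject, condition
(healthy baseline ``BLH`` vs lavage injury ``LAV``) and PEEP level
(0/5/10/15 cmH2O), the generator produces

* a 34-channel, 19.2 kHz thoracic sound recording: band-limited
  (75-2000 Hz) breath noise shaped by a flow envelope, a per-ROI common
  source for coherence structure, plus transient fine crackles — damped
  650 Hz sinusoids — emitted while atelectasis is recruiting and heard
  mostly by the dependent-row sensors;
* a matching HU voxel-field time series (one frame per 0.58 s) in which
  an atelectatic block in each gravity slab shrinks during inspiration
  with an exponential time constant of ~1.5 s and re-collapses during
  expiration;
* breath annotations and a ground-truth record (recruitment curves,
  crackle events, per-frame compartment volumes).

Default recruitment amplitudes per (condition, ROI, PEEP) follow the
published lavage-injury means (Δatelectasis decreasing with PEEP, largest
in the dependent zone); healthy-baseline amplitudes are zero.  Crackle
occurrence is an inhomogeneous Poisson process whose rate is proportional
to the instantaneous de-recruitment rate (clipped at zero), with a free
coupling coefficient in events per cm3 recruited.

Seeding: every random stream is derived from the scenario seed together
with the subject index, PEEP index and a purpose code — never from the
condition label — so that with crackle coupling disabled a BLH and a LAV
run of the same seed produce identical waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .acoustics import Recording
from .ctvol import HUVolumeSeries, partition_rois
from .geometry import (CENTRAL, DEPENDENT, NONDEPENDENT, ROIS, SensorMatrix,
                       build_default_matrix)

# published lavage-injury group means (cm3): within-breath Delta atelectasis
# and cycle-averaged atelectatic volume, per ROI and PEEP
LAV_DELTA_CM3 = {
    NONDEPENDENT: {0: 1.61, 5: 1.69, 10: 1.26, 15: 1.17},
    CENTRAL: {0: 7.63, 5: 6.98, 10: 3.81, 15: 3.31},
    DEPENDENT: {0: 28.27, 5: 23.93, 10: 14.70, 15: 7.34},
}
LAV_ATELECTASIS_CM3 = {
    NONDEPENDENT: {0: 9.82, 5: 8.74, 10: 7.96, 15: 8.11},
    CENTRAL: {0: 24.81, 5: 16.92, 10: 15.43, 15: 15.63},
    DEPENDENT: {0: 38.32, 5: 23.64, 10: 16.40, 15: 12.59},
}
# healthy lungs: a small static atelectatic rim, no cyclic component
BLH_ATELECTASIS_CM3 = {NONDEPENDENT: 1.0, CENTRAL: 2.0, DEPENDENT: 5.0}

# purpose codes for seed derivation (condition-independent)
_STREAM_SUBJECT = 901
_STREAM_COMMON = {NONDEPENDENT: 10, CENTRAL: 11, DEPENDENT: 12}
_STREAM_INDEP = 20
_STREAM_CRACKLE = 30
_STREAM_HU = 40


@dataclass
class ScenarioConfig:
    """Study-design grid and generator parameters.

    Defaults reproduce the experimental conditions: 6 subjects, BLH and
    LAV, PEEP 0/5/10/15 cmH2O, 20 s records at 19.2 kHz, 6 breaths/min at
    an I:E ratio of 1:1, frames every 0.58 s.
    """

    seed: int = 0
    n_subjects: int = 6
    conditions: tuple[str, ...] = ("BLH", "LAV")
    peep_levels: tuple[int, ...] = (0, 5, 10, 15)
    respiratory_rate_bpm: float = 6.0
    ie_ratio: float = 1.0
    duration_s: float = 20.0
    fs_hz: float = 19200.0
    frame_interval_s: float = 0.58
    first_inspiration_s: float = 2.5
    recruitment_tau_s: float = 1.5
    # acoustics
    crackle_coupling_per_cm3: float = 2.0     # events per cm3 recruited
    crackle_center_hz: float = 650.0
    crackle_amplitude: float = 0.25
    breath_noise_rms: float = 0.05
    breath_band_hz: tuple[float, float] = (75.0, 2000.0)
    expiratory_noise_gain: float = 0.35
    common_mix: dict[str, float] = field(default_factory=lambda: {
        NONDEPENDENT: 0.4, CENTRAL: 0.4, DEPENDENT: 0.4})
    crackle_roi_gain: dict[str, float] = field(default_factory=lambda: {
        NONDEPENDENT: 0.05, CENTRAL: 0.25, DEPENDENT: 1.0})
    subject_sigma: float = 0.25               # lognormal amplitude spread
    # CT rendering
    grid_shape: tuple[int, int, int] = (20, 20, 24)
    total_lung_cm3: float = 295.0
    hu_noise_sd: float = 30.0
    hu_atelectatic_mean: float = -150.0
    hu_aerated_mean: float = -750.0
    gravity_axis: int = 2

    def __post_init__(self) -> None:
        for cond in self.conditions:
            if cond not in ("BLH", "LAV"):
                raise ValueError(f"unknown condition {cond!r}")
        # the published per-ROI means are slightly non-monotone in the
        # nondependent zone, so the PEEP trend is enforced on the summed
        # whole-lung amplitude
        amps = self.delta_table("LAV")
        seq = [sum(amps[roi][p] for roi in ROIS)
               for p in sorted(self.peep_levels)]
        if any(b > a + 1e-9 for a, b in zip(seq, seq[1:])):
            raise ValueError(
                "LAV whole-lung recruitment amplitude must be "
                "non-increasing in PEEP")

    @property
    def voxel_volume_cm3(self) -> float:
        return self.total_lung_cm3 / int(np.prod(self.grid_shape))

    @property
    def breath_period_s(self) -> float:
        return 60.0 / self.respiratory_rate_bpm

    @property
    def inspiration_s(self) -> float:
        return self.breath_period_s * self.ie_ratio / (1.0 + self.ie_ratio)

    def breaths(self) -> list[tuple[float, float]]:
        """Inspiration (start, duration) windows inside the record."""
        out = []
        t = self.first_inspiration_s
        while t + 1e-9 < self.duration_s:
            out.append((t, min(self.inspiration_s, self.duration_s - t)))
            t += self.breath_period_s
        return out

    def delta_table(self, condition: str) -> dict[str, dict[int, float]]:
        if condition == "BLH":
            return {roi: {p: 0.0 for p in self.peep_levels} for roi in ROIS}
        return {roi: {p: LAV_DELTA_CM3[roi][p] for p in self.peep_levels}
                for roi in ROIS}

    def baseline_table(self, condition: str) -> dict[str, dict[int, float]]:
        """End-expiratory atelectatic volume per ROI and PEEP."""
        if condition == "BLH":
            return {roi: {p: BLH_ATELECTASIS_CM3[roi]
                          for p in self.peep_levels} for roi in ROIS}
        # cycle-average + half the swing ~= end-expiratory level
        return {roi: {p: LAV_ATELECTASIS_CM3[roi][p] + LAV_DELTA_CM3[roi][p] / 2
                      for p in self.peep_levels} for roi in ROIS}


@dataclass
class ScenarioTruth:
    """Ground truth for one subject x condition x PEEP cell."""

    subject: int
    condition: str
    peep: int
    delta_atelectasis_cm3: dict[str, float]      # per ROI + "global"
    frame_volumes_cm3: dict[str, np.ndarray]     # rendered (quantised) curves
    crackle_times_s: np.ndarray
    crackle_amplitudes: np.ndarray
    subject_multiplier: float


@dataclass
class ScenarioItem:
    subject: int
    condition: str
    peep: int
    recording: Recording
    hu_series: HUVolumeSeries
    breaths: list[tuple[float, float]]
    truth: ScenarioTruth


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), *key)))


# ---------------------------------------------------------------------------
# recruitment curve


def synth_recruitment_curve(amplitude_cm3: float, tau_s: float,
                            breaths: list[tuple[float, float]],
                            times_s: np.ndarray,
                            baseline_cm3: float = 0.0) -> np.ndarray:
    """Atelectatic volume over time for one recruiting compartment.

    During inspiration the volume falls exponentially toward
    ``baseline - amplitude`` with time constant ``tau_s``; during
    expiration it relaxes back toward the baseline with the same time
    constant (symmetric de-recruitment).
    """
    if amplitude_cm3 < 0:
        raise ValueError("recruitment amplitude must be >= 0")
    if tau_s <= 0:
        raise ValueError("time constant must be positive")
    times_s = np.asarray(times_s, dtype=float)
    v = np.full_like(times_s, baseline_cm3)
    if amplitude_cm3 == 0 or not breaths:
        return v
    for i, t in enumerate(times_s):
        drop = 0.0
        for start, dur in breaths:
            if t < start:
                break
            if t < start + dur:                   # inspiring
                drop = amplitude_cm3 * (1.0 - np.exp(-(t - start) / tau_s))
            else:                                 # expiring / later breath
                end_drop = amplitude_cm3 * (1.0 - np.exp(-dur / tau_s))
                drop = end_drop * np.exp(-(t - start - dur) / tau_s)
        v[i] = baseline_cm3 - drop
    return v


# ---------------------------------------------------------------------------
# CT rendering


def render_hu_frames(curves: dict[str, np.ndarray],
                     grid_shape: tuple[int, int, int],
                     voxel_volume_cm3: float,
                     hu_noise_sd: float,
                     rng: np.random.Generator,
                     frame_interval_s: float = 0.58,
                     hu_atelectatic_mean: float = -150.0,
                     hu_aerated_mean: float = -750.0,
                     gravity_axis: int = 2) -> tuple[HUVolumeSeries,
                                                     dict[str, np.ndarray]]:
    """Render HU frames whose atelectatic block tracks a volume curve.

    ``curves`` maps each of the three gravity-zone ROIs to a per-frame
    atelectatic-volume series (cm3).  Within each zone slab, voxels are
    filled from the dorsal end with attenuation drawn around the
    atelectatic mean; the remainder of the lung is aerated.  Gaussian HU
    noise is clipped to the respective compartment interval so rendered
    voxels stay classifiable.  Returns the series and the quantised
    (voxel-resolution) ground-truth volume per ROI per frame.
    """
    mask = np.ones(grid_shape, dtype=bool)
    labels = partition_rois(mask, gravity_axis)
    n_frames = len(next(iter(curves.values())))
    order = {}          # per-ROI voxel fill order: most dorsal first
    coords = np.indices(grid_shape)[gravity_axis]
    from .ctvol import ROI_CODE
    for roi in ROIS:
        vox = np.argwhere(labels == ROI_CODE[roi])
        depth = coords[tuple(vox.T)]
        order[roi] = vox[np.argsort(-depth, kind="stable")]

    frames = np.empty((n_frames, *grid_shape), dtype=np.float32)
    truth = {roi: np.empty(n_frames) for roi in ROIS}
    for i in range(n_frames):
        atel = np.zeros(grid_shape, dtype=bool)
        for roi in ROIS:
            vol = float(curves[roi][i])
            n_vox = int(round(vol / voxel_volume_cm3))
            if n_vox > len(order[roi]):
                raise ValueError(
                    f"requested {vol:.1f} cm3 exceeds {roi} slab capacity")
            sel = order[roi][:n_vox]
            atel[tuple(sel.T)] = True
            truth[roi][i] = n_vox * voxel_volume_cm3
        hu = rng.normal(hu_aerated_mean, hu_noise_sd, size=grid_shape)
        hu = np.clip(hu, -899.0, -602.0)
        hu_at = rng.normal(hu_atelectatic_mean, hu_noise_sd, size=grid_shape)
        hu_at = np.clip(hu_at, -299.0, -1.0)
        frames[i] = np.where(atel, hu_at, hu)
    series = HUVolumeSeries(frames=frames, voxel_volume_cm3=voxel_volume_cm3,
                            mask=mask, frame_interval_s=frame_interval_s,
                            roi_labels=labels, gravity_axis=gravity_axis)
    return series, truth


# ---------------------------------------------------------------------------
# acoustics


def flow_envelope(duration_s: float, fs_hz: float,
                  breaths: list[tuple[float, float]],
                  expiratory_gain: float = 0.35,
                  ramp_s: float = 0.2) -> np.ndarray:
    """Flow-proportional amplitude envelope: high in inspiration, low out."""
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    env = np.full(n, expiratory_gain)
    for start, dur in breaths:
        env = np.maximum(env, expiratory_gain + (1.0 - expiratory_gain)
                         * np.clip(np.minimum(t - start, start + dur - t)
                                   / ramp_s, 0.0, 1.0))
    return env


def synth_breath_sound(duration_s: float, fs_hz: float,
                       band_hz: tuple[float, float],
                       envelope: np.ndarray | None,
                       rng: np.random.Generator,
                       rms: float = 1.0) -> np.ndarray:
    """Band-limited Gaussian noise shaped by an amplitude envelope.

    The band limitation is exact (spectral masking), so essentially all
    signal energy lies inside ``band_hz``.
    """
    if fs_hz <= 2 * band_hz[1]:
        raise ValueError("sampling rate must exceed twice the band top")
    n = int(round(duration_s * fs_hz))
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    spec[(f < band_hz[0]) | (f > band_hz[1])] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    if envelope is not None:
        x = x * envelope
    return x


def crackle_wavelet(fs_hz: float, f_center_hz: float = 650.0,
                    decay_tau_s: float | None = None,
                    length_s: float = 0.03) -> np.ndarray:
    """Exponentially damped sinusoid idealising one fine crackle.

    The default decay constant puts 90% of the event energy inside the
    first 10 ms, matching the short explosive character of fine crackles.
    """
    if decay_tau_s is None:
        decay_tau_s = 2 * 0.010 / np.log(10.0)   # 90% energy in 10 ms
    t = np.arange(int(round(length_s * fs_hz))) / fs_hz
    return np.exp(-t / decay_tau_s) * np.sin(2 * np.pi * f_center_hz * t)


def recruitment_rate(curve_cm3: np.ndarray, times_s: np.ndarray,
                     fine_times_s: np.ndarray) -> np.ndarray:
    """Instantaneous recruitment rate (-dV/dt clipped at 0) on a fine grid."""
    v = np.interp(fine_times_s, times_s, curve_cm3)
    rate = -np.gradient(v, fine_times_s)
    return np.clip(rate, 0.0, None)


def synth_crackles(curve_cm3: np.ndarray, times_s: np.ndarray,
                   coupling_per_cm3: float, fs_hz: float,
                   duration_s: float, rng: np.random.Generator,
                   f_center_hz: float = 650.0,
                   amplitude: float = 1.0,
                   amp_jitter_sigma: float = 0.2
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Crackle event train tied to a recruitment curve.

    Events follow an inhomogeneous Poisson process with rate
    ``coupling x max(-dV/dt, 0)``, so the expected event count equals the
    coupling times the total volume recruited.  Each event is a damped
    650 Hz sinusoid with log-normal amplitude jitter.

    Returns (event times, event amplitudes, summed waveform).
    """
    if coupling_per_cm3 < 0:
        raise ValueError("coupling must be >= 0")
    n = int(round(duration_s * fs_hz))
    wave = np.zeros(n)
    if coupling_per_cm3 == 0 or np.ptp(curve_cm3) == 0:
        return np.empty(0), np.empty(0), wave
    dt = 1e-3
    fine_t = np.arange(0.0, duration_s, dt)
    lam = coupling_per_cm3 * recruitment_rate(curve_cm3, times_s, fine_t)
    counts = rng.poisson(lam * dt)
    idx = np.repeat(np.arange(len(fine_t)), counts)
    t_events = fine_t[idx] + rng.uniform(0.0, dt, size=len(idx))
    t_events.sort()
    amps = amplitude * rng.lognormal(0.0, amp_jitter_sigma, size=len(t_events))
    kernel = crackle_wavelet(fs_hz, f_center_hz)
    for t0, a in zip(t_events, amps):
        i0 = int(round(t0 * fs_hz))
        seg = kernel[:max(0, min(len(kernel), n - i0))]
        wave[i0:i0 + len(seg)] += a * seg
    return t_events, amps, wave


# ---------------------------------------------------------------------------
# full scenario


def _cell_acoustics(cfg: ScenarioConfig, matrix: SensorMatrix,
                    subject: int, peep_idx: int,
                    breaths: list[tuple[float, float]],
                    crackle_wave: np.ndarray,
                    crackle_events: int) -> np.ndarray:
    """Mix breath noise, per-ROI common sources and crackles per sensor."""
    n = int(round(cfg.duration_s * cfg.fs_hz))
    env = flow_envelope(cfg.duration_s, cfg.fs_hz, breaths,
                        cfg.expiratory_noise_gain)
    common = {}
    for roi in ROIS:
        rng = _rng(cfg.seed, subject, peep_idx, _STREAM_COMMON[roi])
        common[roi] = synth_breath_sound(cfg.duration_s, cfg.fs_hz,
                                         cfg.breath_band_hz, env, rng,
                                         rms=cfg.breath_noise_rms)
    rng_ind = _rng(cfg.seed, subject, peep_idx, _STREAM_INDEP)
    active = matrix.active_sensors
    out = np.empty((len(active), n))
    for i, sensor in enumerate(active):
        roi = matrix.row_to_roi[sensor.row]
        w = cfg.common_mix[roi]
        indep = synth_breath_sound(cfg.duration_s, cfg.fs_hz,
                                   cfg.breath_band_hz, env, rng_ind,
                                   rms=cfg.breath_noise_rms)
        x = np.sqrt(w) * common[roi] + np.sqrt(1.0 - w) * indep
        if crackle_events:
            gain = cfg.crackle_roi_gain[roi] \
                * rng_ind.lognormal(0.0, 0.1)
            x = x + gain * crackle_wave
        out[i] = x
    return out


def generate_scenario(config: ScenarioConfig) -> Iterator[ScenarioItem]:
    """Yield one fully rendered cell per subject x condition x PEEP.

    Cells are produced lazily (a 34-channel 20 s recording at 19.2 kHz is
    ~50 MB) in a fixed deterministic order: subject-major, then condition,
    then PEEP.
    """
    matrix = build_default_matrix()
    breaths = config.breaths()
    n_frames = int(np.floor(config.duration_s / config.frame_interval_s
                            + 1e-9))
    frame_times = (np.arange(n_frames) + 0.5) * config.frame_interval_s

    for subject in range(config.n_subjects):
        mult = float(_rng(config.seed, subject, _STREAM_SUBJECT)
                     .lognormal(0.0, config.subject_sigma))
        for condition in config.conditions:
            deltas = config.delta_table(condition)
            baselines = config.baseline_table(condition)
            for peep_idx, peep in enumerate(config.peep_levels):
                curves = {}
                for roi in ROIS:
                    amp = deltas[roi][peep] * (mult if condition == "LAV"
                                               else 1.0)
                    curves[roi] = synth_recruitment_curve(
                        amp, config.recruitment_tau_s, breaths, frame_times,
                        baseline_cm3=baselines[roi][peep])
                rng_hu = _rng(config.seed, subject, peep_idx, _STREAM_HU)
                hu_series, rendered = render_hu_frames(
                    curves, config.grid_shape, config.voxel_volume_cm3,
                    config.hu_noise_sd, rng_hu,
                    frame_interval_s=config.frame_interval_s,
                    hu_atelectatic_mean=config.hu_atelectatic_mean,
                    hu_aerated_mean=config.hu_aerated_mean,
                    gravity_axis=config.gravity_axis)

                total_curve = np.sum([curves[r] for r in ROIS], axis=0)
                rng_cr = _rng(config.seed, subject, peep_idx, _STREAM_CRACKLE)
                t_ev, a_ev, wave = synth_crackles(
                    total_curve, frame_times,
                    config.crackle_coupling_per_cm3, config.fs_hz,
                    config.duration_s, rng_cr,
                    f_center_hz=config.crackle_center_hz,
                    amplitude=config.crackle_amplitude)

                samples = _cell_acoustics(config, matrix, subject, peep_idx,
                                          breaths, wave, len(t_ev))
                recording = Recording(samples=samples, fs=config.fs_hz,
                                      sensor_ids=matrix.active_ids,
                                      breaths=breaths)

                true_delta = {}
                for roi in ROIS:
                    true_delta[roi] = _annotated_delta(
                        rendered[roi], frame_times, breaths)
                true_delta["global"] = float(
                    sum(true_delta[r] for r in ROIS))
                truth = ScenarioTruth(
                    subject=subject, condition=condition, peep=peep,
                    delta_atelectasis_cm3=true_delta,
                    frame_volumes_cm3=rendered,
                    crackle_times_s=t_ev, crackle_amplitudes=a_ev,
                    subject_multiplier=mult)
                yield ScenarioItem(subject=subject, condition=condition,
                                   peep=peep, recording=recording,
                                   hu_series=hu_series, breaths=breaths,
                                   truth=truth)


def _annotated_delta(volumes: np.ndarray, times: np.ndarray,
                     breaths: list[tuple[float, float]]) -> float:
    """End-expiratory minus end-inspiratory volume, averaged over breaths."""
    deltas = []
    for start, dur in breaths:
        before = np.where(times < start)[0]
        inside = np.where((times >= start) & (times < start + dur))[0]
        if len(before) and len(inside):
            deltas.append(volumes[before[-1]] - volumes[inside[-1]])
    return float(np.mean(deltas)) if deltas else 0.0
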