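"""Acoustic parameters of within-breath recruitment: dCE, FFT-area, SC/dSC.

Three per-clip parameters are extracted from multi-channel thoracic sound
recordings, on contiguous clips of 0.58 s (the frame time of the reference
4D-CT acquisition):

dCE (dynamic crackle energy)
    RMS of the signal band-passed to 600-700 Hz — the fine-crackle band —
    after downsampling to 4800 Hz.
FFT area
    Share (in %) of the supra-threshold (> -70 dB) Welch spectral area that
    lies above 500 Hz, computed on the 75-2000 Hz band-passed signal.
SC / dSC (spectral coherence and its dynamic variation)
    Mean magnitude-squared coherence of neighbouring-sensor pairs over
    75-2000 Hz, scaled to 0-100; SC averages the inspiratory clips, dSC is
    their standard deviation over the inspiratory phase.

All Welch/coherence estimates use 200-sample Hamming windows at 50% overlap.
The per-clip spectrum is normalised to its own maximum (peak = 0 dB) before
the -70 dB threshold is applied, which makes FFT-area invariant to overall
recording gain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .geometry import GLOBAL, SensorMatrix, neighbor_pairs

CLIP_DURATION_S = 0.58
CRACKLE_BAND_HZ = (600.0, 700.0)
ANALYSIS_BAND_HZ = (75.0, 2000.0)
FIR_ORDER = 200
WELCH_NPERSEG = 200
WELCH_NOVERLAP = 100
FFT_FLOOR_DB = -70.0
FFT_SPLIT_HZ = 500.0
TARGET_FS_HZ = 4800.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class Recording:
    """Multi-channel sound recording with breath-phase annotations.

    samples : (n_sensors, n_samples) float array, dimensionless amplitude
    fs : sampling rate in Hz
    sensor_ids : channel order, aligned to a :class:`SensorMatrix`
    breaths : list of (inspiration_start_s, inspiration_duration_s)
    """

    samples: np.ndarray
    fs: float
    sensor_ids: list[str]
    breaths: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[None, :]
        if self.samples.shape[0] != len(self.sensor_ids):
            raise ValueError("channel count does not match sensor_ids")
        dur = self.duration_s
        for start, length in self.breaths:
            if start < 0 or start + length > dur + 1e-9:
                raise ValueError(
                    f"inspiration ({start}, {length}) outside recording of {dur:.2f} s")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, sensor_id: str) -> np.ndarray:
        return self.samples[self.sensor_ids.index(sensor_id)]


@dataclass
class ClipGrid:
    """Per-clip values on the fixed 0.58 s clip grid.

    ``values`` is (n_sensors, n_clips) for per-sensor parameters or
    (n_clips,) for ROI-level series (SC).  ``inspiratory`` marks clips whose
    midpoint falls inside an inspiration window; ``breath`` gives the index
    of that inspiration (-1 outside).  ``reliable`` flags clips free of FIR
    edge effects.
    """

    clip_duration_s: float
    start_times: np.ndarray
    inspiratory: np.ndarray
    breath: np.ndarray
    values: np.ndarray | None = None
    sensor_ids: list[str] | None = None
    reliable: np.ndarray | None = None

    @property
    def n_clips(self) -> int:
        return len(self.start_times)

    @property
    def midpoints(self) -> np.ndarray:
        return self.start_times + self.clip_duration_s / 2.0

    def with_values(self, values: np.ndarray,
                    sensor_ids: list[str] | None = None) -> "ClipGrid":
        return dataclasses.replace(self, values=np.asarray(values, float),
                                   sensor_ids=sensor_ids)


@dataclass
class AcousticSummary:
    """Inspiratory-phase summary of one parameter in one ROI."""

    parameter: str
    roi: str
    value: float                 # pooled over breaths
    per_breath: dict[int, float]


def make_clip_grid(duration_s: float,
                   breaths: list[tuple[float, float]],
                   clip_duration_s: float = CLIP_DURATION_S) -> ClipGrid:
    """Contiguous, non-overlapping clips starting at t = 0.

    A clip is inspiratory iff its midpoint lies inside an inspiration
    window; the trailing partial clip is dropped.
    """
    n_clips = int(np.floor(duration_s / clip_duration_s + 1e-9))
    starts = np.arange(n_clips) * clip_duration_s
    mids = starts + clip_duration_s / 2.0
    insp = np.zeros(n_clips, dtype=bool)
    breath = np.full(n_clips, -1, dtype=int)
    for k, (t0, dur) in enumerate(breaths):
        inside = (mids >= t0) & (mids < t0 + dur)
        insp |= inside
        breath[inside] = k
    return ClipGrid(clip_duration_s=clip_duration_s, start_times=starts,
                    inspiratory=insp, breath=breath)


def _clip_slices(grid: ClipGrid, fs: float, n_samples: int):
    spc = int(round(grid.clip_duration_s * fs))
    for start in grid.start_times:
        i0 = int(round(start * fs))
        if i0 + spc <= n_samples:
            yield slice(i0, i0 + spc)


def _edge_reliability(grid: ClipGrid, fs: float, n_samples: int,
                      order: int) -> np.ndarray:
    """Clips lying wholly inside the FIR settling margin are unreliable."""
    margin = order // 2 / fs
    ends = grid.start_times + grid.clip_duration_s
    lo_bad = ends <= margin
    hi_bad = grid.start_times >= n_samples / fs - margin
    return ~(lo_bad | hi_bad)


# ---------------------------------------------------------------------------
# signal conditioning


def downsample(recording: Recording, factor: int) -> Recording:
    """Anti-aliased decimation by an integer factor (FIR, zero phase)."""
    if int(factor) != factor or factor < 1:
        raise ValueError("downsampling factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return dataclasses.replace(recording,
                                   samples=recording.samples.copy())
    out = signal.decimate(recording.samples, factor, ftype="fir",
                          zero_phase=True, axis=-1)
    return dataclasses.replace(recording, samples=out,
                               fs=recording.fs / factor)


def bandpass_fir(x: np.ndarray, order: int, f_lo: float, f_hi: float,
                 fs: float) -> np.ndarray:
    """Linear-phase FIR band-pass with group-delay compensation.

    Window-method (Hamming) design of the given even order; the output is
    time-aligned with the input and has the same length.
    """
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError(f"band ({f_lo}, {f_hi}) outside (0, fs/2)")
    if order % 2 != 0:
        raise ValueError("FIR order must be even for exact delay compensation")
    taps = signal.firwin(order + 1, [f_lo, f_hi], pass_zero=False,
                         window="hamming", fs=fs)
    x = np.asarray(x, dtype=float)
    full = signal.oaconvolve(x, taps[None, :] if x.ndim == 2 else taps,
                             axes=-1 if x.ndim == 2 else None)
    half = order // 2
    return full[..., half:half + x.shape[-1]]


# ---------------------------------------------------------------------------
# dCE


def dynamic_crackle_energy(recording: Recording,
                           grid: ClipGrid | None = None,
                           band: tuple[float, float] = CRACKLE_BAND_HZ,
                           order: int = FIR_ORDER) -> ClipGrid:
    """Per-sensor, per-clip RMS of the crackle-band (600-700 Hz) signal.

    Expects the recording already downsampled to 4800 Hz.  Clips falling
    wholly inside the filter settling margin are flagged unreliable rather
    than dropped.
    """
    if grid is None:
        grid = make_clip_grid(recording.duration_s, recording.breaths)
    filtered = bandpass_fir(recording.samples, order, band[0], band[1],
                            recording.fs)
    vals = np.stack([np.sqrt(np.mean(filtered[:, sl] ** 2, axis=1))
                     for sl in _clip_slices(grid, recording.fs,
                                            recording.n_samples)], axis=1)
    out = grid.with_values(vals, sensor_ids=list(recording.sensor_ids))
    out.reliable = _edge_reliability(grid, recording.fs,
                                     recording.n_samples, order)
    return out


# ---------------------------------------------------------------------------
# FFT area


def welch_psd_db(x: np.ndarray, fs: float,
                 nperseg: int = WELCH_NPERSEG,
                 noverlap: int = WELCH_NOVERLAP) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of one clip, in dB relative to the clip's spectral peak.

    200-sample Hamming segments at 50% overlap; a partial trailing segment
    is discarded.  A zero (or constant) clip returns a -inf spectrum, which
    downstream area computation treats as entirely below threshold.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < nperseg:
        raise ValueError(f"clip shorter than one Welch segment ({nperseg})")
    win = signal.get_window("hamming", nperseg)
    f, pxx = signal.welch(x, fs=fs, window=win, nperseg=nperseg,
                          noverlap=noverlap, axis=-1)
    peak = pxx.max(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(np.where(peak > 0, pxx / peak, 0.0))
    return f, db


def fft_area(freqs: np.ndarray, psd_db: np.ndarray,
             amp_floor_db: float = FFT_FLOOR_DB,
             f_split_hz: float = FFT_SPLIT_HZ) -> float:
    """Supra-threshold spectral area above ``f_split_hz`` as % of total.

    Both areas are trapezoidal areas between the dB curve and the amplitude
    floor, restricted to frequencies where the curve exceeds the floor.
    Returns 0 when nothing exceeds the floor.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd_db = np.asarray(psd_db, dtype=float)
    if freqs.ndim != 1 or np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if freqs[0] < f_split_hz < freqs[-1] and f_split_hz not in freqs:
        split_val = np.interp(f_split_hz, freqs, psd_db)
        idx = np.searchsorted(freqs, f_split_hz)
        freqs = np.insert(freqs, idx, f_split_hz)
        psd_db = np.insert(psd_db, idx, split_val)
    height = np.clip(psd_db - amp_floor_db, 0.0, None)
    total = np.trapezoid(height, freqs)
    if total <= 0:
        return 0.0
    above = freqs >= f_split_hz
    high = np.trapezoid(height[above], freqs[above]) if above.sum() >= 2 else 0.0
    return float(100.0 * high / total)


def fft_area_series(recording: Recording,
                    grid: ClipGrid | None = None,
                    band: tuple[float, float] = ANALYSIS_BAND_HZ,
                    order: int = FIR_ORDER,
                    amp_floor_db: float = FFT_FLOOR_DB,
                    f_split_hz: float = FFT_SPLIT_HZ) -> ClipGrid:
    """Per-sensor, per-clip FFT-area (%) on the 75-2000 Hz band-passed signal."""
    if grid is None:
        grid = make_clip_grid(recording.duration_s, recording.breaths)
    filtered = bandpass_fir(recording.samples, order, band[0], band[1],
                            recording.fs)
    cols = []
    for sl in _clip_slices(grid, recording.fs, recording.n_samples):
        f, db = welch_psd_db(filtered[:, sl], recording.fs)
        keep = (f >= band[0]) & (f <= band[1])
        cols.append([fft_area(f[keep], row[keep], amp_floor_db, f_split_hz)
                     for row in db])
    vals = np.asarray(cols, dtype=float).T
    out = grid.with_values(vals, sensor_ids=list(recording.sensor_ids))
    out.reliable = _edge_reliability(grid, recording.fs,
                                     recording.n_samples, order)
    return out


# ---------------------------------------------------------------------------
# coherence


def _segment_ffts(x: np.ndarray, nperseg: int, noverlap: int) -> np.ndarray:
    """Hamming-windowed, mean-removed segment rFFTs, (..., n_seg, n_freq)."""
    step = nperseg - noverlap
    n = x.shape[-1]
    n_seg = (n - nperseg) // step + 1
    if n_seg < 1:
        raise ValueError("clip shorter than one Welch segment")
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = x[..., idx]                                    # (..., n_seg, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    win = signal.get_window("hamming", nperseg)
    return np.fft.rfft(segs * win, axis=-1)


def pair_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                   band: tuple[float, float] = ANALYSIS_BAND_HZ,
                   nperseg: int = WELCH_NPERSEG,
                   noverlap: int = WELCH_NOVERLAP) -> float:
    """Band-mean magnitude-squared coherence of two equal-length signals.

    Same Welch segmentation as the PSD estimate.  Raises on zero-variance
    input, where coherence is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have identical shape")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("coherence undefined for constant input")
    f, cxy = signal.coherence(x, y, fs=fs,
                              window=signal.get_window("hamming", nperseg),
                              nperseg=nperseg, noverlap=noverlap)
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.mean(cxy[sel]))


def roi_coherence_series(recording: Recording, matrix: SensorMatrix,
                         roi: str,
                         grid: ClipGrid | None = None,
                         band: tuple[float, float] = ANALYSIS_BAND_HZ,
                         order: int = FIR_ORDER,
                         boundary: str = "strict",
                         prefiltered: bool = False) -> ClipGrid:
    """Per-clip SC: 100 x mean neighbour-pair coherence over a ROI.

    The recording is band-passed to 75-2000 Hz first (unless
    ``prefiltered``), then for each 0.58 s clip the magnitude-squared
    coherence of every grid-adjacent sensor pair in the ROI is averaged.
    """
    pairs = neighbor_pairs(matrix, roi, boundary=boundary)
    pairs = [p for p in pairs
             if p[0] in recording.sensor_ids and p[1] in recording.sensor_ids]
    if not pairs:
        raise ValueError(f"no neighbour pairs available in ROI {roi!r}")
    if grid is None:
        grid = make_clip_grid(recording.duration_s, recording.breaths)
    x = recording.samples
    if not prefiltered:
        x = bandpass_fir(x, order, band[0], band[1], recording.fs)

    chan = {sid: i for i, sid in enumerate(recording.sensor_ids)}
    needed = sorted({chan[s] for p in pairs for s in p})
    pos = {c: i for i, c in enumerate(needed)}
    ia = np.array([pos[chan[a]] for a, _ in pairs])
    ib = np.array([pos[chan[b]] for _, b in pairs])

    nperseg, noverlap = WELCH_NPERSEG, WELCH_NOVERLAP
    f = np.fft.rfftfreq(nperseg, d=1.0 / recording.fs)
    sel = (f >= band[0]) & (f <= band[1])

    sc = np.empty(grid.n_clips)
    sc[:] = np.nan
    for ci, sl in enumerate(_clip_slices(grid, recording.fs,
                                         recording.n_samples)):
        ff = _segment_ffts(x[needed][:, sl], nperseg, noverlap)
        pxx = np.mean(np.abs(ff) ** 2, axis=-2)               # (nch, nf)
        pxy = np.mean(ff[ia] * np.conj(ff[ib]), axis=-2)      # (npair, nf)
        with np.errstate(divide="ignore", invalid="ignore"):
            cxy = np.abs(pxy) ** 2 / (pxx[ia] * pxx[ib])
        sc[ci] = 100.0 * np.nanmean(cxy[:, sel])
    out = grid.with_values(sc)
    out.reliable = _edge_reliability(grid, recording.fs,
                                     recording.n_samples, order)
    return out


def sc_dsc_summary(series: ClipGrid, ddof: int = 1) -> tuple[float, float]:
    """Inspiratory-phase mean (SC) and standard deviation (dSC) of a SC series.

    dSC is the sample SD (``ddof=1``) by default; pass ``ddof=0`` for the
    population SD.
    """
    if series.values is None or series.values.ndim != 1:
        raise ValueError("expected a 1-D SC clip series")
    mask = series.inspiratory.copy()
    if series.reliable is not None:
        mask &= series.reliable
    vals = series.values[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise ValueError("need at least 2 inspiratory clips for SC/dSC")
    return float(np.mean(vals)), float(np.std(vals, ddof=ddof))


# ---------------------------------------------------------------------------
# regional aggregation


def roi_aggregate(grid: ClipGrid, matrix: SensorMatrix, roi: str,
                  parameter: str = "value") -> AcousticSummary:
    """Mean over a ROI's sensors and inspiratory clips, per breath then pooled.

    The pooled value is the unweighted mean of the per-breath means, so a
    truncated final breath does not dominate.
    """
    if grid.values is None or grid.sensor_ids is None:
        raise ValueError("grid carries no per-sensor values")
    roi_ids = [s.id for s in matrix.sensors_in_roi(roi)]
    rows = [i for i, sid in enumerate(grid.sensor_ids) if sid in roi_ids]
    if not rows:
        raise ValueError(f"ROI {roi!r} has no sensors in this grid")
    mask = grid.inspiratory.copy()
    if grid.reliable is not None:
        mask &= grid.reliable
    per_breath: dict[int, float] = {}
    for k in sorted(set(grid.breath[mask])):
        clips = np.where(mask & (grid.breath == k))[0]
        per_breath[int(k)] = float(np.mean(grid.values[np.ix_(rows, clips)]))
    if not per_breath:
        raise ValueError("no inspiratory clips to aggregate")
    pooled = float(np.mean(list(per_breath.values())))
    return AcousticSummary(parameter=parameter, roi=roi, value=pooled,
                           per_breath=per_breath)
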