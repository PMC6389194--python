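"""dCE, FFT-area and coherence computations on analytically known signals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crackletrace as ct
from crackletrace import acoustics as ac


def sine_recording(freq, fs, duration=2.9, amp=1.0, channels=1,
                   breaths=()):
    t = np.arange(int(round(duration * fs))) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return ac.Recording(samples=np.tile(x, (channels, 1)), fs=fs,
                        sensor_ids=[f"s{i}" for i in range(channels)],
                        breaths=list(breaths))


def steady_rms(x, margin=300):
    return np.sqrt(np.mean(x[margin:-margin] ** 2))


# ---------------------------------------------------------------- downsample

class TestDownsample:
    def test_rate_divides_by_factor(self):
        rec = sine_recording(100, 19200, duration=1.0)
        out = ac.downsample(rec, 4)
        assert out.fs == 4800
        assert out.n_samples == rec.n_samples // 4

    def test_factor_one_is_identity(self):
        rec = sine_recording(100, 19200, duration=0.5)
        out = ac.downsample(rec, 1)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_passband_sine_amplitude_preserved_within_1pct(self):
        rec = ac.downsample(sine_recording(100, 19200, duration=2.0), 4)
        ref = sine_recording(100, 4800, duration=2.0)
        assert abs(steady_rms(rec.samples[0]) / steady_rms(ref.samples[0])
                   - 1.0) < 0.01

    @pytest.mark.parametrize("factor", [0, -2, 1.5])
    def test_invalid_factor_raises(self, factor):
        with pytest.raises(ValueError):
            ac.downsample(sine_recording(100, 19200, duration=0.1), factor)


# ---------------------------------------------------------------- FIR filter

class TestBandpassFir:
    def test_crackle_band_passes_650hz_under_3db(self):
        x = sine_recording(650, 4800).samples[0]
        y = ac.bandpass_fir(x, 200, 600, 700, 4800)
        loss = 20 * np.log10(steady_rms(y) / steady_rms(x))
        assert loss > -3.0

    def test_stopband_rejects_100hz_over_40db(self):
        x = sine_recording(100, 4800).samples[0]
        y = ac.bandpass_fir(x, 200, 600, 700, 4800)
        assert 20 * np.log10(steady_rms(y) / steady_rms(x)) < -40.0

    def test_zero_signal_stays_zero(self):
        y = ac.bandpass_fir(np.zeros(5000), 200, 600, 700, 4800)
        assert y.shape == (5000,)
        np.testing.assert_array_equal(y, 0.0)

    def test_group_delay_compensation_keeps_alignment(self):
        # a tone burst must stay where it was
        fs = 4800
        x = np.zeros(int(fs * 2))
        i0 = int(fs * 0.9)
        t = np.arange(int(fs * 0.2)) / fs
        x[i0:i0 + len(t)] = np.sin(2 * np.pi * 650 * t)
        y = ac.bandpass_fir(x, 200, 600, 700, fs)
        assert np.argmax(np.abs(y) > 0.5 * np.abs(y).max()) == pytest.approx(
            i0, abs=150)

    def test_white_noise_energy_concentrates_in_band(self, rng):
        x = rng.standard_normal(4800 * 30)
        y = ac.bandpass_fir(x, 200, 600, 700, 4800)
        f, p = ac.welch_psd_db(y, 4800)
        lin = 10 ** (p / 10.0)
        inband = (f >= 580) & (f <= 720)
        assert lin[inband].sum() / lin.sum() >= 0.90

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError):
            ac.bandpass_fir(np.zeros(1000), 200, 600, 2600, 4800)


# ----------------------------------------------------------------------- dCE

class TestDynamicCrackleEnergy:
    def test_zero_channel_gives_zero_clips(self):
        rec = ac.Recording(samples=np.zeros((1, 4800 * 3)), fs=4800,
                           sensor_ids=["s0"])
        grid = ac.dynamic_crackle_energy(rec)
        np.testing.assert_array_equal(grid.values, 0.0)

    def test_pure_650hz_sine_rms_is_amplitude_over_sqrt2(self):
        amp = 0.7
        rec = sine_recording(650, 4800, duration=4.1, amp=amp)
        grid = ac.dynamic_crackle_energy(rec)
        interior = grid.values[0][1:-1]    # skip filter settling clips
        np.testing.assert_allclose(interior, amp / np.sqrt(2), rtol=0.02)

    def test_crackle_burst_raises_only_its_clip(self, rng):
        fs = 4800
        x = np.zeros(int(fs * 3.0))
        kern = ct.crackle_wavelet(fs)
        i0 = int(1.0 * fs)                 # inside clip 1 (0.58-1.16 s)
        x[i0:i0 + len(kern)] = kern
        rec = ac.Recording(samples=x[None, :], fs=fs, sensor_ids=["s0"])
        grid = ac.dynamic_crackle_energy(rec)
        v = grid.values[0]
        assert np.argmax(v) == 1
        assert v[1] > 100 * np.max(np.delete(v, 1))

    def test_burst_clip_beats_quiet_clip_on_noise_floor(self, rng):
        fs = 4800
        noise = 0.01 * rng.standard_normal(int(fs * 3.0))
        kern = ct.crackle_wavelet(fs)
        burst = noise.copy()
        burst[int(1.0 * fs):int(1.0 * fs) + len(kern)] += kern
        for sig, name in ((noise, "quiet"), (burst, "burst")):
            rec = ac.Recording(samples=sig[None, :], fs=fs, sensor_ids=["s0"])
            vals = ac.dynamic_crackle_energy(rec).values[0]
            if name == "quiet":
                quiet_val = vals[1]
            else:
                assert vals[1] > quiet_val


# ------------------------------------------------------------ Welch PSD / dB

class TestWelchPsdDb:
    def test_sine_peak_is_zero_db_at_its_frequency(self):
        fs = 4800
        x = np.sin(2 * np.pi * 600 * np.arange(2784) / fs)  # 600 = bin centre
        f, db = ac.welch_psd_db(x, fs)
        assert db.max() == 0.0
        assert f[np.argmax(db)] == pytest.approx(600.0)

    def test_white_noise_spectrum_flat_within_3db(self, rng):
        f, db = ac.welch_psd_db(rng.standard_normal(2784 * 16), 4800)
        sel = (f >= 75) & (f <= 2000)
        assert db[sel].max() - db[sel].min() < 3.0

    def test_zero_clip_maps_to_all_below_threshold(self):
        f, db = ac.welch_psd_db(np.zeros(2784), 4800)
        assert np.all(np.isneginf(db))
        assert ac.fft_area(f, db) == 0.0

    def test_short_clip_raises(self):
        with pytest.raises(ValueError):
            ac.welch_psd_db(np.ones(150), 4800)


# ------------------------------------------------------------------ FFT area

class TestFftArea:
    def test_all_below_floor_is_zero(self):
        f = np.linspace(75, 2000, 500)
        assert ac.fft_area(f, np.full_like(f, -90.0)) == 0.0

    def test_energy_only_above_split_is_100(self):
        f = np.linspace(75, 2000, 771)
        db = np.where(f > 500, -40.0, -90.0)
        assert ac.fft_area(f, db) == pytest.approx(100.0)

    def test_flat_minus60_matches_rectangle_oracle(self):
        f = np.linspace(75, 2000, 1001)
        db = np.full_like(f, -60.0)
        expected = 100.0 * (2000 - 500) / (2000 - 75)   # analytic rectangle
        assert ac.fft_area(f, db) == pytest.approx(expected, rel=1e-9)

    @given(st.floats(min_value=0.01, max_value=1000.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_gain_invariance_under_per_clip_normalization(self, k):
        fs = 4800
        rng = np.random.default_rng(99)
        x = rng.standard_normal(2784)
        f1, d1 = ac.welch_psd_db(x, fs)
        f2, d2 = ac.welch_psd_db(k * x, fs)
        assert ac.fft_area(f1, d1) == pytest.approx(ac.fft_area(f2, d2),
                                                    rel=1e-9)

    @given(st.lists(st.floats(min_value=-120, max_value=0), min_size=3,
                    max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_result_always_in_0_100(self, levels):
        f = np.linspace(75, 2000, len(levels))
        out = ac.fft_area(f, np.asarray(levels))
        assert 0.0 <= out <= 100.0


# ----------------------------------------------------------------- coherence

class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(2784)
        assert ac.pair_coherence(x, x, 4800) == pytest.approx(1.0, abs=1e-9)

    def test_delay_invariance(self, rng):
        x = rng.standard_normal(2784)
        y = np.roll(x, 9)
        assert ac.pair_coherence(x, y, 4800) > 0.95

    def test_independent_noise_coherence_low(self, rng):
        x = rng.standard_normal(2784 * 4)
        y = rng.standard_normal(2784 * 4)
        assert ac.pair_coherence(x, y, 4800) < 0.3

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            ac.pair_coherence(np.ones(2784), np.ones(2784), 4800)

    def test_matches_scipy_reference_per_clip(self, matrix, rng):
        """Vectorised per-clip SC equals a direct scipy coherence average."""
        from scipy import signal as sig
        ids = sorted({s for p in ct.neighbor_pairs(matrix, "dependent")[:4]
                      for s in p})
        n = int(4800 * 1.16)
        rec = ac.Recording(samples=rng.standard_normal((len(ids), n)),
                           fs=4800, sensor_ids=ids)
        # every dependent-ROI pair realisable from these channels
        keep = [p for p in ct.neighbor_pairs(matrix, "dependent")
                if p[0] in ids and p[1] in ids]
        series = ac.roi_coherence_series(rec, matrix, "dependent",
                                         prefiltered=True)
        sl = slice(0, 2784)
        win = sig.get_window("hamming", 200)
        ref = []
        for a, b in keep:
            f, c = sig.coherence(rec.channel(a)[sl], rec.channel(b)[sl],
                                 fs=4800, window=win, nperseg=200,
                                 noverlap=100)
            ref.append(np.mean(c[(f >= 75) & (f <= 2000)]))
        assert series.values[0] == pytest.approx(100 * np.mean(ref),
                                                 rel=1e-9)


class TestRoiCoherenceSeries:
    def test_identical_channels_give_sc_100(self, matrix, rng):
        x = rng.standard_normal(int(4800 * 2.5))
        ids = [s.id for s in matrix.sensors_in_roi("dependent")]
        rec = ac.Recording(samples=np.tile(x, (len(ids), 1)), fs=4800,
                           sensor_ids=ids)
        series = ac.roi_coherence_series(rec, matrix, "dependent",
                                         prefiltered=True)
        np.testing.assert_allclose(series.values, 100.0, atol=1e-9)

    def test_common_source_roi_more_coherent_than_independent(self, matrix,
                                                              rng):
        n = int(4800 * 2.5)
        common = rng.standard_normal(n)
        dep = [s.id for s in matrix.sensors_in_roi("dependent")]
        non = [s.id for s in matrix.sensors_in_roi("nondependent")]
        samples = np.vstack(
            [np.tile(common, (len(dep), 1))
             + 0.2 * rng.standard_normal((len(dep), n)),
             rng.standard_normal((len(non), n))])
        rec = ac.Recording(samples=samples, fs=4800, sensor_ids=dep + non)
        sc_dep = ac.roi_coherence_series(rec, matrix, "dependent",
                                         prefiltered=True).values
        sc_non = ac.roi_coherence_series(rec, matrix, "nondependent",
                                         prefiltered=True).values
        assert np.all(sc_dep > sc_non)

    def test_no_pairs_raises(self, matrix, rng):
        rec = ac.Recording(samples=rng.standard_normal((2, 4800)),
                           fs=4800, sensor_ids=["L5M1", "R6M2"])
        with pytest.raises(ValueError, match="pair"):
            ac.roi_coherence_series(rec, matrix, "dependent",
                                    prefiltered=True)


class TestScDscSummary:
    def _series(self, values, insp=None):
        n = len(values)
        grid = ac.ClipGrid(clip_duration_s=0.58,
                           start_times=0.58 * np.arange(n),
                           inspiratory=np.ones(n, bool) if insp is None
                           else np.asarray(insp, bool),
                           breath=np.zeros(n, int))
        return grid.with_values(np.asarray(values, float))

    def test_constant_series_has_zero_dsc(self):
        sc, dsc = ac.sc_dsc_summary(self._series([56.0] * 6))
        assert sc == 56.0 and dsc == 0.0

    def test_hand_computed_sd_oracle(self):
        # {50,54,58,62}: mean 56, sample SD sqrt(80/3)
        sc, dsc = ac.sc_dsc_summary(self._series([50, 54, 58, 62]))
        assert sc == pytest.approx(56.0)
        assert dsc == pytest.approx(np.sqrt(80.0 / 3.0))
        _, dsc_pop = ac.sc_dsc_summary(self._series([50, 54, 58, 62]), ddof=0)
        assert dsc_pop == pytest.approx(np.sqrt(20.0))

    def test_expiratory_clips_do_not_contribute(self):
        insp = [True, False, True, False, True, True]
        base = [50, 0, 54, 0, 58, 62]
        changed = [50, 99, 54, -5, 58, 62]
        assert ac.sc_dsc_summary(self._series(base, insp)) == \
            ac.sc_dsc_summary(self._series(changed, insp))

    def test_single_inspiratory_clip_raises(self):
        with pytest.raises(ValueError):
            ac.sc_dsc_summary(self._series([50.0, 60.0],
                                           insp=[True, False]))


# --------------------------------------------------------------- aggregation

class TestRoiAggregate:
    def _grid(self, matrix, values, breath=None):
        ids = matrix.active_ids
        n = values.shape[1]
        return ac.ClipGrid(
            clip_duration_s=0.58, start_times=0.58 * np.arange(n),
            inspiratory=np.ones(n, bool),
            breath=np.zeros(n, int) if breath is None else breath,
            values=values, sensor_ids=ids)

    def test_constant_grid_returns_constant(self, matrix):
        grid = self._grid(matrix, np.full((34, 6), 3.25))
        for roi in ("global", *ct.ROIS):
            assert ac.roi_aggregate(grid, matrix, roi).value == 3.25

    def test_masking_values_in_dependent_rows_only(self, matrix):
        vals = np.zeros((34, 4))
        dep_rows = [i for i, sid in enumerate(matrix.active_ids)
                    if matrix.sensor(sid).row >= 5]
        vals[dep_rows] = 2.0
        grid = self._grid(matrix, vals)
        assert ac.roi_aggregate(grid, matrix, "dependent").value == 2.0
        assert ac.roi_aggregate(grid, matrix, "nondependent").value == 0.0

    def test_global_equals_sensor_weighted_roi_mean(self, matrix, rng):
        grid = self._grid(matrix, rng.uniform(0, 5, size=(34, 5)))
        means = {roi: ac.roi_aggregate(grid, matrix, roi).value
                 for roi in ct.ROIS}
        weights = {roi: len(matrix.sensors_in_roi(roi)) for roi in ct.ROIS}
        expected = sum(means[r] * weights[r] for r in ct.ROIS) / 34
        assert ac.roi_aggregate(grid, matrix, "global").value == \
            pytest.approx(expected, rel=1e-12)


# ----------------------------------------------------- gain equivariance law

@pytest.mark.parametrize("k", [0.1, 3.0, 42.0])
def test_gain_equivariance_of_all_parameters(matrix, rng, k):
    """Scaling the recording scales dCE by k and leaves the others fixed."""
    ids = [s.id for s in matrix.sensors_in_roi("dependent")]
    n = int(4800 * 2.5)
    base = rng.standard_normal((len(ids), n))
    rec1 = ac.Recording(samples=base, fs=4800, sensor_ids=ids,
                        breaths=[(0.0, 2.0)])
    rec2 = ac.Recording(samples=k * base, fs=4800, sensor_ids=ids,
                        breaths=[(0.0, 2.0)])
    d1 = ac.dynamic_crackle_energy(rec1).values
    d2 = ac.dynamic_crackle_energy(rec2).values
    np.testing.assert_allclose(d2, k * d1, rtol=1e-9)
    f1 = ac.fft_area_series(rec1).values
    f2 = ac.fft_area_series(rec2).values
    np.testing.assert_allclose(f1, f2, rtol=1e-9)
    s1 = ac.roi_coherence_series(rec1, matrix, "dependent").values
    s2 = ac.roi_coherence_series(rec2, matrix, "dependent").values
    np.testing.assert_allclose(s1, s2, rtol=1e-9)
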