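import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from physeter import detect, synth

FS = 200_000.0


def tone(freq_hz, dur_s=0.05, fs=FS):
    t = np.arange(int(dur_s * fs)) / fs
    return np.sin(2 * np.pi * freq_hz * t)


class TestBandpass:
    def test_passband_tone_preserved(self):
        x = tone(50_000)
        y = detect.bandpass(x, FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)  # avoid filter edge transients
        gain_db = 20 * np.log10(np.abs(y[mid]).max() / np.abs(x[mid]).max())
        assert abs(gain_db) <= 1.0

    def test_stopband_tone_attenuated(self):
        x = tone(1_000)
        y = detect.bandpass(x, FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        atten_db = -20 * np.log10(np.abs(y[mid]).max() / np.abs(x[mid]).max())
        assert atten_db >= 40.0

    def test_one_octave_stopband(self):
        x = tone(2_500)  # one octave below the 5 kHz edge
        y = detect.bandpass(x, FS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        atten_db = -20 * np.log10(np.abs(y[mid]).max() / np.abs(x[mid]).max())
        assert atten_db >= 40.0

    def test_zero_signal(self):
        assert np.allclose(detect.bandpass(np.zeros(4096), FS), 0.0)

    def test_zero_phase(self):
        # an in-band impulse must not shift
        x = np.zeros(8192)
        x[4096] = 1.0
        y = detect.bandpass(x, FS)
        assert abs(int(np.argmax(np.abs(y))) - 4096) <= 1

    @pytest.mark.parametrize("lo,hi", [(5_000, 120_000), (95_000, 5_000), (0, 95_000)])
    def test_invalid_band(self, lo, hi):
        with pytest.raises(ValueError):
            detect.bandpass(np.zeros(100), FS, lo, hi)


class TestDetectClicks:
    def test_ten_scheduled_clicks(self, small_scene, small_scene_detections):
        dets = small_scene_detections
        truth = small_scene.clicks["time_s"].to_numpy()
        assert len(dets) == len(truth) == 10
        errs = np.abs(np.array([d.time_s for d in dets]) - truth)
        assert errs.max() <= 1e-3

    def test_lockout_merges_close_pulses(self):
        # two pulses 10 ms apart: a single detection
        fs = FS
        x = np.zeros(int(0.2 * fs))
        pulse = synth.generate_multipulse_click(4.0, 1, fs)
        for t in (0.05, 0.06):
            i = int(t * fs)
            x[i : i + len(pulse)] += pulse
        dets = detect.detect_clicks(x, fs, compute_psd=False)
        assert len(dets) == 1

    def test_noise_only_scene(self):
        scene = synth.render_scene(
            synth.SceneConfig(duration_s=2.0, noise_db=90.0), seed=2
        )
        filtered = detect.bandpass(scene.waveform, scene.fs_hz)
        assert detect.detect_clicks(filtered, scene.fs_hz, compute_psd=False) == []

    def test_empty_segment(self):
        assert detect.detect_clicks(np.array([]), FS) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_lockout_property_random_scenes(self, seed):
        rng = np.random.default_rng(seed)
        fs = FS
        x = rng.normal(0, 1e-4, int(3.0 * fs))
        pulse = synth.generate_multipulse_click(4.0, 2, fs)
        for t in np.sort(rng.uniform(0.1, 2.8, 15)):  # some closer than 30 ms
            i = int(t * fs)
            x[i : i + len(pulse)] += pulse
        dets = detect.detect_clicks(x, fs, compute_psd=False)
        times = np.array([d.time_s for d in dets])
        if len(times) > 1:
            assert np.diff(times).min() >= 0.030 - 1e-9


class TestClickPsd:
    def test_tone_peak_bin(self):
        freqs, psd_db = detect.click_psd(tone(10_000, dur_s=0.01), FS)
        assert len(psd_db) == 257
        assert abs(freqs[np.argmax(psd_db)] - 10_000) <= FS / 512

    def test_white_noise_flat_on_average(self):
        rng = np.random.default_rng(0)
        acc = np.zeros(257)
        n_avg = 200
        for _ in range(n_avg):
            _, psd_db = detect.click_psd(rng.normal(size=2048), FS)
            acc += 10 ** (psd_db / 10)
        freqs = np.fft.rfftfreq(512, 1 / FS)
        avg_db = 10 * np.log10(acc / n_avg)
        band = (freqs > 5_000) & (freqs < 95_000)
        assert avg_db[band].max() - avg_db[band].min() <= 3.0

    def test_zero_snippet_floor(self):
        _, psd_db = detect.click_psd(np.zeros(2048), FS)
        assert np.all(psd_db == detect.PSD_FLOOR_DB)

    def test_short_snippet_error(self):
        with pytest.raises(ValueError, match="shorter"):
            detect.click_psd(np.zeros(100), FS)


class TestRlFilter:
    def _det(self, rl):
        return detect.ClickDetection(0.0, rl, np.zeros(8), FS)

    def test_boundary_kept(self):
        assert len(detect.rl_filter([self._det(125.0)])) == 1

    def test_below_removed(self):
        assert detect.rl_filter([self._det(124.9)]) == []

    def test_empty(self):
        assert detect.rl_filter([]) == []

    @given(
        st.lists(st.floats(100, 160), max_size=30),
        st.floats(110, 150),
        st.floats(0, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, rls, thresh, bump):
        dets = [self._det(rl) for rl in rls]
        assert len(detect.rl_filter(dets, thresh + bump)) <= len(
            detect.rl_filter(dets, thresh)
        )


class TestSpectralShapeClassify:
    def _detection_from_wave(self, wave):
        d = detect.ClickDetection(0.0, 135.0, wave, FS)
        d.freqs, d.psd_db = detect.click_psd(wave, FS)
        return d

    def test_sperm_click_accepted(self):
        w = synth.generate_multipulse_click(4.0, 3, FS, spectral_peak_hz=10_000)
        assert detect.spectral_shape_classify(self._detection_from_wave(w)) == "sperm_whale"

    def test_confuser_rejected(self):
        pulse = synth.generate_multipulse_click(4.0, 1, FS, spectral_peak_hz=40_000)
        w = np.zeros(2000)  # detector snippets are 10 ms
        w[760 : 760 + pulse.size] = pulse
        assert detect.spectral_shape_classify(self._detection_from_wave(w)) == "other"

    def test_flat_spectrum_rejected(self):
        # equal PSD everywhere: low band (15 kHz wide) < high band (70 kHz wide)
        d = detect.ClickDetection(0.0, 135.0, np.zeros(1024), FS)
        d.freqs = np.fft.rfftfreq(512, 1 / FS)
        d.psd_db = np.zeros(257)
        assert detect.spectral_shape_classify(d) == "other"


class TestLtsa:
    FS_LOW = 25_600.0

    def test_stationary_noise_columns_agree(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, int(30 * self.FS_LOW))
        _, freqs, mat = detect.ltsa(x, self.FS_LOW, 5.0, 100.0)
        assert mat.shape[1] == 6
        col_means = mat.mean(axis=0)
        assert col_means.max() - col_means.min() <= 1.0

    def test_tone_burst_elevates_cell(self):
        rng = np.random.default_rng(1)
        fs = self.FS_LOW
        x = rng.normal(0, 0.01, int(30 * fs))
        t = np.arange(int(10 * fs)) / fs
        x[int(10 * fs) : int(20 * fs)] += np.sin(2 * np.pi * 3_000 * t)
        times, freqs, mat = detect.ltsa(x, fs, 5.0, 100.0)
        fbin = np.argmin(np.abs(freqs - 3_000))
        row = mat[fbin]
        assert row[2] > row[0] + 20 and row[3] > row[0] + 20

    def test_empty_and_bad_resolution(self):
        with pytest.raises(ValueError):
            detect.ltsa(np.array([]), self.FS_LOW, 5.0, 100.0)
        with pytest.raises(ValueError):
            detect.ltsa(np.zeros(1000), self.FS_LOW, 5.0, 1.0)


class TestShipPassageDetect:
    FS = 25_600.0
    BANDS = dict(
        low_band_hz=(1_000, 5_000), med_band_hz=(5_000, 8_000), high_band_hz=(8_000, 12_000)
    )

    def _scene(self, ship, seed):
        events = [synth.ShipEvent(240.0, 300.0, level_db=95.0)] if ship else []
        cfg = synth.SceneConfig(
            fs_hz=self.FS, duration_s=600.0, noise_db=70.0, ship_events=events
        )
        scene = synth.render_scene(cfg, seed=seed)
        return detect.ltsa(scene.waveform, self.FS, 5.0, 100.0)

    def test_injected_ship_flagged(self):
        times, freqs, mat = self._scene(True, 4)
        ivs = detect.ship_passage_detect(times, freqs, mat, block_s=120.0, **self.BANDS)
        assert len(ivs) == 1
        s, e = ivs[0]
        assert s <= 240.0 and e >= 300.0
        assert e - s <= 300.0  # not over-flagged

    def test_no_ship_no_flags(self):
        times, freqs, mat = self._scene(False, 5)
        assert detect.ship_passage_detect(times, freqs, mat, block_s=120.0, **self.BANDS) == []

    def test_too_short_ltsa(self):
        with pytest.raises(ValueError):
            detect.ship_passage_detect(
                np.array([0.0, 5.0]), np.linspace(0, 12_800, 129),
                np.zeros((129, 2)), block_s=120.0,
            )


class TestEffortMask:
    def test_continuous(self):
        m = detect.EffortMask.continuous(3600.0)
        assert m.effort_s() == 3600.0

    def test_duty_cycled(self):
        m = detect.EffortMask.duty_cycled(3600.0, 600.0, 720.0)
        assert m.effort_s() == 3000.0
        assert m.status_s(detect.NO_EFFORT_DUTYCYCLE) == 600.0

    def test_ship_removal_conservation(self):
        m = detect.EffortMask.duty_cycled(7200.0, 600.0, 720.0)
        m2 = m.with_ship_intervals([(100.0, 800.0), (3000.0, 3100.0)])
        total = (
            m2.effort_s()
            + m2.status_s(detect.NO_EFFORT_SHIP)
            + m2.status_s(detect.NO_EFFORT_DUTYCYCLE)
        )
        assert total == pytest.approx(7200.0, abs=1e-6)
        assert m2.effort_s() < m.effort_s()

    @given(
        st.lists(
            st.tuples(st.floats(0, 7000), st.floats(10, 500)), min_size=0, max_size=5
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, raw_ships):
        ships = [(s, s + d) for s, d in raw_ships]
        m = detect.EffortMask.continuous(7200.0).with_ship_intervals(ships)
        total = m.effort_s() + m.status_s(detect.NO_EFFORT_SHIP)
        assert total == pytest.approx(7200.0, abs=1e-6)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            detect.EffortMask(
                [(0.0, 10.0, detect.RECORDING), (5.0, 15.0, detect.RECORDING)]
            )

    def test_contains(self):
        m = detect.EffortMask.continuous(100.0).with_ship_intervals([(10.0, 20.0)])
        assert m.contains(5.0)
        assert not m.contains(15.0)
        assert m.contains(15.0, detect.NO_EFFORT_SHIP)
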