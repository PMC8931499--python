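"""Simulator tests: burst morphology, background spectrum, segment/dataset
generation, continuous recordings, and the class-separability invariants."""

import numpy as np
import pytest
from scipy.signal import periodogram

import meghfo as m
from meghfo.preprocess import bandpass
from meghfo.synthetic import BackgroundParams, HFOEventParams


class TestBurst:
    def test_zero_amplitude_is_silent(self):
        p = HFOEventParams(center_freq=200, duration=0.05, amplitude=0.0)
        w = m.simulate_hfo_burst(p, fs=2400, seed=1)
        assert w.shape == (120,)
        assert np.all(w == 0)

    def test_length_and_spectral_peak(self):
        p = HFOEventParams(center_freq=200, duration=0.05, amplitude=3.0)
        w = m.simulate_hfo_burst(p, fs=2400, seed=7)
        assert w.size == 120
        f, P = periodogram(w, fs=2400)
        assert abs(f[np.argmax(P)] - 200) <= 10

    def test_rms_matches_amplitude_convention(self):
        p = HFOEventParams(center_freq=150, duration=0.08, amplitude=3.0)
        w = m.simulate_hfo_burst(p, fs=2400, seed=3)
        # amplitude == burst RMS over its duration (up to the cos^2 ~ 1/2
        # finite-cycle approximation)
        assert np.std(w) == pytest.approx(3.0, rel=0.05)

    def test_determinism(self):
        p = HFOEventParams()
        a = m.simulate_hfo_burst(p, 2400, seed=9)
        b = m.simulate_hfo_burst(p, 2400, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs", [dict(center_freq=50), dict(center_freq=600),
                   dict(duration=-1), dict(center_freq=100, duration=0.01)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HFOEventParams(**kwargs)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            m.simulate_hfo_burst(HFOEventParams(center_freq=400), fs=700)


class TestBackground:
    def test_degenerate_noise_is_zero(self):
        p = BackgroundParams(pink_sd=0.0, white_sd=0.0)
        assert np.all(m.simulate_background(500, 2400, p) == 0)

    def test_length_contract(self):
        assert m.simulate_background(2000, 2400).size == 2000
        with pytest.raises(ValueError):
            m.simulate_background(0, 2400)

    def test_pink_spectral_slope(self):
        """Log-periodogram of pure 1/f noise regresses to slope ~ -1."""
        x = m.simulate_background(
            8192, 2400, BackgroundParams(pink_exponent=1.0, white_sd=0.0, seed=5)
        )
        f, P = periodogram(x, fs=2400)
        band = (f >= 5) & (f <= 500)
        slope = np.polyfit(np.log(f[band]), np.log(P[band]), 1)[0]
        assert -slope == pytest.approx(1.0, abs=0.3)

    def test_band_rms_calibration(self):
        rms = [
            bandpass(m.simulate_background(2000, 2400, BackgroundParams(seed=s)),
                     fs=2400).std()
            for s in range(25)
        ]
        assert np.mean(rms) == pytest.approx(1.0, abs=0.1)


class TestSegment:
    def test_default_length(self):
        seg = m.simulate_segment(m.HFO, seed=0)
        assert len(seg.samples) == 2000
        assert seg.label == m.HFO

    def test_zero_amplitude_reduces_to_background(self):
        quiet = HFOEventParams(amplitude=0.0)
        h = m.simulate_segment(m.HFO, hfo=quiet, seed=17)
        n = m.simulate_segment(m.NC, hfo=quiet, seed=17)
        np.testing.assert_array_equal(h.samples, n.samples)

    def test_band_rms_separates_classes_on_average(self):
        strong = HFOEventParams(amplitude=3.0)
        diffs = []
        for s in range(100):
            h = m.simulate_segment(m.HFO, hfo=strong, T=1000, seed=s)
            n = m.simulate_segment(m.NC, hfo=strong, T=1000, seed=s)
            diffs.append(
                bandpass(h.samples, fs=2400).std()
                - bandpass(n.samples, fs=2400).std()
            )
        assert np.mean(diffs) > 0

    def test_burst_must_fit(self):
        with pytest.raises(ValueError):
            m.simulate_segment(m.HFO, hfo=HFOEventParams(duration=0.5), T=100)

    def test_burst_energy_is_in_band(self):
        """The added oscillation lives in 80-500 Hz, not below 70 Hz."""
        for s in range(10):
            p = HFOEventParams(
                center_freq=float(np.random.default_rng(s).uniform(90, 450))
            )
            w = m.simulate_hfo_burst(p, 2400, seed=s)
            hi = bandpass(np.pad(w, 200), fs=2400)
            lo = bandpass(np.pad(w, 200), m.FilterSpec(1.0, 70.0), fs=2400)
            assert np.sum(hi**2) > np.sum(lo**2)


class TestDataset:
    def test_requested_counts(self):
        ds = m.simulate_dataset(101, 101, HFOEventParams(center_freq=200, duration=0.04), T=200, seed=0)
        assert len(ds) == 202
        assert ds.class_counts()["HFO"] == 101
        assert ds.class_counts()["NC"] == 101

    def test_empty_dataset(self):
        ds = m.simulate_dataset(0, 0, T=200, seed=0)
        assert len(ds) == 0

    @pytest.mark.parametrize("n_hfo,n_nc", [(3, 7), (10, 0), (0, 5)])
    def test_counts_over_random_configs(self, n_hfo, n_nc):
        ds = m.simulate_dataset(n_hfo, n_nc, HFOEventParams(center_freq=200, duration=0.04), T=120, seed=n_hfo + 13 * n_nc)
        assert int(np.sum(ds.y == m.HFO)) == n_hfo
        assert int(np.sum(ds.y == m.NC)) == n_nc

    def test_determinism(self):
        a = m.simulate_dataset(5, 5, HFOEventParams(center_freq=200, duration=0.04), T=200, seed=3)
        b = m.simulate_dataset(5, 5, HFOEventParams(center_freq=200, duration=0.04), T=200, seed=3)
        np.testing.assert_array_equal(a.X, b.X)

    def test_separability_monotone_in_amplitude(self):
        """A trained detector does better at SNR 3 than at SNR 0.5."""
        accs = {}
        for amp in (0.5, 3.0):
            vals = []
            for seed in range(3):
                ds = m.preprocess_dataset(
                    m.simulate_dataset(40, 40, HFOEventParams(amplitude=amp),
                                       seed=200 + seed)
                )
                rng = np.random.default_rng(seed)
                idx = rng.permutation(len(ds))
                tr, te = idx[:60], idx[60:]
                det = m.LogisticDetector().fit(ds.X[tr], ds.y[tr])
                vals.append(np.mean(det.predict(ds.X[te]) == (ds.y[te] == m.HFO)))
            accs[amp] = np.mean(vals)
        assert accs[3.0] >= accs[0.5]


class TestRecording:
    def test_no_events_is_pure_background(self):
        rec = m.simulate_recording(1.0, [], fs=2400, seed=4)
        assert rec.event_truth == []
        assert rec.data.shape == (1, 2400)

    def test_length_arithmetic(self):
        rec = m.simulate_recording(60.0, [], fs=2400, seed=0)
        assert rec.n_samples == 144000

    def test_event_localized_by_band_rms_scan(self):
        ev = HFOEventParams(center_freq=180, duration=0.1, amplitude=5.0)
        rec = m.simulate_recording(20.0, [(10.0, ev)], fs=2400, seed=2)
        x = bandpass(rec.data[0], fs=2400)
        w = 240  # 0.1 s scan window
        c = np.cumsum(x**2)
        mov = c[w:] - c[:-w]
        t_peak = (np.argmax(mov) + w / 2) / 2400.0
        assert abs(t_peak - (10.0 + ev.duration / 2)) <= 0.1

    def test_event_beyond_end_rejected(self):
        with pytest.raises(ValueError):
            m.simulate_recording(1.0, [(0.99, HFOEventParams())], seed=0)

    def test_multichannel_independent_backgrounds(self):
        rec = m.simulate_recording(0.5, [], n_channels=2, seed=1)
        assert rec.n_channels == 2
        assert not np.allclose(rec.data[0], rec.data[1])
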