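"""Screening, notch/band filtering and clean-window selection."""

import numpy as np
import pytest

from megconn.io_core import (
    AnalysisConfig,
    BandDefinition,
    CANONICAL_BANDS,
    ParameterError,
    ScreeningError,
    SourceTimeSeries,
    band_by_name,
)
from megconn.preprocessing import (
    band_filter,
    bandpass_decompose,
    dilate_mask,
    notch_filter,
    preprocess_subject,
    screen_artifacts,
    screen_spikes,
    select_clean_window,
    usable_bands,
)


def make_ts(data, fs=300.0, subject_id="S01"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return SourceTimeSeries(
        subject_id, "control", data, fs,
        tuple(f"ch{i}" for i in range(data.shape[0])),
    )


def sinusoid(freq, fs=300.0, duration=10.0, n_channels=2):
    t = np.arange(int(duration * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))


class TestArtifactScreen:
    def test_all_zero_record_empty_mask(self):
        assert not screen_artifacts(make_ts(np.zeros((2, 100)))).any()

    def test_single_deflection_flagged_exactly(self):
        data = np.zeros((2, 500))
        data[1, 200:205] = 8.0  # 8 pT deflection on one channel
        mask = screen_artifacts(make_ts(data), amp_pT=6.0)
        assert np.flatnonzero(mask).tolist() == list(range(200, 205))

    def test_infinite_threshold_vacuous(self, rng):
        data = rng.standard_normal((3, 400))
        assert not screen_artifacts(make_ts(data), amp_pT=np.inf).any()

    def test_negative_deflections_count(self):
        data = np.zeros((2, 100))
        data[0, 50] = -7.0
        assert screen_artifacts(make_ts(data), amp_pT=6.0)[50]


class TestNotch:
    def test_mains_tone_suppressed(self):
        ts = make_ts(sinusoid(50.0))
        out = notch_filter(ts, 50.0)
        assert np.sqrt((out.data**2).mean()) < 0.1 * np.sqrt((ts.data**2).mean())

    def test_passband_tone_untouched(self):
        ts = make_ts(sinusoid(20.0))
        out = notch_filter(ts, 50.0)
        mid = slice(500, 2500)
        ratio = np.sqrt((out.data[:, mid] ** 2).mean()) / np.sqrt(
            (ts.data[:, mid] ** 2).mean()
        )
        assert abs(ratio - 1) < 0.05

    def test_zero_in_zero_out(self):
        out = notch_filter(make_ts(np.zeros((2, 1000))), 50.0)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_nyquist_violation(self):
        with pytest.raises(ParameterError):
            notch_filter(make_ts(np.zeros((2, 100)), fs=80.0), freq=50.0)


class TestSpikeScreen:
    def test_gaussian_noise_rarely_flagged(self, rng):
        data = rng.standard_normal((4, 6000))
        mask = screen_spikes(make_ts(data), z_thresh=8.0)
        assert mask.mean() < 0.001

    def test_injected_transient_flagged(self, rng):
        data = rng.standard_normal((3, 6000))
        center = 3000
        data[1, center - 15 : center + 15] += 10 * data[1].std()
        mask = screen_spikes(make_ts(data), z_thresh=8.0)
        assert mask[center]
        # dilation: ±200 ms at 300 Hz = 60 samples around the transient
        assert mask[center - 70] and mask[center + 70]

    def test_infinite_threshold_empty(self, rng):
        data = rng.standard_normal((2, 3000))
        assert not screen_spikes(make_ts(data), z_thresh=np.inf).any()

    def test_constant_record_unflagged(self):
        assert not screen_spikes(make_ts(np.ones((2, 3000)))).any()


class TestDilate:
    def test_dilation_extends_runs(self):
        mask = np.zeros(20, dtype=bool)
        mask[10] = True
        out = dilate_mask(mask, 3)
        assert np.flatnonzero(out).tolist() == list(range(7, 14))

    def test_zero_dilation_identity(self):
        mask = np.zeros(10, dtype=bool)
        mask[2] = True
        np.testing.assert_array_equal(dilate_mask(mask, 0), mask)


def brute_force_earliest_window(mask, ws):
    for start in range(len(mask) - ws + 1):
        if not mask[start : start + ws].any():
            return start
    return None


class TestCleanWindow:
    def test_clean_record_starts_at_zero(self, rng):
        ts = make_ts(rng.standard_normal((2, 6000)))
        w = select_clean_window(ts, np.zeros(6000, dtype=bool), window_s=10.0)
        assert (w.start, w.stop) == (0, 3000)

    def test_window_skips_flagged_region(self, rng):
        # artifact at t=10 s of a 120 s record; 60 s window must start after it
        fs = 50.0
        n = int(120 * fs)
        ts = make_ts(rng.standard_normal((2, n)), fs=fs)
        mask = np.zeros(n, dtype=bool)
        bad = slice(int(10 * fs) - 5, int(10 * fs) + 5)
        mask[bad] = True
        w = select_clean_window(ts, mask, window_s=60.0)
        assert w.start == bad.stop
        assert not mask[w.start : w.stop].any()

    def test_equivalent_to_brute_force_scan(self, rng):
        fs = 10.0
        n = 1000
        ts = make_ts(rng.standard_normal((2, n)), fs=fs)
        for seed in range(20):
            r = np.random.default_rng(seed)
            mask = r.uniform(size=n) < 0.01
            ws = int(20 * fs)
            expected = brute_force_earliest_window(mask, ws)
            if expected is None:
                with pytest.raises(ScreeningError):
                    select_clean_window(ts, mask, window_s=20.0)
            else:
                assert select_clean_window(ts, mask, 20.0).start == expected

    def test_contaminated_record_errors_with_subject(self, rng):
        ts = make_ts(rng.standard_normal((2, 600)), subject_id="S99")
        with pytest.raises(ScreeningError, match="S99"):
            select_clean_window(ts, np.ones(600, dtype=bool), window_s=1.0)

    def test_window_longer_than_record(self, rng):
        ts = make_ts(rng.standard_normal((2, 100)))
        with pytest.raises(ParameterError):
            select_clean_window(ts, np.zeros(100, dtype=bool), window_s=10.0)


class TestBandDecomposition:
    def _window(self, data, fs=300.0):
        ts = make_ts(data, fs=fs)
        return select_clean_window(
            ts, np.zeros(ts.n_samples, dtype=bool),
            window_s=ts.n_samples / fs,
        )

    def test_alpha_tone_lands_in_alpha(self):
        w = self._window(sinusoid(10.0))
        bandpass_decompose(w, CANONICAL_BANDS)
        mid = slice(600, 2400)
        p_in = (w.band_data["alpha"][:, mid] ** 2).mean()
        p_src = (w.data[:, mid] ** 2).mean()
        p_beta = (w.band_data["beta"][:, mid] ** 2).mean()
        assert p_in >= 0.9 * p_src
        assert p_beta < 0.05 * p_src

    def test_disjoint_tones_separate(self):
        data = sinusoid(3.0) + sinusoid(40.0)
        w = self._window(data)
        bandpass_decompose(w, CANONICAL_BANDS)
        mid = slice(600, 2400)
        for band, freq in (("delta", 3.0), ("gamma", 40.0)):
            out = w.band_data[band][:, mid]
            ref = sinusoid(freq)[:, mid]
            # band output should be essentially the matching tone alone
            assert np.sqrt(((out - ref) ** 2).mean()) < 0.1 * np.sqrt((ref**2).mean())

    def test_white_noise_band_variance_proportional_to_width(self, rng):
        fs = 1100.0
        data = rng.standard_normal((4, int(120 * fs)))
        w = self._window(data, fs=fs)
        bandpass_decompose(w, CANONICAL_BANDS)
        mid = slice(int(10 * fs), int(110 * fs))
        ratios = {
            name: w.band_data[name][:, mid].var() / band_by_name(name).width
            for name in w.band_data
        }
        assert len(ratios) == 7
        mean_ratio = np.mean(list(ratios.values()))
        for name, ratio in ratios.items():
            assert abs(ratio - mean_ratio) < 0.15 * mean_ratio, name

    def test_nyquist_violating_bands_dropped(self, rng):
        w = self._window(rng.standard_normal((2, 3000)))
        bandpass_decompose(w, CANONICAL_BANDS)  # fs=300: ripple+ dropped
        assert set(w.band_data) == {"delta", "theta", "alpha", "beta", "gamma"}
        assert usable_bands(CANONICAL_BANDS, 6000.0) == CANONICAL_BANDS

    def test_empty_band_list_rejected(self, rng):
        w = self._window(rng.standard_normal((2, 300)))
        with pytest.raises(ParameterError):
            bandpass_decompose(w, ())


class TestFilterProperties:
    def test_zero_phase_no_lag_for_inband_tone(self):
        fs = 300.0
        x = sinusoid(10.0, fs=fs, n_channels=1)
        y = band_filter(x, band_by_name("alpha"), fs)
        mid = slice(600, 2400)
        xc = np.correlate(x[0, mid], y[0, mid], mode="full")
        lag = xc.argmax() - (len(x[0, mid]) - 1)
        assert lag == 0

    def test_inband_idempotence_within_2pct(self):
        fs = 300.0
        b = band_by_name("alpha")
        x = sinusoid(10.0, fs=fs, n_channels=1)
        once = band_filter(x, b, fs)
        twice = band_filter(once, b, fs)
        mid = slice(600, 2400)
        amp1 = np.sqrt((once[:, mid] ** 2).mean())
        amp2 = np.sqrt((twice[:, mid] ** 2).mean())
        assert abs(amp2 - amp1) < 0.02 * amp1


def test_preprocess_subject_end_to_end(rng):
    config = AnalysisConfig(
        bands=tuple(band_by_name(b) for b in ("theta", "alpha", "beta")),
        fs=300.0, window_s=10.0,
    )
    data = 0.5 * rng.standard_normal((3, 6000))
    data[0, 4000] = 8.0  # artifact late in the record
    ts = make_ts(data)
    w = preprocess_subject(ts, config)
    assert w.n_samples == 3000
    assert w.stop <= 4000  # clean window avoids the artifact
    assert set(w.band_data) == {"theta", "alpha", "beta"}
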