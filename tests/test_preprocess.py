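"""Filtering, windowing, artifact screening, phase matching, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import filtfilt

from wavebp.errors import (DegenerateWindowError, ParameterError,
                           TooShortError)
from wavebp.preprocess import (FilterSpec, RawWindowPair, align_and_trim,
                               denormalize, design_bandpass, estimate_lag,
                               extract_windows, filter_ppg,
                               fit_normalization, normalize,
                               preprocess_records, screen_artifacts)
from wavebp.records import SignalRecord
from wavebp.synth import SimulationParams, simulate_cohort, simulate_record

FS = 125.0


def tone(freq, dur_s=20.0, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(int(dur_s * fs)) / fs)


class TestBandpassDesign:
    def test_taps_symmetric_and_odd(self, filter_taps):
        assert len(filter_taps) % 2 == 1
        np.testing.assert_allclose(filter_taps, filter_taps[::-1], atol=1e-12)

    def test_inband_tone_passes_within_5pct(self, filter_taps):
        y = filtfilt(filter_taps, [1.0], tone(2.0))
        steady = y[int(5 * FS):int(15 * FS)]
        assert abs(np.abs(steady).max() - 1.0) <= 0.05

    def test_stopband_tone_attenuated_20db(self, filter_taps):
        y = filtfilt(filter_taps, [1.0], tone(0.05, dur_s=60.0))
        assert np.abs(y[int(20 * FS):int(40 * FS)]).max() <= 0.1

    def test_response_has_no_transition_anomaly(self, filter_taps):
        from scipy.signal import freqz
        _, h = freqz(filter_taps, worN=16384, fs=FS)
        assert np.abs(h).max() <= 1.1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            design_bandpass(FilterSpec(pass_lo=9.0, pass_hi=8.0))
        with pytest.raises(ParameterError):
            FilterSpec(n_taps=100).validate()  # even tap count


class TestFilterPPG:
    def test_inband_signal_preserved(self, filter_taps):
        x = tone(1.5, dur_s=60.0)
        rec = SignalRecord("s", FS, x, np.full_like(x, 100.0))
        out = filter_ppg(rec, taps=filter_taps)
        core = slice(int(10 * FS), int(50 * FS))
        r = np.corrcoef(out.ppg[core], x[core])[0, 1]
        assert r > 0.99

    def test_baseline_wander_suppressed_10x(self, filter_taps):
        t = np.arange(int(60 * FS)) / FS
        wander = 0.5 * np.sin(2 * np.pi * 0.1 * t)
        x = tone(1.5, dur_s=60.0) + wander
        rec = SignalRecord("s", FS, x, np.full_like(x, 100.0))
        out = filter_ppg(rec, taps=filter_taps)

        def mag_at(sig, f):
            core = sig[int(10 * FS):int(50 * FS)]
            freqs = np.fft.rfftfreq(len(core), 1 / FS)
            return np.abs(np.fft.rfft(core))[np.argmin(np.abs(freqs - f))]

        assert mag_at(out.ppg, 0.1) <= mag_at(x, 0.1) / 10

    def test_abp_untouched(self, clean_record, filter_taps):
        out = filter_ppg(clean_record, taps=filter_taps)
        assert np.array_equal(out.abp, clean_record.abp)

    def test_zero_phase_no_lag(self, filter_taps):
        x = tone(1.5, dur_s=60.0)
        rec = SignalRecord("s", FS, x, np.full_like(x, 100.0))
        out = filter_ppg(rec, taps=filter_taps)
        s = slice(int(20 * FS), int(20 * FS) + 350)
        assert estimate_lag(out.ppg[s], x[s], max_lag=100) == 0

    def test_short_record_rejected(self, filter_taps):
        n = len(filter_taps)
        rec = SignalRecord("s", FS, np.zeros(2 * n), np.full(2 * n, 100.0))
        with pytest.raises(TooShortError):
            filter_ppg(rec, taps=filter_taps)

    def test_fs_mismatch_rejected(self, clean_record):
        with pytest.raises(ParameterError):
            filter_ppg(clean_record, FilterSpec(fs=500.0))


class TestExtractWindows:
    @pytest.mark.parametrize("n,expected_starts", [
        (350, [0]),
        (600, [0, 250]),
        (349, []),
        (850, [0, 250, 500]),
    ])
    def test_window_starts(self, n, expected_starts):
        rec = SignalRecord("s", FS, np.arange(n, dtype=float),
                           np.full(n, 100.0))
        wins = extract_windows(rec)
        assert [w.start_index for w in wins] == expected_starts
        assert all(len(w.ppg_w) == 350 for w in wins)

    @given(n=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None)
    def test_count_matches_brute_force(self, n):
        rec = SignalRecord("s", FS, np.zeros(n), np.full(n, 100.0))
        wins = extract_windows(rec)
        brute = [s for s in range(0, max(n - 350 + 1, 0), 250)]
        assert len(wins) == len(brute)
        expected = (n - 350) // 250 + 1 if n >= 350 else 0
        assert len(wins) == expected

    def test_invalid_geometry_rejected(self, clean_record):
        with pytest.raises(ParameterError):
            extract_windows(clean_record, win_len=100, overlap=100)


def _pair(ppg, abp):
    return RawWindowPair(ppg_w=np.asarray(ppg, dtype=float),
                         abp_w=np.asarray(abp, dtype=float),
                         subject_id="s", start_index=0)


class TestArtifactScreen:
    def test_flatline_abp_rejected(self, rng):
        abp = 100 + rng.normal(size=350)
        abp[100:100 + 126] = abp[100]  # > 0.5 s constant
        ok, reason = screen_artifacts(_pair(rng.normal(size=350), abp))
        assert not ok and reason == "flat-line"

    def test_out_of_range_abp_rejected(self, rng):
        abp = 100 + rng.normal(size=350)
        abp[7] = 350.0
        ok, reason = screen_artifacts(_pair(rng.normal(size=350), abp))
        assert not ok and reason == "range"

    def test_ppg_rail_rejected(self, rng):
        ppg = rng.normal(size=350)
        ppg[10:10 + 40] = ppg[10]  # > 0.25 s but < 0.5 s
        ok, reason = screen_artifacts(_pair(ppg, 100 + rng.normal(size=350)))
        assert not ok and reason == "rail"

    def test_nonfinite_rejected(self, rng):
        ppg = rng.normal(size=350)
        ppg[3] = np.nan
        ok, reason = screen_artifacts(_pair(ppg, 100 + rng.normal(size=350)))
        assert not ok and reason == "non-finite"

    def test_clean_synthetic_window_accepted(self, clean_record):
        for w in extract_windows(clean_record)[:5]:
            ok, reason = screen_artifacts(w)
            assert ok, reason


class TestEstimateLag:
    def test_identical_windows_zero_lag(self, rng):
        x = rng.normal(size=350)
        assert estimate_lag(x, x, max_lag=100) == 0

    def test_delayed_abp_gives_negative_lag(self, rng):
        x = rng.normal(size=500)
        ppg = x[100:450]
        abp = x[93:443]  # ABP carries ppg's content 7 samples later
        assert estimate_lag(ppg, abp, max_lag=100) == -7

    def test_constructed_shifts_exact_full_range(self, rng):
        x = rng.normal(size=800)
        for lag in range(-50, 51):
            ppg = x[200:550]
            abp = x[200 + lag:550 + lag]
            assert estimate_lag(ppg, abp, max_lag=125) == lag

    def test_quasi_periodic_shift_exact(self):
        rec = simulate_record(SimulationParams(duration_s=30.0, seed=4))
        x = rec.abp
        for lag in (-50, -20, 0, 20, 50):
            assert estimate_lag(x[500:850], x[500 + lag:850 + lag]) == lag

    def test_degenerate_window_raises(self):
        with pytest.raises(DegenerateWindowError):
            estimate_lag(np.ones(350), np.arange(350.0), max_lag=100)

    def test_max_lag_bound_enforced(self, rng):
        with pytest.raises(ParameterError):
            estimate_lag(rng.normal(size=350), rng.normal(size=350),
                         max_lag=200)


class TestAlignAndTrim:
    def _raw(self):
        return _pair(np.arange(350.0), 1000.0 + np.arange(350.0))

    def test_zero_lag_keeps_first_256(self):
        out = align_and_trim(self._raw(), 0)
        np.testing.assert_array_equal(out.ppg_w, np.arange(256.0))
        np.testing.assert_array_equal(out.abp_w, 1000.0 + np.arange(256.0))

    def test_lag_94_is_kept_at_exactly_256(self):
        out = align_and_trim(self._raw(), 94)
        assert out is not None
        assert len(out.ppg_w) == len(out.abp_w) == 256

    def test_lag_95_rejected(self):
        assert align_and_trim(self._raw(), 95) is None
        assert align_and_trim(self._raw(), -95) is None

    def test_positive_lag_aligns_content(self, rng):
        # ppg delayed by 10 relative to abp: lag +10 re-aligns them
        x = rng.normal(size=400)
        raw = _pair(x[0:350], x[10:360])
        out = align_and_trim(raw, 10)
        np.testing.assert_allclose(out.ppg_w, out.abp_w)


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        assert normalize(2.0, 2.0, 6.0) == 0.0
        assert normalize(6.0, 2.0, 6.0) == 1.0
        assert normalize(4.0, 2.0, 6.0) == 0.5

    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=64),
           st.floats(-100, 99), st.floats(100, 300))
    @settings(max_examples=60, deadline=None)
    def test_round_trip_identity(self, xs, lo, hi):
        x = np.asarray(xs)
        np.testing.assert_allclose(denormalize(normalize(x, lo, hi), lo, hi),
                                   x, atol=1e-9)

    def test_values_outside_range_not_clipped(self):
        assert normalize(10.0, 0.0, 5.0) == 2.0
        assert normalize(-5.0, 0.0, 5.0) == -1.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ParameterError):
            normalize(1.0, 5.0, 5.0)

    def test_fit_normalization_matches_brute_force(self, rng):
        from wavebp.preprocess import WindowPair
        pairs = [WindowPair(ppg_w=rng.normal(size=256),
                            abp_w=80 + 40 * rng.random(256),
                            lag=0, subject_id="s", start_index=i)
                 for i in range(3)]
        params = fit_normalization(pairs)
        all_ppg = np.concatenate([p.ppg_w for p in pairs])
        all_abp = np.concatenate([p.abp_w for p in pairs])
        assert params.ppg_min == min(all_ppg) and params.ppg_max == max(all_ppg)
        assert params.abp_min == min(all_abp) and params.abp_max == max(all_abp)

    def test_single_outlier_sample_defines_max(self):
        from wavebp.preprocess import WindowPair
        abp = np.full(256, 100.0)
        abp[17] = 140.0
        pair = WindowPair(ppg_w=np.linspace(0, 1, 256), abp_w=abp, lag=0,
                          subject_id="s", start_index=0)
        params = fit_normalization([pair])
        assert params.abp_min == 100.0 and params.abp_max == 140.0

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            fit_normalization([])

    def test_constant_modality_rejected(self):
        from wavebp.preprocess import WindowPair
        pair = WindowPair(ppg_w=np.ones(256), abp_w=np.full(256, 100.0),
                          lag=0, subject_id="s", start_index=0)
        with pytest.raises(DegenerateWindowError):
            fit_normalization([pair])


class TestPreprocessChain:
    def test_bookkeeping_sums(self, filter_taps):
        records = simulate_cohort(3, duration_s=40.0, seed=6)
        pairs, counts = preprocess_records(records)
        assert counts["kept"] == len(pairs)
        assert (counts["kept"] + counts["rejected_artifact"]
                + counts["rejected_length"] + counts["rejected_degenerate"]
                == counts["extracted"])
        assert all(len(p.ppg_w) == 256 and len(p.abp_w) == 256 for p in pairs)
        assert all(abs(p.lag) <= 125 for p in pairs)
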