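"""Marking precision (artifact onset) and inter-device lag estimation."""

import numpy as np
import pytest

import multisync as ms
from multisync.sync import (
    NoArtifactError,
    detect_artifact_onset,
    estimate_event_lag,
    precision_stats,
    preprocess_monitor_ecg,
    preprocess_research_ecg,
    session_precision,
    session_sync_offset,
)
from multisync.timeseries import TimeSeries


def step_epoch(onset_rel=-0.1, mark=10.0, rate=62.5, depth=1.0):
    """0 before mark+onset_rel, -depth after; spans mark +/- 1.5 s."""
    t = np.arange(mark - 1.5, mark + 1.5, 1 / rate)
    x = np.where(t >= mark + onset_rel, -depth, 0.0)
    return TimeSeries(x, rate=rate, start=t[0])


class TestArtifactOnset:
    def test_step_signal_onset_and_latency(self):
        ts = step_epoch(onset_rel=-0.1)
        onset = detect_artifact_onset(ts, mark_time=10.0)
        # one-sample quantisation of the first sample below threshold
        assert onset == pytest.approx(-0.1, abs=1.0 / 62.5)
        assert onset <= 0

    def test_translation_equivariance(self):
        a = detect_artifact_onset(step_epoch(mark=10.0), 10.0)
        shifted = step_epoch(mark=10.0)
        shifted = TimeSeries(shifted.samples, rate=shifted.rate,
                             start=shifted.start + 123.0)
        b = detect_artifact_onset(shifted, 133.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_no_negative_deflection_raises(self):
        t = np.arange(0, 3, 1 / 62.5)
        flat = TimeSeries(np.zeros(t.size), 62.5)
        with pytest.raises(NoArtifactError):
            detect_artifact_onset(flat, 1.5)

    def test_epoch_coverage_required(self):
        ts = step_epoch()
        with pytest.raises(ValueError):
            detect_artifact_onset(ts, ts.start + 0.2)

    def test_recovery_against_session_truth(self, bench_session):
        """mark - onset equals the configured marking latency within one
        IP sample plus the rule's one-sample detection delay."""
        s = bench_session
        marks = [m for m in s.monitor_events if m.marker.name == "push_button"]
        res = session_precision(s.monitor["IP"], marks)
        truth = s.truth.per_event_marking_latency
        err = res.per_event_latency - truth
        assert np.all(np.abs(err) <= 2.0 / 62.5)

    def test_onset_override_table(self, bench_session):
        s = bench_session
        marks = [m for m in s.monitor_events if m.marker.name == "push_button"]
        res = session_precision(s.monitor["IP"], marks,
                                onset_overrides={0: -0.123})
        assert res.per_event_latency[0] == pytest.approx(0.123)


class TestPrecisionStats:
    def test_constant_latencies(self):
        r = precision_stats([0.1, 0.1, 0.1])
        assert r.mean == pytest.approx(0.1)
        assert r.sd == pytest.approx(0.0, abs=1e-12)
        assert r.n_events == 3

    def test_min_max(self):
        r = precision_stats([0.04, 0.136])
        assert r.min == 0.04 and r.max == 0.136

    def test_sd_uses_n_minus_one(self):
        r = precision_stats([0.1, 0.2])
        assert r.sd == pytest.approx(np.std([0.1, 0.2], ddof=1))

    def test_session_grouping(self):
        r = precision_stats([0.1, 0.2, 0.3, 0.4],
                            sessions=["a", "a", "b", "b"])
        assert r.session_means == {"a": pytest.approx(0.15),
                                   "b": pytest.approx(0.35)}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            precision_stats([])


class TestEcgPreprocessing:
    def test_dc_rejected_by_monitor_band(self):
        ts = TimeSeries(np.full(5000, 3.3), 250.0)
        out = preprocess_monitor_ecg(ts)
        assert np.abs(out.samples[500:-500]).max() < 1e-6 * 3.3

    def test_passband_and_stopband_gains(self):
        t = np.arange(0, 20, 1 / 250)
        g25 = np.abs(preprocess_monitor_ecg(
            TimeSeries(np.sin(2 * np.pi * 25 * t), 250.0)).samples[1000:-1000]).max()
        g5 = np.abs(preprocess_monitor_ecg(
            TimeSeries(np.sin(2 * np.pi * 5 * t), 250.0)).samples[1000:-1000]).max()
        assert 0.9 <= g25 <= 1.1
        assert g5 < 0.1

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 5000))
        fa = preprocess_monitor_ecg(TimeSeries(a, 250.0)).samples
        fb = preprocess_monitor_ecg(TimeSeries(b, 250.0)).samples
        fab = preprocess_monitor_ecg(TimeSeries(a + b, 250.0)).samples
        assert np.allclose(fab, fa + fb, atol=1e-9)

    def test_research_notch_kills_mains(self):
        t = np.arange(0, 20, 1 / 2000)
        out = preprocess_research_ecg(TimeSeries(np.sin(2 * np.pi * 50 * t), 2000.0))
        assert np.abs(out.samples[1000:-1000]).max() < 0.05

    def test_research_output_rate_and_length(self):
        ts, _ = ms.simulate_ecg(10.0, 120.0, 2000.0, rng=0)
        out = preprocess_research_ecg(ts)
        assert out.rate == 250.0
        assert out.n == round(10.0 * 250)

    def test_filtering_is_deterministic(self):
        x = np.random.default_rng(5).standard_normal(20000)
        a = preprocess_research_ecg(TimeSeries(x, 2000.0)).samples
        b = preprocess_research_ecg(TimeSeries(x, 2000.0)).samples
        assert np.array_equal(a, b)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            preprocess_monitor_ecg(TimeSeries(np.zeros(100), 62.5))


class TestEventLag:
    def _ecg250(self, seed=0, duration=30.0):
        ts, _ = ms.simulate_ecg(duration, 150.0, 2000.0, rng=seed,
                                rr_jitter_frac=0.04)
        return preprocess_research_ecg(ts)

    def test_identical_series_zero_lag(self):
        a = self._ecg250()
        assert estimate_event_lag(a, a, 15.0) == 0.0

    def test_known_delay_recovered(self):
        a = self._ecg250(seed=1)
        shifted = TimeSeries(np.roll(a.samples, 25), a.rate, start=a.start)
        lag = estimate_event_lag(a, shifted, 15.0, max_lag=1.0)
        assert lag == pytest.approx(25 / 250.0, abs=1e-12)

    def test_antisymmetry(self):
        a = self._ecg250(seed=2)
        b = TimeSeries(np.roll(a.samples, 40), a.rate, start=a.start)
        assert estimate_event_lag(a, b, 15.0) == pytest.approx(
            -estimate_event_lag(b, a, 15.0), abs=1e-12)

    def test_tie_break_toward_smallest_lag(self):
        # impulse 'a'; 'b' duplicates it at 0 and +k: equal correlation peaks
        n = 2501
        a = np.zeros(n); a[n // 2] = 1.0
        b = np.zeros(n); b[n // 2] = 1.0; b[n // 2 + 100] = 1.0
        lag = estimate_event_lag(TimeSeries(a, 250.0), TimeSeries(b, 250.0),
                                 5.0, half_window=5.0, max_lag=2.0)
        assert lag == 0.0

    def test_insufficient_coverage_rejected(self):
        a = self._ecg250()
        with pytest.raises(ValueError):
            estimate_event_lag(a, a, 1.0)  # window starts before the record

    def test_session_offset_recovery(self, clinical_session):
        from multisync.sync import session_lag_analysis

        res = session_lag_analysis(clinical_session)
        truth = clinical_session.truth.inter_device_offset
        assert np.all(np.abs(res.per_event_lag - truth) <= 1.0 / 250.0)

    def test_device_mark_variant_reflects_marking_latency(self, clinical_session):
        from multisync.sync import session_lag_analysis

        res = session_lag_analysis(clinical_session, use_device_marks=True)
        lat = clinical_session.truth.per_event_marking_latency
        # lag ~ -(monitor latency - research latency): monitor content leads
        assert np.all(np.abs(np.abs(res.per_event_lag) - lat) < 0.012)


class TestSessionSyncOffset:
    def test_signed_and_absolute_means(self):
        r = session_sync_offset([0.1, -0.1])
        assert r.session_mean == pytest.approx(0.0)
        assert r.session_abs_mean == pytest.approx(0.1)

    def test_single_lag(self):
        r = session_sync_offset([0.05])
        assert r.session_mean == r.session_abs_mean == pytest.approx(0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            session_sync_offset([])
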