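"""EEG filtering, epoching, averaging, Woody alignment, vitals epochs."""

import numpy as np
import pytest

import multisync as ms
from multisync.evoked import (
    Template,
    average_epochs,
    bandpass_eeg,
    default_noxious_template,
    epoch_and_baseline,
    epoch_vitals,
    woody_align,
)
from multisync.timeseries import TimeSeries


class TestBandpassEeg:
    def test_dc_rejected(self):
        out = bandpass_eeg(TimeSeries(np.full(10000, 7.0), 500.0))
        assert np.abs(out.samples[2000:-2000]).max() < 1e-6 * 7.0

    def test_passband_and_notch_gains(self):
        t = np.arange(0, 30, 1 / 500)
        g10 = np.abs(bandpass_eeg(
            TimeSeries(np.sin(2 * np.pi * 10 * t), 500.0)).samples[3000:-3000]).max()
        g50 = np.abs(bandpass_eeg(
            TimeSeries(np.sin(2 * np.pi * 50 * t), 500.0)).samples[3000:-3000]).max()
        assert 0.9 <= g10 <= 1.1
        assert g50 < 0.05

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 8000))
        fa = bandpass_eeg(TimeSeries(a, 500.0)).samples
        fb = bandpass_eeg(TimeSeries(b, 500.0)).samples
        fab = bandpass_eeg(TimeSeries(a + b, 500.0)).samples
        assert np.allclose(fab, fa + fb, atol=1e-9)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_eeg(TimeSeries(np.zeros(500), 100.0))


class TestEpochAndBaseline:
    def test_constant_signal_gives_zero_epochs(self):
        ts = TimeSeries(np.full(2000, 4.2), 200.0)
        es = epoch_and_baseline(ts, [3.0, 6.0])
        assert np.abs(es.data).max() == 0.0

    def test_row_count_and_sample_count(self):
        ts = TimeSeries(np.zeros(2000), 200.0)
        es = epoch_and_baseline(ts, [2.0, 5.0, 8.0], pre=0.5, post=1.0)
        assert es.data.shape == (3, round(1.5 * 200) + 1)

    def test_baseline_mean_zero_per_row(self):
        rng = np.random.default_rng(2)
        ts = TimeSeries(rng.standard_normal(4000), 200.0)
        es = epoch_and_baseline(ts, [5.0, 10.0, 15.0])
        rel = es.rel_times()
        sel = rel < 0
        scale = np.abs(es.data).max()
        assert np.abs(es.data[:, sel].mean(axis=1)).max() < 1e-9 * scale

    def test_edge_event_skipped_with_warning(self):
        ts = TimeSeries(np.zeros(2000), 200.0)
        with pytest.warns(UserWarning):
            es = epoch_and_baseline(ts, [0.1, 5.0])
        assert es.n_trials == 1
        assert es.event_indices == (1,)

    def test_edge_event_raises_in_strict_mode(self):
        ts = TimeSeries(np.zeros(2000), 200.0)
        with pytest.raises(ValueError):
            epoch_and_baseline(ts, [0.1, 5.0], strict=True)

    def test_inserted_template_recovered_exactly(self):
        tpl = default_noxious_template(500.0).waveform
        eeg, _ = ms.simulate_eeg(20.0, [8.0], tpl, rate=500.0, noise_sd=0.0)
        es = epoch_and_baseline(eeg, [8.0], pre=0.5, post=1.0)
        rel = es.rel_times()
        sel = (rel >= -1e-9) & (rel <= 0.8 + 1e-9)
        assert np.allclose(es.data[0][sel], tpl.samples, atol=1e-12)


class TestAverageEpochs:
    def test_identical_trials(self):
        row = np.sin(np.linspace(0, 3, 301))
        es = ms.EpochSet(np.vstack([row] * 5), 200.0, (0.5, 1.0), None)
        assert np.allclose(average_epochs(es).samples, row)

    def test_trial_and_negation_cancel(self):
        row = np.sin(np.linspace(0, 3, 301))
        es = ms.EpochSet(np.vstack([row, -row]), 200.0, (0.5, 1.0), None)
        assert np.abs(average_epochs(es).samples).max() < 1e-12

    def test_commutes_with_baseline_correction(self):
        rng = np.random.default_rng(3)
        ts = TimeSeries(rng.standard_normal(6000), 200.0)
        events = [5.0, 12.0, 20.0]
        corrected = epoch_and_baseline(ts, events)
        raw = epoch_and_baseline(ts, events, baseline=None)
        avg_then_correct = average_epochs(raw).samples
        rel = corrected.rel_times()
        avg_then_correct = avg_then_correct - avg_then_correct[rel < 0].mean()
        correct_then_avg = average_epochs(corrected).samples
        assert np.allclose(avg_then_correct, correct_then_avg, atol=1e-12)

    def test_average_of_noisy_trials_matches_template(self):
        tpl = default_noxious_template(500.0).waveform
        times = np.arange(2.0, 202.0, 2.0)
        peak = np.abs(tpl.samples).max()
        eeg, _ = ms.simulate_eeg(205.0, times, tpl, noise_sd=peak,
                                 rate=500.0, rng=4)
        es = epoch_and_baseline(eeg, times, pre=0.5, post=1.0)
        avg = average_epochs(es)
        rel = es.rel_times()
        sel = (rel >= 0) & (rel <= 0.8)
        r = np.corrcoef(avg.samples[sel], tpl.samples)[0, 1]
        assert r > 0.95


@pytest.fixture(scope="module")
def template():
    return default_noxious_template(2000.0)


class TestWoodyAlign:
    def _epoch_with_shift(self, template, shift_samples, scale=1.0, n=3001):
        base = int(round(0.5 * 2000))
        w = template.waveform.samples
        epoch = np.zeros(n)
        epoch[base + shift_samples: base + shift_samples + w.size] = scale * w
        return epoch

    def test_epoch_equals_template(self, template):
        r = woody_align(self._epoch_with_shift(template, 0), template, 2000.0)
        assert r.shift == 0.0
        assert r.magnitude == pytest.approx(1.0)

    def test_known_delay_recovered_exactly(self, template):
        r = woody_align(self._epoch_with_shift(template, 80), template, 2000.0)
        assert r.shift == pytest.approx(0.040, abs=1e-12)

    def test_scaled_template_magnitude(self, template):
        r = woody_align(self._epoch_with_shift(template, 0, scale=2.5),
                        template, 2000.0)
        assert r.shift == 0.0
        assert r.magnitude == pytest.approx(2.5)

    @pytest.mark.parametrize("shift", [-200, -57, -1, 1, 63, 200])
    def test_every_admissible_shift_recovered(self, template, shift):
        r = woody_align(self._epoch_with_shift(template, shift),
                        template, 2000.0)
        assert r.shift == pytest.approx(shift / 2000.0, abs=1e-12)
        assert r.magnitude == pytest.approx(1.0)

    def test_out_of_bound_shift_clamps(self, template):
        r = woody_align(self._epoch_with_shift(template, 300),
                        template, 2000.0)
        assert abs(r.shift) == pytest.approx(0.1)

    def test_fitted_is_scaled_shifted_template(self, template):
        r = woody_align(self._epoch_with_shift(template, 40, scale=1.7),
                        template, 2000.0)
        nz = np.flatnonzero(r.fitted)
        w = template.waveform.samples
        expect = 1.7 * w
        assert np.allclose(r.fitted[nz], expect[np.flatnonzero(expect != 0.0)],
                           atol=1e-9)

    def test_template_longer_than_epoch_rejected(self, template):
        with pytest.raises(ValueError):
            woody_align(np.zeros(100), template, 2000.0)

    def test_jitter_recovery_from_simulated_eeg(self):
        tpl = default_noxious_template(500.0)
        times = np.arange(5.0, 45.0, 5.0)
        eeg, jit = ms.simulate_eeg(50.0, times, tpl.waveform, jitter_sd=0.02,
                                   rate=500.0, rng=6)
        es = epoch_and_baseline(eeg, times, pre=0.5, post=1.0, baseline=None)
        for row, j in zip(es.data, jit):
            r = woody_align(row, tpl, rate=500.0)
            assert r.shift == pytest.approx(j, abs=1.0 / 500.0)


class TestEpochVitals:
    def test_constant_hr_train_mode_zero(self):
        hr = TimeSeries(np.full(120, 150.0), 1.0)
        es = epoch_vitals(hr, [60.0], mode="stimulus_train")
        assert np.abs(es.data).max() == 0.0

    def test_single_lance_window_is_61_samples(self):
        hr = TimeSeries(np.full(120, 150.0), 1.0)
        es = epoch_vitals(hr, [30.0], mode="single_lance")
        assert es.data.shape == (1, 61)
        assert es.baseline is None
        assert np.all(es.data == 150.0)  # raw values, no correction

    def test_step_response_recovered(self):
        x = np.r_[np.full(30, 150.0), np.full(70, 160.0)]
        hr = TimeSeries(x, 1.0)
        es = epoch_vitals(hr, [30.0], mode="stimulus_train")
        rel = es.rel_times()
        assert es.data[0][rel >= 1].mean() == pytest.approx(10.0)

    def test_unknown_mode_rejected(self):
        hr = TimeSeries(np.full(120, 150.0), 1.0)
        with pytest.raises(ValueError):
            epoch_vitals(hr, [60.0], mode="nope")


def test_template_must_be_nonzero():
    with pytest.raises(ValueError):
        Template(waveform=TimeSeries(np.zeros(10), 100.0))
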