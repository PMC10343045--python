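"""Synchronisation assessment between two recording devices.

Two complementary measurements:

* **Marking precision** — how late an event annotation lands on the
  vital-signs-monitor recording relative to the physical event.  Measured by
  pressing a push button onto the ECG electrodes (which leaves a sharp
  negative artifact on the impedance pneumograph) and timing the artifact
  onset against the event mark: the signal around each mark is baseline
  corrected to the pre-mark mean and the onset is the earliest point where it
  drops below 3% of the post-mark minimum.

* **Inter-device lag** — the time shift between the two devices' recordings
  of the same ECG, found as the peak of the cross-correlation of 10-second
  epochs around each stimulus.  Both ECGs are first band-passed 12-40 Hz
  (research signal additionally 50 Hz notched and down-sampled to 250 Hz) so
  the sharp QRS complexes dominate the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

from .dsp import bandpass_zero_phase, notch_zero_phase, resample_to
from .timeseries import TimeSeries

__all__ = [
    "PrecisionResult",
    "LagResult",
    "NoArtifactError",
    "detect_artifact_onset",
    "precision_stats",
    "preprocess_monitor_ecg",
    "preprocess_research_ecg",
    "estimate_event_lag",
    "session_sync_offset",
]


class NoArtifactError(ValueError):
    """No negative deflection after the event mark: nothing to time."""


@dataclass(frozen=True)
class PrecisionResult:
    """Marking-precision summary over a set of push-button events."""

    per_event_latency: np.ndarray
    mean: float
    sd: float
    min: float
    max: float
    n_events: int
    session_means: dict[str, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "per_event_latency_s": [float(v) for v in self.per_event_latency],
            "mean_s": self.mean, "sd_s": self.sd,
            "min_s": self.min, "max_s": self.max, "n_events": self.n_events,
        }
        if self.session_means is not None:
            d["session_means_s"] = dict(self.session_means)
        return d


@dataclass(frozen=True)
class LagResult:
    """Per-event inter-device lags and their session summaries."""

    per_event_lag: np.ndarray
    session_mean: float
    session_abs_mean: float

    def to_dict(self) -> dict:
        return {
            "per_event_lag_s": [float(v) for v in self.per_event_lag],
            "session_mean_s": self.session_mean,
            "session_abs_mean_s": self.session_abs_mean,
        }


# ---------------------------------------------------------------------------
# Study-1 style marking precision
# ---------------------------------------------------------------------------

def detect_artifact_onset(
    ip_epoch: TimeSeries,
    mark_time: float,
    threshold_fraction: float = 0.03,
) -> float:
    """Onset of the push-button artifact, in seconds relative to the mark.

    The epoch must span [-1, +1] s around ``mark_time`` on the epoch's own
    clock.  The signal is baseline corrected to the pre-mark mean; the
    threshold is ``threshold_fraction`` times the minimum value in the second
    *after* the mark, and the onset is the earliest sample anywhere in the
    epoch at which the corrected signal falls below that threshold.  A
    negative return value means the artifact precedes the (delayed) mark,
    which is the normal case.

    Raises :class:`NoArtifactError` when the post-mark minimum is
    non-negative (no deflection to time).
    """
    if not ip_epoch.covers(mark_time - 1.0, mark_time + 1.0):
        raise ValueError("epoch must cover [-1, +1] s around the mark")
    epoch = ip_epoch.slice(mark_time - 1.0, mark_time + 1.0)
    rel = epoch.times() - mark_time
    x = epoch.samples.astype(float)
    pre = rel < 0
    x = x - x[pre].mean()
    post = (rel > 0) & (rel <= 1.0)
    post_min = x[post].min()
    if post_min >= 0:
        raise NoArtifactError(
            "no negative deflection in the 1 s after the event mark"
        )
    threshold = threshold_fraction * post_min  # negative
    below = np.flatnonzero(x < threshold)
    return float(rel[below[0]])


def precision_stats(
    latencies: Sequence[float],
    sessions: Sequence[str] | None = None,
) -> PrecisionResult:
    """Summary statistics of per-event marking latencies.

    ``sessions`` optionally labels each latency with its recording session;
    per-session mean latencies are then reported as well.  The sd uses the
    n-1 denominator (sample standard deviation).
    """
    lat = np.asarray(list(latencies), dtype=float)
    if lat.size == 0:
        raise ValueError("need at least one latency")
    session_means = None
    if sessions is not None:
        sessions = list(sessions)
        if len(sessions) != lat.size:
            raise ValueError("sessions must label every latency")
        session_means = {
            s: float(lat[[i for i, q in enumerate(sessions) if q == s]].mean())
            for s in dict.fromkeys(sessions)
        }
    sd = float(lat.std(ddof=1)) if lat.size > 1 else 0.0
    return PrecisionResult(
        per_event_latency=lat, mean=float(lat.mean()), sd=sd,
        min=float(lat.min()), max=float(lat.max()), n_events=int(lat.size),
        session_means=session_means,
    )


def session_precision(
    ip: TimeSeries,
    marks: Sequence,
    threshold_fraction: float = 0.03,
    onset_overrides: Mapping[int, float] | None = None,
) -> PrecisionResult:
    """Marking precision for one recording: latency = mark - artifact onset.

    ``marks`` are event marks (or bare times) on the IP record's clock.
    ``onset_overrides`` maps event index -> onset seconds relative to the
    mark, replacing the automatic threshold crossing for events where the
    rule needs manual adjustment.
    """
    overrides = dict(onset_overrides or {})
    latencies = []
    for i, m in enumerate(marks):
        t_mark = m.time if hasattr(m, "time") else float(m)
        if i in overrides:
            onset = float(overrides[i])
        else:
            onset = detect_artifact_onset(ip, t_mark, threshold_fraction)
        latencies.append(-onset)  # positive latency when artifact precedes mark
    return precision_stats(latencies)


# ---------------------------------------------------------------------------
# Study-2 style inter-device lag
# ---------------------------------------------------------------------------

def preprocess_monitor_ecg(ts: TimeSeries) -> TimeSeries:
    """Zero-phase 12-40 Hz band-pass; rate unchanged."""
    if ts.rate < 100:
        raise ValueError("rate must be >= 100 Hz for a 12-40 Hz band")
    return ts.with_samples(bandpass_zero_phase(ts.samples, ts.rate, 12.0, 40.0))


def preprocess_research_ecg(ts: TimeSeries, target_rate: float = 250.0) -> TimeSeries:
    """12-40 Hz band-pass, 50 Hz notch, anti-aliased resample to 250 Hz."""
    if ts.rate < target_rate:
        raise ValueError("research ECG rate must be >= the target rate")
    x = bandpass_zero_phase(ts.samples, ts.rate, 12.0, 40.0)
    x = notch_zero_phase(x, ts.rate, 50.0)
    if abs(ts.rate - target_rate) > 1e-9:
        x = resample_to(x, ts.rate, target_rate)
    return TimeSeries(x, rate=target_rate, start=ts.start,
                      label=ts.label, units=ts.units)


def _argmax_smallest_lag(c: np.ndarray, lags: np.ndarray) -> int:
    """Index of the maximum of ``c``; ties resolved toward smallest |lag|."""
    cmax = c.max()
    tol = 1e-9 * max(abs(cmax), 1e-300)
    cand = np.flatnonzero(c >= cmax - tol)
    return int(cand[np.argmin(np.abs(lags[cand]))])


def estimate_event_lag(
    ecg_a: TimeSeries,
    ecg_b: TimeSeries,
    event_time: float,
    half_window: float = 5.0,
    max_lag: float = 2.5,
) -> float:
    """Inter-device lag around one event via the cross-correlation peak.

    Both series must share a sampling rate (preprocess first).  Each is
    epoched ``half_window`` seconds either side of ``event_time`` on its own
    device clock; the lag is the shift in [-max_lag, +max_lag] maximising the
    cross-correlation of the mean-removed epochs.  Positive lag means ``b``
    lags ``a``.  Ties break toward the smallest absolute lag.
    """
    if abs(ecg_a.rate - ecg_b.rate) > 1e-6:
        raise ValueError("series must be preprocessed to a common rate")
    for ts, name in ((ecg_a, "a"), (ecg_b, "b")):
        if not ts.covers(event_time - half_window, event_time + half_window):
            raise ValueError(
                f"series {name} does not cover the +/-{half_window} s window"
            )
    ea = ecg_a.slice(event_time - half_window, event_time + half_window)
    eb = ecg_b.slice(event_time - half_window, event_time + half_window)
    xa = ea.samples - ea.samples.mean()
    xb = eb.samples - eb.samples.mean()
    rate = ecg_a.rate
    c = _sig.correlate(xb, xa, mode="full")
    lags = _sig.correlation_lags(xb.size, xa.size, mode="full") / rate
    # sub-sample start misalignment between the two slices
    lags = lags + (eb.start - ea.start)
    keep = np.abs(lags) <= max_lag + 0.5 / rate
    if not keep.any():
        raise ValueError("max_lag too small for these epochs")
    idx = _argmax_smallest_lag(c[keep], lags[keep])
    return float(lags[keep][idx])


def session_sync_offset(lags: Sequence[float]) -> LagResult:
    """Average the per-event lags of one session (signed and absolute)."""
    lag = np.asarray(list(lags), dtype=float)
    if lag.size == 0:
        raise ValueError("need at least one lag")
    return LagResult(per_event_lag=lag,
                     session_mean=float(lag.mean()),
                     session_abs_mean=float(np.abs(lag).mean()))


def session_lag_analysis(session, use_device_marks: bool = False,
                         half_window: float = 5.0,
                         max_lag: float = 2.5) -> LagResult:
    """Run the full inter-device lag assessment on a simulated session.

    With ``use_device_marks=False`` (default) both ECGs are epoched at the
    research-device mark time, so the recovered lag is the inter-device clock
    offset.  With ``use_device_marks=True`` each ECG is epoched at its own
    device's mark — the clinical procedure — and the lag instead reflects the
    difference in marking latency between the two paths (the clock offset
    cancels).
    """
    res = preprocess_research_ecg(session.research["ECG"])
    mon = preprocess_monitor_ecg(session.monitor["ECG"])
    lags = []
    for rm, mm in zip(session.research_events, session.monitor_events):
        if use_device_marks:
            # re-centre the monitor epoch on its own mark by shifting its
            # time axis so both marks coincide at t=0
            shift = mm.time - rm.time
            mon_shifted = TimeSeries(mon.samples, rate=mon.rate,
                                     start=mon.start - shift,
                                     label=mon.label, units=mon.units)
            lags.append(estimate_event_lag(res, mon_shifted, rm.time,
                                           half_window, max_lag))
        else:
            lags.append(estimate_event_lag(res, mon, rm.time,
                                           half_window, max_lag))
    return session_sync_offset(lags)
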