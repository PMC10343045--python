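"""Breath detection from impedance pneumography and windowed respiratory rate.

The impedance pneumograph (IP) is a respiration signal derived from thoracic
impedance between ECG electrodes, so each heartbeat leaks a small
cardiac-frequency component into it.  The pipeline here is:

1. :func:`remove_cardiac_interference` — low-pass the IP below the cardiac
   band, with the cutoff steered by the instantaneous cardiac frequency
   estimated from ECG R peaks.
2. :func:`detect_breaths` — an adaptive amplitude-threshold detector: the
   threshold is a configurable fraction of the running median of recent
   peak excursion amplitudes, and each breath is timed at the rising
   threshold crossing (linear-interpolated between samples).  A refractory
   period suppresses double counting.
3. :func:`windowed_rr` — respiratory rate in sliding windows (default 20 s
   window, 1 s step) as 60 / mean(inter-breath interval), with an edge-gap
   rule: if the first or last breath in a window sits more than 1.5 s from
   the window edge, that gap is included as an additional interval so that
   breathing pauses overlapping the window edge depress the rate instead of
   being ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .dsp import lowpass_zero_phase
from .timeseries import TimeSeries

__all__ = [
    "IBISequence",
    "RRSeries",
    "BreathDetectorParams",
    "remove_cardiac_interference",
    "detect_breaths",
    "windowed_rr",
]


@dataclass(frozen=True)
class IBISequence:
    """Ordered breath times and the intervals between them."""

    breath_times: np.ndarray

    def __post_init__(self) -> None:
        bt = np.asarray(self.breath_times, dtype=float)
        if bt.size > 1 and not np.all(np.diff(bt) > 0):
            raise ValueError("breath times must be strictly increasing")
        object.__setattr__(self, "breath_times", bt)

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.breath_times)

    @property
    def n_breaths(self) -> int:
        return int(self.breath_times.size)


@dataclass(frozen=True)
class RRSeries:
    """Windowed respiratory rate; undefined windows carry NaN + defined=False."""

    window_centers: np.ndarray
    rr: np.ndarray  # breaths per minute; NaN where undefined
    defined: np.ndarray  # bool mask
    window: float
    step: float


@dataclass(frozen=True)
class BreathDetectorParams:
    """Constants of the adaptive-threshold breath detector.

    threshold_frac
        Fraction of the running amplitude statistic used as the crossing
        threshold (0.4 tolerates a sudden halving of breath amplitude).
    history
        Number of recent excursion amplitudes in the running median.
    refractory
        Minimum time between breaths, seconds.
    init_window
        Seconds of signal used to seed the initial amplitude estimate.
    """

    threshold_frac: float = 0.4
    history: int = 5
    refractory: float = 0.3
    init_window: float = 15.0


def remove_cardiac_interference(ip: TimeSeries, ecg: TimeSeries) -> TimeSeries:
    """Suppress the cardiac component of the IP using the ECG as a guide.

    R peaks are detected on the ECG; the median inter-beat interval gives the
    cardiac frequency, and the IP is zero-phase low-passed below it (cutoff
    0.6 x cardiac frequency, clipped to [0.8 Hz, 0.45 x Nyquist]).  If no R
    peaks are found a fixed 1.5 Hz low-pass is applied with a warning.
    """
    if ecg.rate < ip.rate:
        raise ValueError("ECG rate must be >= IP rate")
    x = ecg.samples
    height = x.mean() + 2.0 * x.std()
    peaks, _ = _sig.find_peaks(x, height=height,
                               distance=max(int(0.25 * ecg.rate), 1))
    nyq = ip.rate / 2.0
    if peaks.size < 2:
        warnings.warn("no reliable R peaks; falling back to fixed 1.5 Hz low-pass")
        cutoff = min(1.5, 0.45 * ip.rate)
    else:
        f_cardiac = 1.0 / float(np.median(np.diff(peaks)) / ecg.rate)
        cutoff = float(np.clip(0.6 * f_cardiac, 0.8, 0.9 * nyq))
    return ip.with_samples(lowpass_zero_phase(ip.samples, ip.rate, cutoff, order=6))


def detect_breaths(ip_clean: TimeSeries,
                   params: BreathDetectorParams | None = None) -> IBISequence:
    """Adaptive amplitude-threshold breath detection.

    Scans for upward crossings of a threshold set to ``threshold_frac`` times
    the running median of the last ``history`` excursion peak amplitudes
    (seeded from the first ``init_window`` seconds).  Each breath time is the
    linear-interpolated rising crossing; crossings within the refractory
    period of the previous breath are ignored.  A flat record yields an empty
    sequence.
    """
    p = params or BreathDetectorParams()
    x = ip_clean.samples
    rate = ip_clean.rate
    n_init = min(int(p.init_window * rate), x.size)
    seed_amp = float(np.percentile(x[:n_init], 98)) if n_init else 0.0
    if seed_amp <= 0:
        seed_amp = float(x.max()) if x.max() > 0 else 0.0
    if seed_amp <= 0:
        return IBISequence(np.empty(0))

    amps: list[float] = [seed_amp]
    thr = p.threshold_frac * seed_amp
    times: list[float] = []
    i = 1
    n = x.size
    last_t = -np.inf
    while i < n:
        if x[i - 1] < thr <= x[i]:
            # rising crossing; interpolate the crossing time
            frac = (thr - x[i - 1]) / (x[i] - x[i - 1])
            t_cross = ip_clean.start + (i - 1 + frac) / rate
            # follow the excursion to its peak (until it falls back below)
            j = i
            peak = x[i]
            while j + 1 < n and x[j + 1] >= thr:
                j += 1
                peak = max(peak, x[j])
            if t_cross - last_t >= p.refractory:
                times.append(float(t_cross))
                last_t = t_cross
                amps.append(float(peak))
                amps = amps[-p.history:]
                thr = p.threshold_frac * float(np.median(amps))
            i = j + 1
        else:
            i += 1
    return IBISequence(np.asarray(times))


def windowed_rr(
    ibi: IBISequence,
    window: float = 20.0,
    step: float = 1.0,
    edge_gap: float = 1.5,
    t_start: float | None = None,
    t_end: float | None = None,
) -> RRSeries:
    """Respiratory rate in sliding windows from an inter-breath sequence.

    For each window the intervals between consecutive breaths inside it are
    collected; if the first (last) breath lies more than ``edge_gap`` seconds
    from the window start (end), that gap is prepended (appended) as an extra
    interval.  The rate is 60 / mean(intervals), in breaths per minute.
    Windows containing no breath — or one breath with both edge gaps within
    tolerance — are undefined (NaN, flagged).

    ``t_start``/``t_end`` set the span covered by the sliding windows;
    they default to the first and last breath time.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    bt = ibi.breath_times
    if t_start is None:
        t_start = float(bt[0]) if bt.size else 0.0
    if t_end is None:
        t_end = float(bt[-1]) if bt.size else 0.0
    starts = np.arange(t_start, t_end - window + 1e-9 + step, step)
    if starts.size == 0:
        starts = np.asarray([t_start])
    centers, rates, defined = [], [], []
    for w0 in starts:
        w1 = w0 + window
        centers.append(w0 + window / 2.0)
        inside = bt[(bt >= w0 - 1e-12) & (bt <= w1 + 1e-12)]
        if inside.size == 0:
            rates.append(np.nan)
            defined.append(False)
            continue
        intervals = list(np.diff(inside))
        if inside[0] - w0 > edge_gap:
            intervals.insert(0, float(inside[0] - w0))
        if w1 - inside[-1] > edge_gap:
            intervals.append(float(w1 - inside[-1]))
        if not intervals:
            rates.append(np.nan)
            defined.append(False)
            continue
        rates.append(60.0 / float(np.mean(intervals)))
        defined.append(True)
    return RRSeries(window_centers=np.asarray(centers),
                    rr=np.asarray(rates), defined=np.asarray(defined),
                    window=window, step=step)
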