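"""Stimulus-locked analysis: epoching, averaging, Woody alignment, projection.

EEG is band-passed 0.5-30 Hz with a 50 Hz notch, cut into epochs from 0.5 s
before each stimulus to 1 s after, and baseline corrected to the
pre-stimulus mean.  Single-trial noxious responses are characterised by
aligning a canonical template to the epoch within +/-100 ms (Woody
filtering) and projecting it with a scalar least-squares fit, yielding a
response magnitude.  Vital-sign numerics (1 Hz) are epoched either around a
single clinical event (-15 s to +45 s, raw values) or around stimulus trains
(-5 s to +10 s, baseline corrected).

Epoch windows include both endpoints: an epoch from ``-pre`` to ``+post``
has ``round((pre+post)*rate) + 1`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np

from .dsp import bandpass_zero_phase, notch_zero_phase
from .timeseries import TimeSeries

__all__ = [
    "EpochSet",
    "Template",
    "ProjectionResult",
    "bandpass_eeg",
    "epoch_and_baseline",
    "average_epochs",
    "woody_align",
    "epoch_vitals",
    "default_noxious_template",
]


@dataclass(frozen=True)
class EpochSet:
    """Stimulus-locked trials-by-samples matrix with window metadata."""

    data: np.ndarray  # (n_trials, n_samples)
    rate: float
    window: tuple[float, float]  # (pre, post), both positive seconds
    baseline: tuple[float, float] | None  # relative to stimulus, or None
    channel: str = ""
    event_indices: tuple[int, ...] = ()

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def rel_times(self) -> np.ndarray:
        pre, post = self.window
        return -pre + np.arange(self.data.shape[1]) / self.rate


@dataclass(frozen=True)
class Template:
    """A canonical evoked waveform with its support relative to the stimulus."""

    waveform: TimeSeries
    support: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not np.any(self.waveform.samples):
            raise ValueError("template waveform must be nonzero")


@dataclass(frozen=True)
class ProjectionResult:
    """Woody-aligned template fit: latency shift, magnitude, fitted trace."""

    shift: float
    magnitude: float
    fitted: np.ndarray


def bandpass_eeg(ts: TimeSeries) -> TimeSeries:
    """Zero-phase 0.5-30 Hz band-pass with a 50 Hz notch."""
    if ts.rate <= 100:
        raise ValueError("EEG rate must exceed 100 Hz")
    x = bandpass_zero_phase(ts.samples, ts.rate, 0.5, 30.0)
    x = notch_zero_phase(x, ts.rate, 50.0)
    return ts.with_samples(x)


def _event_times(events: Sequence) -> list[float]:
    return [e.time if hasattr(e, "time") else float(e) for e in events]


def epoch_and_baseline(
    ts: TimeSeries,
    events: Sequence,
    pre: float = 0.5,
    post: float = 1.0,
    baseline: tuple[float, float] | None = "pre",
    channel: str | None = None,
    strict: bool = False,
) -> EpochSet:
    """Cut stimulus-locked epochs and subtract the baseline mean per trial.

    ``baseline="pre"`` (default) uses the full pre-stimulus interval
    ``[-pre, 0)``; an explicit ``(from, to)`` pair or ``None`` (no
    correction) is also accepted.  Events whose window falls outside the
    record are skipped with a warning, or raise in strict mode.
    """
    times = _event_times(events)
    n_samp = int(round((pre + post) * ts.rate)) + 1
    if baseline == "pre":
        baseline = (-pre, 0.0)
    if baseline is not None:
        if baseline[0] < -pre - 1e-9 or baseline[1] > post + 1e-9:
            raise ValueError("baseline interval must lie within the window")
    rows, kept = [], []
    rel = -pre + np.arange(n_samp) / ts.rate
    for i, t0 in enumerate(times):
        i0 = int(round((t0 - pre - ts.start) * ts.rate))
        if i0 < 0 or i0 + n_samp > ts.n:
            msg = f"event {i} at t={t0:.3f}s too near the record edge; skipped"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
            continue
        row = ts.samples[i0:i0 + n_samp].astype(float)
        if baseline is not None:
            # half-open [from, to): the sample at the stimulus itself is post
            sel = (rel >= baseline[0] - 1e-9) & (rel < baseline[1] - 1e-9)
            row = row - row[sel].mean()
        rows.append(row)
        kept.append(i)
    if not rows:
        raise ValueError("no event produced a valid epoch")
    return EpochSet(data=np.vstack(rows), rate=ts.rate, window=(pre, post),
                    baseline=baseline, channel=channel or ts.label,
                    event_indices=tuple(kept))


def average_epochs(es: EpochSet) -> TimeSeries:
    """Point-wise mean across trials (the classical evoked average)."""
    if es.n_trials < 1:
        raise ValueError("need at least one trial")
    return TimeSeries(es.data.mean(axis=0), rate=es.rate, start=-es.window[0],
                      label=f"{es.channel}_avg" if es.channel else "avg")


def woody_align(
    epoch: np.ndarray,
    template: Template,
    rate: float,
    max_shift: float = 0.1,
    epoch_window: tuple[float, float] = (0.5, 1.0),
) -> ProjectionResult:
    """Align a template to a single trial within a bounded latency shift.

    The template, nominally occupying its support interval relative to the
    stimulus, is slid over integer-sample shifts in [-max_shift, +max_shift];
    the shift maximising the normalised cross-correlation wins (ties toward
    the smallest |shift|).  The magnitude is the scalar least-squares
    coefficient regressing the shifted template onto the epoch over the
    template support.  ``fitted`` is the magnitude-scaled template placed in
    an array the size of the epoch.
    """
    epoch = np.asarray(epoch, dtype=float)
    w = template.waveform.samples
    if abs(template.waveform.rate - rate) > 1e-9:
        raise ValueError("template rate must match the epoch rate")
    if w.size > epoch.size:
        raise ValueError("template longer than epoch")
    pre, _post = epoch_window
    base = int(round((template.support[0] + pre) * rate))
    s_max = int(round(max_shift * rate))
    shifts = np.arange(-s_max, s_max + 1)
    ok = (base + shifts >= 0) & (base + shifts + w.size <= epoch.size)
    if not ok.any():
        raise ValueError("template support does not fit inside the epoch")
    shifts = shifts[ok]
    wn = w - w.mean()
    denom_w = float(np.sqrt((wn ** 2).sum()))
    scores = np.empty(shifts.size)
    for k, s in enumerate(shifts):
        seg = epoch[base + s: base + s + w.size]
        segn = seg - seg.mean()
        denom = denom_w * float(np.sqrt((segn ** 2).sum()))
        scores[k] = (segn @ wn) / denom if denom > 0 else -np.inf
    cmax = scores.max()
    cand = np.flatnonzero(scores >= cmax - 1e-12 * max(abs(cmax), 1e-300))
    best = int(cand[np.argmin(np.abs(shifts[cand]))])
    s = int(shifts[best])
    seg = epoch[base + s: base + s + w.size]
    magnitude = float((seg @ w) / (w @ w))
    fitted = np.zeros_like(epoch)
    fitted[base + s: base + s + w.size] = magnitude * w
    return ProjectionResult(shift=s / rate, magnitude=magnitude, fitted=fitted)


def epoch_vitals(
    numeric: TimeSeries,
    events: Sequence,
    mode: str,
    strict: bool = False,
) -> EpochSet:
    """Epoch 1 Hz vital-sign numerics around clinical or train stimuli.

    ``mode="single_lance"``: one-minute epoch starting 15 s before the event,
    raw values (no baseline subtraction).  ``mode="stimulus_train"``: -5 s to
    +10 s, baseline corrected by subtracting the pre-stimulus mean.
    """
    if mode == "single_lance":
        return epoch_and_baseline(numeric, events, pre=15.0, post=45.0,
                                  baseline=None, strict=strict)
    if mode == "stimulus_train":
        return epoch_and_baseline(numeric, events, pre=5.0, post=10.0,
                                  baseline="pre", strict=strict)
    raise ValueError(f"unknown mode {mode!r}")


def default_noxious_template(rate: float = 2000.0,
                             support: tuple[float, float] = (0.0, 0.8)) -> Template:
    """Packaged synthetic noxious-evoked template (damped biphasic wave).

    A stand-in morphology — a negative deflection near 400 ms followed by a
    broad positive rebound, tapered to zero at both ends — exercising the
    alignment/projection machinery.  Any user-supplied waveform can be used
    in its place.  The default support (0-0.8 s) leaves head-room for the
    full +/-100 ms alignment range inside a -0.5 to +1 s epoch.
    """
    t0, t1 = support
    n = int(round((t1 - t0) * rate)) + 1
    t = np.linspace(t0, t1, n)
    wave = (-1.0 * np.exp(-0.5 * ((t - 0.40) / 0.05) ** 2)
            + 0.6 * np.exp(-0.5 * ((t - 0.56) / 0.09) ** 2))
    taper = np.sin(np.pi * (t - t0) / (t1 - t0)) ** 2
    wave = wave * taper
    ts = TimeSeries(wave, rate=rate, start=t0, label="noxious_template",
                    units="uV")
    return Template(waveform=ts, support=support)
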