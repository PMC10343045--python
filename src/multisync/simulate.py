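"""Synthetic dual-device acquisition sessions with known ground truth.

The generator emulates the data-flow of a cot-side multimodal rig: one
research-grade electrophysiology amplifier (EEG + ECG at 2000 Hz) and one
vital-signs monitor whose channels (ECG 250 Hz, impedance pneumograph
62.5 Hz, PPG 125 Hz, heart rate and SpO2 numerics at 1 Hz) are derived from
the same physiological source, band-limited by the monitor's inbuilt
filtering, and recorded on a clock offset from the research device.  Stimulus
triggers are stamped onto both timelines through per-device marking-latency
models, and every hidden quantity (R-peak times, breath times, per-event
marking latency, the clock offset) is returned as ground truth so downstream
estimators can be scored without re-simulation.

Morphology is deliberately schematic — sums of Gaussian bumps for ECG/PPG,
raised cosines for breaths — because none of the analyses here depend on
clinical waveform detail, only on timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .dsp import bandpass_zero_phase, resample_to
from .events import (
    ClockLatencyModel,
    EventMark,
    MONITOR_CLOCK_DEFAULT,
    RESEARCH_CLOCK_DEFAULT,
    bridge_trigger,
)
from .timeseries import TimeSeries

__all__ = [
    "SessionConfig",
    "SessionTruth",
    "Session",
    "simulate_ecg",
    "simulate_ip",
    "inject_pushbutton_artifact",
    "simulate_eeg",
    "simulate_session",
]


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _gaussian_bumps(t: np.ndarray, centers: np.ndarray, amp: float,
                    sigma: float, out: np.ndarray, rate: float) -> None:
    """Add ``amp * exp(-((t-c)/sigma)^2 / 2)`` for each center, in place."""
    half = int(np.ceil(5 * sigma * rate))
    n = t.size
    for c in centers:
        i0 = max(int(np.floor((c - t[0]) * rate)) - half, 0)
        i1 = min(i0 + 2 * half + 1, n)
        if i1 <= i0:
            continue
        seg = t[i0:i1]
        out[i0:i1] += amp * np.exp(-0.5 * ((seg - c) / sigma) ** 2)


def _beat_times(duration: float, heart_rate, rr_jitter_frac: float,
                rng: np.random.Generator) -> np.ndarray:
    """Beat schedule from a bpm profile (scalar or callable of time)."""
    hr_fn: Callable[[float], float]
    if callable(heart_rate):
        hr_fn = heart_rate
    else:
        hr0 = float(heart_rate)
        hr_fn = lambda _t: hr0
    times = []
    t = 0.3  # first beat shortly after record start
    while t < duration:
        hr = hr_fn(t)
        if not (30.0 < hr < 250.0):
            raise ValueError(f"heart rate {hr} bpm outside (30, 250)")
        times.append(t)
        rr = 60.0 / hr
        if rr_jitter_frac > 0:
            rr *= 1.0 + rr_jitter_frac * float(rng.standard_normal())
            rr = max(rr, 0.24)  # physiological ceiling 250 bpm
        t += rr
    return np.asarray(times)


def simulate_ecg(
    duration: float,
    heart_rate: float | Callable[[float], float] = 120.0,
    rate: float = 2000.0,
    rng: np.random.Generator | int | None = 0,
    rr_jitter_frac: float = 0.0,
    noise_sd: float = 0.0,
    label: str = "ECG",
) -> tuple[TimeSeries, np.ndarray]:
    """Quasi-periodic ECG-like waveform with one dominant R peak per beat.

    Each beat is a sum of Gaussian bumps (dominant R, smaller P and T).
    ``heart_rate`` may be a constant in bpm or a callable ``bpm(t)``;
    ``rr_jitter_frac`` adds multiplicative beat-to-beat RR variability.

    Returns the series and the R-peak times (the ground truth).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r_peaks = _beat_times(duration, heart_rate, rr_jitter_frac, rng)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    # R is tall and narrow so it survives the 12-40 Hz sync band; P/T are
    # broad low-frequency bumps placed as fractions of the local RR.
    rr_local = np.diff(r_peaks, append=r_peaks[-1] + np.median(np.diff(r_peaks))
                       if r_peaks.size > 1 else r_peaks[-1] + 0.5)
    _gaussian_bumps(t, r_peaks, 1.0, 0.010, x, rate)
    _gaussian_bumps(t, r_peaks - 0.25 * rr_local, 0.12, 0.025, x, rate)
    _gaussian_bumps(t, r_peaks + 0.35 * rr_local, 0.25, 0.050, x, rate)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return TimeSeries(x, rate=rate, label=label, units="a.u."), r_peaks


# ---------------------------------------------------------------------------
# Impedance pneumograph
# ---------------------------------------------------------------------------

def simulate_ip(
    duration: float,
    breath_times: Sequence[float],
    rate: float = 62.5,
    cardiac_gain: float = 0.0,
    r_peak_times: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = 0,
    breath_width: float = 1.2,
    breath_amplitude: float | Sequence[float] = 1.0,
    label: str = "IP",
) -> TimeSeries:
    """Impedance-pneumograph signal: one raised-cosine excursion per breath.

    Each breath time marks the *onset* of a smooth positive excursion of
    duration ``breath_width``.  ``cardiac_gain`` adds a small bump at each
    R-peak time (the cardiac interference that leaks into thoracic impedance);
    ``noise_sd`` adds white noise.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    breath_times = np.asarray(breath_times, dtype=float)
    if breath_times.size and (breath_times.min() < 0 or breath_times.max() > duration):
        raise ValueError("breath times must lie within [0, duration]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    amps = np.broadcast_to(np.asarray(breath_amplitude, dtype=float),
                           breath_times.shape)
    for tb, a in zip(breath_times, amps):
        i0 = max(int(np.floor(tb * rate)), 0)
        i1 = min(int(np.ceil((tb + breath_width) * rate)) + 1, n)
        if i1 <= i0:
            continue
        u = (t[i0:i1] - tb) / breath_width
        seg = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(u, 0.0, 1.0)))
        x[i0:i1] += a * seg
    if cardiac_gain != 0.0 and r_peak_times is not None:
        _gaussian_bumps(t, np.asarray(r_peak_times, dtype=float),
                        cardiac_gain, 0.04, x, rate)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return TimeSeries(x, rate=rate, label=label, units="a.u.")


def inject_pushbutton_artifact(
    ip: TimeSeries,
    press_time: float,
    depth: float = 5.0,
    width: float = 0.5,
) -> TimeSeries:
    """Add the negative deflection a push-button press leaves on the IP trace.

    The deflection is a negative half-sine starting exactly at ``press_time``
    (device clock), reaching ``-depth`` at its midpoint and recovering after
    ``width`` seconds.  The onset sample is ``floor((press_time-start)*rate)``.
    """
    if not (ip.start <= press_time < ip.end):
        raise ValueError(
            f"press_time {press_time} outside record [{ip.start}, {ip.end})"
        )
    if depth == 0:
        return ip.with_samples(ip.samples.copy())
    x = ip.samples.copy()
    t = ip.times()
    i0 = ip.index_at(press_time)
    i1 = min(int(np.ceil((press_time + width - ip.start) * ip.rate)) + 1, ip.n)
    u = (t[i0:i1] - press_time) / width
    x[i0:i1] -= depth * np.sin(np.pi * np.clip(u, 0.0, 1.0))
    return ip.with_samples(x)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def simulate_eeg(
    duration: float,
    stimulus_times: Sequence[float],
    template: TimeSeries,
    jitter_sd: float = 0.0,
    amplitude_scales: float | Sequence[float] = 1.0,
    noise_sd: float = 0.0,
    rate: float = 2000.0,
    rng: np.random.Generator | int | None = 0,
    label: str = "EEG",
) -> tuple[TimeSeries, np.ndarray]:
    """Background noise plus a stimulus-locked template at each event.

    The template is inserted starting at ``stimulus_time + jitter`` where the
    per-trial jitter is N(0, jitter_sd) rounded to the sample grid.  Returns
    the series and the realised jitters (ground truth for latency recovery).

    Raises if consecutive insertions would overlap.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if abs(template.rate - rate) > 1e-9:
        raise ValueError("template rate must match the EEG rate")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    stimulus_times = np.asarray(stimulus_times, dtype=float)
    n = int(round(duration * rate))
    x = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
    jitters = (jitter_sd * rng.standard_normal(stimulus_times.size)
               if jitter_sd > 0 else np.zeros(stimulus_times.size))
    jitters = np.round(jitters * rate) / rate  # realised on the sample grid
    m = template.samples.size
    starts = np.round((stimulus_times + jitters) * rate).astype(int)
    order = np.argsort(starts)
    for a, b in zip(starts[order][:-1], starts[order][1:]):
        if b < a + m:
            raise ValueError("template insertions overlap; space the stimuli")
    scales = np.broadcast_to(np.asarray(amplitude_scales, dtype=float),
                             stimulus_times.shape)
    for i0, sc in zip(starts, scales):
        if i0 < 0 or i0 + m > n:
            raise ValueError("template insertion extends outside the record")
        x[i0:i0 + m] += sc * template.samples
    return TimeSeries(x, rate=rate, label=label, units="uV"), jitters


# ---------------------------------------------------------------------------
# Whole session
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionConfig:
    """Study conditions for one simulated dual-device session.

    Defaults reproduce the acquisition set-up the package targets: a 2000 Hz
    research amplifier, monitor channels at 250/125/62.5/1 Hz, an infant-like
    heart rate of 150 bpm with mild beat-to-beat variability, breathing every
    1.5 s, and the empirical marking-latency model (mean 105 ms, sd 19 ms) on
    the monitor path versus 0.5 ms on the research path.
    """

    duration: float = 60.0
    research_rate: float = 2000.0
    monitor_ecg_rate: float = 250.0
    ip_rate: float = 62.5
    ppg_rate: float = 125.0
    numerics_rate: float = 1.0
    heart_rate: float = 150.0
    rr_jitter_frac: float = 0.03
    breath_period: float = 1.5
    breath_jitter_frac: float = 0.05
    breath_width: float = 1.2
    stimulus_times: tuple[float, ...] = ()
    press_times: tuple[float, ...] = ()
    stimulus_marker: str = "visual"
    inter_device_offset: float = 0.0
    research_clock: ClockLatencyModel = RESEARCH_CLOCK_DEFAULT
    monitor_clock: ClockLatencyModel = MONITOR_CLOCK_DEFAULT
    ip_cardiac_gain: float = 0.15
    ip_breath_amplitude: float = 1.0  # 0 emulates a bench (no-infant) recording
    ip_noise_sd: float = 0.02
    ecg_noise_sd: float = 0.01
    eeg_noise_sd: float = 1.0
    eeg_jitter_sd: float = 0.0
    press_depth: float = 5.0
    press_width: float = 0.5
    eeg_channels: tuple[str, ...] = ("Cz", "Oz")


@dataclass(frozen=True)
class SessionTruth:
    """Everything the simulator knows that the analyses must estimate."""

    stimulus_times: np.ndarray
    press_times: np.ndarray
    breath_times: np.ndarray
    r_peak_times: np.ndarray
    inter_device_offset: float
    per_event_marking_latency: np.ndarray  # monitor-path latency per trigger
    eeg_jitters: np.ndarray
    trigger_times: np.ndarray  # all triggers (stimuli + presses), sorted


@dataclass(frozen=True)
class Session:
    research: Mapping[str, TimeSeries]
    monitor: Mapping[str, TimeSeries]
    research_events: list[EventMark]
    monitor_events: list[EventMark]
    truth: SessionTruth
    config: SessionConfig


def _breath_schedule(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    times = []
    t = 0.5
    while t < cfg.duration - cfg.breath_width:
        times.append(t)
        period = cfg.breath_period
        if cfg.breath_jitter_frac > 0:
            period *= 1.0 + cfg.breath_jitter_frac * float(rng.standard_normal())
        t += max(period, 0.5)
    return np.asarray(times)


def _monitor_mode_filter(x: np.ndarray, rate: float) -> np.ndarray:
    """Approximation of the monitor's inbuilt ECG band limit (0.5-40 Hz)."""
    return bandpass_zero_phase(x, rate, 0.5, 40.0, order=2)


def simulate_session(config: SessionConfig | None = None,
                     rng_seed: int = 0) -> Session:
    """Compose the generators into one dual-device session.

    The monitor channels are derived from the same research-grade sources
    (anti-aliased resampling, then the monitor's nominal band limit) and sit
    on a clock shifted by ``inter_device_offset``; triggers are stamped onto
    both timelines through the configured clock/latency models.
    """
    cfg = config or SessionConfig()
    ss = np.random.SeedSequence(rng_seed)
    (s_ecg, s_breath, s_ip, s_eeg, s_lat, s_num) = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]

    # research-grade sources (device clock == true time)
    ecg_res, r_peaks = simulate_ecg(
        cfg.duration, cfg.heart_rate, cfg.research_rate, s_ecg,
        rr_jitter_frac=cfg.rr_jitter_frac, noise_sd=cfg.ecg_noise_sd,
    )
    from .evoked import default_noxious_template  # local import: avoid cycle
    template = default_noxious_template(rate=cfg.research_rate).waveform
    if cfg.stimulus_times:
        eeg_raw, jitters = simulate_eeg(
            cfg.duration, cfg.stimulus_times, template,
            jitter_sd=cfg.eeg_jitter_sd, noise_sd=cfg.eeg_noise_sd,
            rate=cfg.research_rate, rng=s_eeg,
        )
    else:
        n = int(round(cfg.duration * cfg.research_rate))
        eeg_raw = TimeSeries(cfg.eeg_noise_sd * s_eeg.standard_normal(n)
                             if cfg.eeg_noise_sd > 0 else np.zeros(n),
                             rate=cfg.research_rate, label="EEG", units="uV")
        jitters = np.zeros(0)
    research: dict[str, TimeSeries] = {"ECG": ecg_res}
    for ch in cfg.eeg_channels:
        research[ch] = TimeSeries(eeg_raw.samples, rate=cfg.research_rate,
                                  label=ch, units="uV")

    offset = cfg.inter_device_offset
    mon_clock = ClockLatencyModel(
        offset=offset, drift=cfg.monitor_clock.drift,
        latency_mean=cfg.monitor_clock.latency_mean,
        latency_sd=cfg.monitor_clock.latency_sd,
        latency_floor=cfg.monitor_clock.latency_floor,
    )

    # monitor channels: same sources, resampled/filtered, clock shifted
    ecg_mon = resample_to(ecg_res.samples, cfg.research_rate, cfg.monitor_ecg_rate)
    ecg_mon = _monitor_mode_filter(ecg_mon, cfg.monitor_ecg_rate)
    monitor: dict[str, TimeSeries] = {
        "ECG": TimeSeries(ecg_mon, rate=cfg.monitor_ecg_rate, start=offset,
                          label="ECG", units="a.u."),
    }

    if cfg.ip_breath_amplitude > 0:
        breath_times = _breath_schedule(cfg, s_breath)
    else:  # bench recording: electrodes not on an infant, no respiration
        breath_times = np.empty(0)
    ip = simulate_ip(cfg.duration, breath_times, cfg.ip_rate,
                     cardiac_gain=cfg.ip_cardiac_gain, r_peak_times=r_peaks,
                     noise_sd=cfg.ip_noise_sd, rng=s_ip,
                     breath_width=cfg.breath_width,
                     breath_amplitude=cfg.ip_breath_amplitude)
    ip = TimeSeries(ip.samples, rate=cfg.ip_rate, start=offset,
                    label="IP", units="a.u.")
    for tp in cfg.press_times:
        ip = inject_pushbutton_artifact(ip, tp + offset,
                                        depth=cfg.press_depth,
                                        width=cfg.press_width)
    monitor["IP"] = ip

    # PPG: pulse wave ~200 ms after each R peak
    n_ppg = int(round(cfg.duration * cfg.ppg_rate))
    t_ppg = np.arange(n_ppg) / cfg.ppg_rate
    ppg = np.zeros(n_ppg)
    _gaussian_bumps(t_ppg, r_peaks + 0.2, 1.0, 0.08, ppg, cfg.ppg_rate)
    monitor["PPG"] = TimeSeries(ppg, rate=cfg.ppg_rate, start=offset,
                                label="PPG", units="a.u.")

    # 1 Hz numerics from the beat schedule
    n_num = int(round(cfg.duration * cfg.numerics_rate))
    t_num = np.arange(n_num) / cfg.numerics_rate
    if r_peaks.size > 1:
        inst_hr = 60.0 / np.diff(r_peaks)
        hr = np.interp(t_num, r_peaks[1:], inst_hr)
    else:
        hr = np.full(n_num, cfg.heart_rate)
    spo2 = 97.0 + 0.3 * s_num.standard_normal(n_num)
    monitor["HR"] = TimeSeries(hr, rate=cfg.numerics_rate, start=offset,
                               label="HR", units="bpm")
    monitor["SpO2"] = TimeSeries(spo2, rate=cfg.numerics_rate, start=offset,
                                 label="SpO2", units="%")

    # stamp every trigger onto both timelines
    triggers = sorted(
        [(t, cfg.stimulus_marker) for t in cfg.stimulus_times]
        + [(t, "push_button") for t in cfg.press_times]
    )
    research_events, monitor_events, latencies = [], [], []
    for t0, mk in triggers:
        rm, mm = bridge_trigger(t0, cfg.research_clock, mon_clock,
                                rng=s_lat, marker=mk)
        research_events.append(rm)
        monitor_events.append(mm)
        latencies.append(mm.time - offset - t0)

    truth = SessionTruth(
        stimulus_times=np.asarray(cfg.stimulus_times, dtype=float),
        press_times=np.asarray(cfg.press_times, dtype=float),
        breath_times=breath_times,
        r_peak_times=r_peaks,
        inter_device_offset=offset,
        per_event_marking_latency=np.asarray(latencies),
        eeg_jitters=jitters,
        trigger_times=np.asarray([t for t, _ in triggers]),
    )
    return Session(research=research, monitor=monitor,
                   research_events=research_events,
                   monitor_events=monitor_events, truth=truth, config=cfg)
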