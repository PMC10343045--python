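"""Reproducible end-to-end runs: validated config, staged execution, report.

A run simulates (or loads) a dual-device session, then executes the
requested analysis stages; everything it writes is derived from the config
and the seed, so re-running with the recorded config reproduces the outputs
(report timing fields aside).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .events import write_events_json
from .evoked import (
    average_epochs,
    bandpass_eeg,
    default_noxious_template,
    epoch_and_baseline,
    woody_align,
)
from .io import write_signals_csv
from .respiration import detect_breaths, remove_cardiac_interference, windowed_rr
from .simulate import SessionConfig, simulate_session
from .sync import session_lag_analysis, session_precision
from .timeseries import TimeSeries

STAGES = ("simulate", "precision", "sync", "evoked", "resp")


class SessionParams(BaseModel):
    """Simulation parameters exposed through the run config."""

    model_config = ConfigDict(extra="forbid")

    duration: float = Field(60.0, gt=0)
    heart_rate: float = Field(150.0, gt=30, lt=250)
    rr_jitter_frac: float = Field(0.03, ge=0)
    breath_period: float = Field(1.5, gt=0)
    inter_device_offset: float = 0.0
    stimulus_times: list[float] = [15.0, 27.0, 39.0]
    press_times: list[float] = [20.0, 33.0, 46.0]
    eeg_noise_sd: float = Field(1.0, ge=0)
    ip_noise_sd: float = Field(0.02, ge=0)
    ip_breath_amplitude: float = Field(1.0, ge=0)  # 0 = bench recording
    marking_latency_mean: float = Field(0.105, ge=0)
    marking_latency_sd: float = Field(0.019, ge=0)

    def to_session_config(self) -> SessionConfig:
        from .events import ClockLatencyModel

        return SessionConfig(
            duration=self.duration,
            heart_rate=self.heart_rate,
            rr_jitter_frac=self.rr_jitter_frac,
            breath_period=self.breath_period,
            inter_device_offset=self.inter_device_offset,
            stimulus_times=tuple(self.stimulus_times),
            press_times=tuple(self.press_times),
            eeg_noise_sd=self.eeg_noise_sd,
            ip_noise_sd=self.ip_noise_sd,
            ip_breath_amplitude=self.ip_breath_amplitude,
            monitor_clock=ClockLatencyModel(
                latency_mean=self.marking_latency_mean,
                latency_sd=self.marking_latency_sd,
            ),
        )


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: Path = Path("multisync_out")
    strict: bool = False
    stages: list[Literal["simulate", "precision", "sync", "evoked", "resp"]] = (
        list(STAGES)
    )
    session: SessionParams = SessionParams()
    precision_threshold: float = Field(0.03, gt=0, lt=1)
    rr_window: float = Field(20.0, gt=0)
    rr_step: float = Field(1.0, gt=0)
    rr_edge_gap: float = Field(1.5, ge=0)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a versioned JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.loads(config.model_dump_json())
    report: dict = {
        "report_version": 1,
        "package_version": __version__,
        "config": cfg_json,
        # hash over everything that determines the outputs (not where they go)
        "config_hash": _hash_obj({k: v for k, v in cfg_json.items()
                                  if k != "out_dir"}),
        "stages": {},
    }
    session = None

    def stage(name):
        def deco(fn):
            if name not in config.stages:
                return None
            t0 = time.perf_counter()
            entry: dict = {"status": "ok"}
            try:
                entry["outputs"] = fn()
            except Exception as exc:  # noqa: BLE001 - reported, then re-raised
                entry["status"] = "failed"
                entry["error"] = f"{type(exc).__name__}: {exc}"
                report["stages"][name] = entry
                _write_report(report, out)
                raise
            entry["elapsed_s"] = round(time.perf_counter() - t0, 4)
            report["stages"][name] = entry
            return entry

        return deco

    # -- simulate ----------------------------------------------------------
    scfg = config.session.to_session_config()
    session = simulate_session(scfg, rng_seed=config.seed)

    @stage("simulate")
    def _simulate():
        write_signals_csv(session.research, out / "research")
        write_signals_csv(session.monitor, out / "monitor")
        write_events_json(session.research_events, out / "events_research.json")
        write_events_json(session.monitor_events, out / "events_monitor.json")
        return {
            "research_channels": sorted(session.research),
            "monitor_channels": sorted(session.monitor),
            "n_events": len(session.research_events),
        }

    @stage("precision")
    def _precision():
        # the marking-precision protocol is a bench recording: re-simulate
        # the same presses with no respiration on the electrodes
        from dataclasses import replace

        bench = simulate_session(replace(scfg, ip_breath_amplitude=0.0),
                                 rng_seed=config.seed)
        marks = [m for m in bench.monitor_events
                 if m.marker.name == "push_button"]
        res = session_precision(bench.monitor["IP"], marks,
                                threshold_fraction=config.precision_threshold)
        (out / "precision.json").write_text(json.dumps(res.to_dict(), indent=1))
        return res.to_dict()

    @stage("sync")
    def _sync():
        res = session_lag_analysis(session)
        (out / "lag.json").write_text(json.dumps(res.to_dict(), indent=1))
        return res.to_dict()

    @stage("evoked")
    def _evoked():
        eeg = bandpass_eeg(session.research["Cz"])
        epochs = epoch_and_baseline(
            eeg, [m for m in session.research_events
                  if m.marker.name != "push_button"],
            strict=config.strict,
        )
        avg = average_epochs(epochs)
        template = default_noxious_template(rate=eeg.rate)
        proj = woody_align(epochs.data[0], template, rate=eeg.rate)
        np.savetxt(out / "evoked_average.csv",
                   np.column_stack([avg.times(), avg.samples]),
                   delimiter=",", header="time_s,value", comments="")
        return {
            "n_trials": epochs.n_trials,
            "woody_shift_s": proj.shift,
            "woody_magnitude": proj.magnitude,
        }

    @stage("resp")
    def _resp():
        ip = remove_cardiac_interference(session.monitor["IP"],
                                         session.monitor["ECG"])
        breaths = detect_breaths(ip)
        rr = windowed_rr(breaths, window=config.rr_window,
                         step=config.rr_step, edge_gap=config.rr_edge_gap)
        np.savetxt(out / "breaths.csv", breaths.breath_times[:, None],
                   delimiter=",", header="breath_time_s", comments="")
        np.savetxt(out / "rr.csv",
                   np.column_stack([rr.window_centers, rr.rr]),
                   delimiter=",", header="window_center_s,rr_bpm", comments="")
        return {
            "n_breaths": breaths.n_breaths,
            "rr_median_bpm": float(np.nanmedian(rr.rr)) if rr.rr.size else None,
        }

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
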