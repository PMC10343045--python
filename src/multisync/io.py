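"""Signal file readers and writers (CSV and EDF).

CSV dialect: one channel per file, UTF-8, header ``time_s,value``, '.'
decimal; a directory of ``*.csv`` files is read as one channel per file.
Event times and timestamps are written with enough fractional digits that
millisecond semantics survive a round trip.

EDF is read through :func:`mne.io.read_raw_edf`.  Because EDF stores one
global start time and mixed-rate channels per file, each channel is loaded
individually so every channel keeps its native sampling rate.  Writing uses
a minimal EDF+ writer implemented here (no EDF-writing library is part of
this package's dependency set): 16-bit quantisation means an EDF round trip
is exact only to the quantisation step ``(phys_max - phys_min) / 65535``.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Mapping

import numpy as np

from .timeseries import TimeSeries

__all__ = ["read_signals", "write_signals_csv", "write_signals_edf"]


class SignalFileError(ValueError):
    """Malformed or inconsistent signal file."""


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _write_channel_csv(ts: TimeSeries, path: Path) -> None:
    t = ts.times()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for ti, vi in zip(t, ts.samples):
            w.writerow([f"{ti:.6f}", f"{vi:.12g}"])


def write_signals_csv(channels: Mapping[str, TimeSeries], out_dir: str | Path) -> None:
    """Write each channel as ``<label>.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, ts in channels.items():
        _write_channel_csv(ts, out / f"{name}.csv")


def _read_channel_csv(path: Path) -> TimeSeries:
    times, values = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["time_s", "value"]:
            raise SignalFileError(f"{path}: expected header 'time_s,value'")
        for ln, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                times.append(float(row[0]))
                values.append(float(row[1]))
            except (ValueError, IndexError) as exc:
                raise SignalFileError(f"{path}: parse error at line {ln}: {row!r}") from exc
    if len(values) < 2:
        raise SignalFileError(f"{path}: need at least two samples")
    t = np.asarray(times)
    dt = (t[-1] - t[0]) / (len(t) - 1)
    if dt <= 0:
        raise SignalFileError(f"{path}: timestamps not increasing")
    dev = np.abs(np.diff(t) - dt)
    if dev.max() > 1e-3 * dt:
        raise SignalFileError(
            f"{path}: timestamps deviate from a uniform rate by "
            f"{dev.max() / dt * 100:.3f}% (> 0.1%)"
        )
    return TimeSeries(np.asarray(values), rate=1.0 / dt, start=float(t[0]),
                      label=path.stem)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_record_duration(rates: list[float]) -> int:
    """Smallest integer record duration making every rate an integer count."""
    for d in range(1, 61):
        if all(abs(r * d - round(r * d)) < 1e-9 for r in rates):
            return d
    raise SignalFileError(f"no integer record duration fits rates {rates}")


def write_signals_edf(channels: Mapping[str, TimeSeries], path: str | Path) -> None:
    """Minimal EDF+ (continuous) writer.

    All channels must share a start time (EDF stores a single file start).
    Samples are scaled to 16-bit integers over each channel's physical range;
    the record is zero-padded to a whole number of data records.
    """
    chans = list(channels.items())
    if not chans:
        raise SignalFileError("no channels to write")
    starts = {round(ts.start, 9) for _, ts in chans}
    if len(starts) > 1:
        raise SignalFileError("EDF requires a common start time across channels")
    rates = [ts.rate for _, ts in chans]
    rec_dur = _edf_record_duration(rates)
    n_records = max(
        math.ceil(ts.n / (ts.rate * rec_dur)) for _, ts in chans
    )
    ns = len(chans)

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),                       # version
        pad("X X X X", 80),                # local patient id (anonymous)
        pad("Startdate X X X X", 80),      # local recording id
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8),
        pad("EDF+C", 44),
        pad(str(n_records), 8),
        pad(str(rec_dur), 8),
        pad(str(ns), 4),
    ])
    labels, transducers, units, pmins, pmaxs, dmins, dmaxs, prefilt, nsamp = (
        [], [], [], [], [], [], [], [], []
    )
    scaled: list[np.ndarray] = []
    for name, ts in chans:
        pmin, pmax = float(ts.samples.min()), float(ts.samples.max())
        if pmax <= pmin:
            pmax = pmin + 1.0
        dmin, dmax = -32768, 32767
        gain = (dmax - dmin) / (pmax - pmin)
        total = int(round(ts.rate * rec_dur)) * n_records
        x = np.zeros(total)
        x[: ts.n] = ts.samples
        x[ts.n:] = ts.samples[-1]
        dig = np.clip(np.round((x - pmin) * gain + dmin), dmin, dmax).astype("<i2")
        scaled.append(dig)
        labels.append(pad(name, 16))
        transducers.append(pad("", 80))
        units.append(pad(ts.units, 8))
        pmins.append(pad(f"{pmin:.7g}", 8))
        pmaxs.append(pad(f"{pmax:.7g}", 8))
        dmins.append(pad(str(dmin), 8))
        dmaxs.append(pad(str(dmax), 8))
        prefilt.append(pad("", 80))
        nsamp.append(pad(str(int(round(ts.rate * rec_dur))), 8))
    sig_header = b"".join(
        b"".join(part) for part in
        (labels, transducers, units, pmins, pmaxs, dmins, dmaxs, prefilt,
         nsamp, [pad("", 32)] * ns)
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        counts = [int(round(ts.rate * rec_dur)) for _, ts in chans]
        for r in range(n_records):
            for dig, cnt in zip(scaled, counts):
                fh.write(dig[r * cnt:(r + 1) * cnt].tobytes())


def _read_edf(path: Path) -> dict[str, TimeSeries]:
    import mne

    with np.errstate(all="ignore"):
        info = mne.io.read_raw_edf(path, preload=False, verbose="error")
    out: dict[str, TimeSeries] = {}
    for name in info.ch_names:
        raw = mne.io.read_raw_edf(path, include=[name], preload=True,
                                  verbose="error")
        data = raw.get_data()[0]
        out[name] = TimeSeries(np.asarray(data, dtype=float),
                               rate=float(raw.info["sfreq"]), start=0.0,
                               label=name)
    return out


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def read_signals(path: str | Path, fmt: str | None = None) -> dict[str, TimeSeries]:
    """Read signals into a channel->TimeSeries map.

    ``path`` may be an EDF file, a single-channel CSV file, or a directory of
    per-channel CSV files.  ``fmt`` (``"edf"``/``"csv"``) overrides extension
    sniffing.
    """
    p = Path(path)
    if not p.exists():
        raise SignalFileError(f"no such file: {p}")
    if p.is_dir():
        files = sorted(p.glob("*.csv"))
        if not files:
            raise SignalFileError(f"{p}: no CSV channel files found")
        return {f.stem: _read_channel_csv(f) for f in files}
    kind = fmt or p.suffix.lstrip(".").lower()
    if kind == "edf":
        return _read_edf(p)
    if kind == "csv":
        ts = _read_channel_csv(p)
        return {ts.label: ts}
    raise SignalFileError(f"unsupported signal format: {kind!r}")
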