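"""Event-marking protocol layer.

Models the trigger path of a dual-device acquisition rig: a stimulus trigger
is encoded as a small annotation message, sent over a UDP-like (or TCP-like)
transport, and stamped onto each device's recording through that device's
clock and marking-latency model.  The research-grade EEG path marks events
with sub-millisecond latency; the vital-signs-monitor path marks them with a
~100 ms stochastic delay.  Both are captured by :class:`ClockLatencyModel`.

No real sockets are involved: the transport is an abstraction level, and a
message is a self-describing JSON envelope ``{"label", "seq", "timestamp"}``
wrapping a user-defined payload string.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The six canonical stimulus/marker labels supported out of the box.
CANONICAL_MARKERS = (
    "heel_lance",
    "visual",
    "tactile",
    "auditory",
    "noxious_experimental",
    "push_button",
)

PROTOCOL_VERSION = 1


class UnmappedMarkerError(KeyError):
    """Marker has no payload in the mapping."""


class UnknownMessageError(KeyError):
    """Payload does not correspond to any marker in the mapping."""


class AmbiguousMappingError(ValueError):
    """Two or more markers share the same payload string."""


@dataclass(frozen=True)
class MarkerLabel:
    """A stimulus/event label; canonical names or any non-empty user label."""

    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker label must be non-empty")

    @property
    def is_canonical(self) -> bool:
        return self.name in CANONICAL_MARKERS

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


class Transport(str, Enum):
    udp_like = "udp_like"
    tcp_like = "tcp_like"


@dataclass(frozen=True)
class EventMessage:
    """An annotation message as it travels to the acquisition laptop.

    ``payload`` is the user-defined text for this marker; the serialised wire
    form (:meth:`to_wire`) wraps it in a versioned JSON envelope so the
    protocol stays self-describing.  Both transports behave identically at
    this abstraction level.
    """

    marker: MarkerLabel
    payload: str
    transport: Transport = Transport.udp_like
    seq: int = 0
    timestamp: float | None = None

    def to_wire(self) -> str:
        env = {
            "v": PROTOCOL_VERSION,
            "label": self.payload,
            "seq": self.seq,
            "timestamp": self.timestamp,
        }
        return json.dumps(env, separators=(",", ":"))

    @classmethod
    def from_wire(cls, wire: str, marker: MarkerLabel,
                  transport: Transport = Transport.udp_like) -> "EventMessage":
        env = json.loads(wire)
        return cls(marker=marker, payload=env["label"], transport=transport,
                   seq=int(env.get("seq", 0)), timestamp=env.get("timestamp"))


@dataclass(frozen=True)
class ClockLatencyModel:
    """Affine device clock plus a stochastic event-marking latency.

    The clock transform is ``device_time = offset + (1 + drift) * true_time``.
    Marking latency is drawn from a normal distribution truncated below at
    ``latency_floor`` (>= 0), which prevents unphysical negative delays.
    ``latency_sd = 0`` degenerates to a deterministic delay of
    ``max(latency_mean, latency_floor)``.
    """

    offset: float = 0.0
    drift: float = 0.0
    latency_mean: float = 0.0
    latency_sd: float = 0.0
    latency_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.latency_sd < 0:
            raise ValueError("latency_sd must be >= 0")
        if self.latency_floor < 0:
            raise ValueError("latency_floor must be >= 0")

    def to_device_time(self, true_time: float) -> float:
        return self.offset + (1.0 + self.drift) * true_time

    def draw_latency(self, rng: np.random.Generator, size: int | None = None):
        """Truncated-normal latency draw(s), each >= latency_floor."""
        if self.latency_sd == 0:
            val = max(self.latency_mean, self.latency_floor)
            return val if size is None else np.full(size, val)
        n = 1 if size is None else size
        out = np.empty(n)
        pending = np.arange(n)
        # rejection sampling; acceptance region is wide for the defaults
        while pending.size:
            draw = rng.normal(self.latency_mean, self.latency_sd, pending.size)
            ok = draw >= self.latency_floor
            out[pending[ok]] = draw[ok]
            pending = pending[~ok]
        return float(out[0]) if size is None else out


#: Defaults matching the two marking paths of the acquisition rig: the
#: research device stamps triggers within ~0.5 ms; the monitor path delays
#: them by ~105 ms with 19 ms spread (observed bench values).
RESEARCH_CLOCK_DEFAULT = ClockLatencyModel(latency_mean=0.0005, latency_sd=0.0)
MONITOR_CLOCK_DEFAULT = ClockLatencyModel(
    latency_mean=0.105, latency_sd=0.019, latency_floor=0.0
)


@dataclass(frozen=True)
class EventMark:
    """A labelled timestamp on a specific device's clock."""

    marker: MarkerLabel
    time: float
    device: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValueError("event time must be finite")
        if not self.device:
            raise ValueError("device identifier must be non-empty")


def _as_marker(m: MarkerLabel | str) -> MarkerLabel:
    return m if isinstance(m, MarkerLabel) else MarkerLabel(str(m))


def _normalise_mapping(mapping: Mapping) -> dict[str, str]:
    return {_as_marker(k).name: str(v) for k, v in mapping.items()}


def encode_event(marker: MarkerLabel | str, mapping: Mapping,
                 transport: Transport = Transport.udp_like,
                 seq: int = 0, timestamp: float | None = None) -> EventMessage:
    """Encode a marker as an annotation message via a marker->payload table.

    Raises
    ------
    UnmappedMarkerError
        If the marker is absent from the mapping.
    """
    marker = _as_marker(marker)
    table = _normalise_mapping(mapping)
    if marker.name not in table:
        raise UnmappedMarkerError(f"marker {marker.name!r} has no payload mapping")
    return EventMessage(marker=marker, payload=table[marker.name],
                        transport=transport, seq=seq, timestamp=timestamp)


def decode_event(msg: EventMessage | str, mapping: Mapping) -> MarkerLabel:
    """Inverse of :func:`encode_event`: payload -> marker.

    Accepts either an :class:`EventMessage` or a bare payload string.

    Raises
    ------
    AmbiguousMappingError
        If two markers share a payload (the inverse is ill-defined).
    UnknownMessageError
        If the payload matches no marker.
    """
    table = _normalise_mapping(mapping)
    payload = msg.payload if isinstance(msg, EventMessage) else str(msg)
    hits = [name for name, p in table.items() if p == payload]
    dupes = {p for p in table.values() if list(table.values()).count(p) > 1}
    if payload in dupes:
        raise AmbiguousMappingError(
            f"payload {payload!r} maps to multiple markers: {sorted(hits)}"
        )
    if not hits:
        raise UnknownMessageError(f"no marker for payload {payload!r}")
    return MarkerLabel(hits[0])


def bridge_trigger(
    true_time: float,
    research_clock: ClockLatencyModel = RESEARCH_CLOCK_DEFAULT,
    monitor_clock: ClockLatencyModel = MONITOR_CLOCK_DEFAULT,
    rng: np.random.Generator | int | None = 0,
    marker: MarkerLabel | str = "push_button",
) -> tuple[EventMark, EventMark]:
    """Stamp one physical trigger onto both device timelines.

    The mark on each device lands at the clock-transformed true time plus a
    draw from that device's marking-latency distribution.

    Returns
    -------
    (research_mark, monitor_mark)
    """
    if not math.isfinite(true_time):
        raise ValueError("true_time must be finite")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    marker = _as_marker(marker)
    t_res = research_clock.to_device_time(true_time) + research_clock.draw_latency(rng)
    t_mon = monitor_clock.to_device_time(true_time) + monitor_clock.draw_latency(rng)
    return (
        EventMark(marker=marker, time=float(t_res), device="research"),
        EventMark(marker=marker, time=float(t_mon), device="monitor"),
    )


# ---------------------------------------------------------------------------
# Event-annotation file I/O: JSON array of {label, time_s, device} and a CSV
# twin.  Times are written as decimal text with >= 6 fractional digits so
# millisecond semantics survive round trips exactly.
# ---------------------------------------------------------------------------

def write_events_json(marks: Sequence[EventMark], path: str | Path) -> None:
    rows = [
        {"label": m.marker.name, "time_s": f"{m.time:.6f}", "device": m.device}
        for m in marks
    ]
    Path(path).write_text(json.dumps(rows, indent=1) + "\n")


def read_events_json(path: str | Path) -> list[EventMark]:
    rows = json.loads(Path(path).read_text())
    return [
        EventMark(MarkerLabel(r["label"]), float(r["time_s"]), r["device"])
        for r in rows
    ]


def write_events_csv(marks: Sequence[EventMark], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "time_s", "device"])
        for m in marks:
            w.writerow([m.marker.name, f"{m.time:.6f}", m.device])


def read_events_csv(path: str | Path) -> list[EventMark]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        EventMark(MarkerLabel(r["label"]), float(r["time_s"]), r["device"])
        for r in rows
    ]


def read_events(path: str | Path) -> list[EventMark]:
    """Read an annotation file, dispatching on extension (.json or .csv)."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        return read_events_json(p)
    if p.suffix.lower() == ".csv":
        return read_events_csv(p)
    raise ValueError(f"unsupported event file extension: {p.suffix!r}")


def read_marker_mapping(path: str | Path) -> dict[str, str]:
    """Read a JSON label->payload table."""
    table = json.loads(Path(path).read_text())
    if not isinstance(table, dict):
        raise ValueError("marker mapping must be a JSON object")
    return {str(k): str(v) for k, v in table.items()}
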