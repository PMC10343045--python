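"""Uniformly sampled signal container used throughout the package.

Sample timestamp convention (used everywhere): sample ``i`` of a series with
start ``t0`` and rate ``fs`` lies at ``t0 + i / fs`` on the owning device's
clock; indexing is 0-based and file-time intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled channel on one device's clock.

    Parameters
    ----------
    samples
        Signal values; finite, length >= 1.
    rate
        Sampling rate in Hz, > 0.
    start
        Device-clock time of sample 0, seconds.
    label
        Channel label (e.g. ``"ECG"``, ``"IP"``, ``"Oz"``).
    units
        Physical units of the samples (e.g. ``"uV"``, ``"a.u."``).
    """

    samples: np.ndarray
    rate: float
    start: float = 0.0
    label: str = ""
    units: str = "a.u."

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a 1-D array with length >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if not (self.rate > 0):
            raise ValueError(f"rate must be > 0, got {self.rate}")
        object.__setattr__(self, "samples", arr)

    # -- derived geometry ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the half-open record interval [start, start + n/rate)."""
        return self.n / self.rate

    @property
    def end(self) -> float:
        return self.start + self.duration

    def times(self) -> np.ndarray:
        """Device-clock timestamp of every sample."""
        return self.start + np.arange(self.n) / self.rate

    # -- slicing ------------------------------------------------------------
    def index_at(self, t: float) -> int:
        """Index of the sample covering device-clock time ``t`` (floor)."""
        return int(np.floor((t - self.start) * self.rate + 1e-9))

    def slice(self, t_from: float, t_to: float) -> "TimeSeries":
        """Sub-series covering [t_from, t_to); bounds clipped to the record."""
        i0 = max(self.index_at(t_from), 0)
        i1 = min(int(np.ceil((t_to - self.start) * self.rate - 1e-9)), self.n)
        if i1 <= i0:
            raise ValueError(
                f"empty slice [{t_from}, {t_to}) of record [{self.start}, {self.end})"
            )
        return replace(
            self, samples=self.samples[i0:i1], start=self.start + i0 / self.rate
        )

    def covers(self, t_from: float, t_to: float) -> bool:
        return self.start <= t_from + 1e-9 and t_to <= self.end + 1e-9

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return replace(self, samples=np.asarray(samples, dtype=float))
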