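"""Core containers for voltage-clamp recordings and photostimulation protocols.

Currents are in pA throughout (inward currents negative, following the
voltage-clamp sign convention), times in seconds unless a name says
otherwise.  Traces are uniformly sampled; the default acquisition emulated
here is 20 kHz.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "StimProtocol", "save_trace_text", "load_trace_text",
           "save_trace_hdf5", "load_trace_hdf5"]


@dataclass
class Trace:
    """A uniformly sampled current (or voltage) time series.

    Parameters
    ----------
    data : array of sample values (pA for currents).
    dt : sampling interval in seconds.
    t0 : time of the first sample in seconds.
    units : unit string, default ``"pA"``.
    label : free-form condition label (e.g. ``"control"``, ``"CNQX"``).
    """

    data: np.ndarray
    dt: float
    t0: float = 0.0
    units: str = "pA"
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("trace data must be one-dimensional")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) * self.dt

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    def index_of(self, t: float) -> int:
        """Index of the sample at or immediately before time ``t``."""
        i = int(np.floor((t - self.t0) / self.dt + 1e-9))
        if i < 0 or i >= self.n_samples:
            raise ValueError(f"time {t} s outside trace span")
        return i

    def slice(self, start: float, stop: float) -> "Trace":
        """Sub-trace covering ``[start, stop)`` seconds."""
        i0 = self.index_of(start)
        i1 = int(np.ceil((stop - self.t0) / self.dt - 1e-9))
        i1 = min(max(i1, i0 + 1), self.n_samples)
        return Trace(self.data[i0:i1], self.dt, t0=self.t0 + i0 * self.dt,
                     units=self.units, label=self.label)

    def copy(self) -> "Trace":
        return Trace(self.data.copy(), self.dt, self.t0, self.units, self.label)


@dataclass
class StimProtocol:
    """A photostimulation pulse train.

    ``pulse_onsets`` are in seconds and strictly increasing; ``pulse_width``
    (s) must be shorter than every inter-pulse interval.  ``intensity`` is
    the optical power in mW at the preparation, ``wavelength_nm`` records
    the opsin role (473 nm blue for ChR2 excitation by default).
    """

    pulse_onsets: np.ndarray
    pulse_width: float
    intensity: float
    frequency: float | None = None
    total_duration: float | None = None
    wavelength_nm: float = 473.0

    def __post_init__(self) -> None:
        self.pulse_onsets = np.atleast_1d(np.asarray(self.pulse_onsets, dtype=float))
        if self.pulse_onsets.size == 0:
            raise ValueError("protocol requires at least one pulse")
        d = np.diff(self.pulse_onsets)
        if np.any(d <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if not self.pulse_width > 0:
            raise ValueError("pulse_width must be positive")
        if d.size and self.pulse_width >= d.min():
            raise ValueError("pulse_width must be shorter than the inter-pulse interval")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.frequency is None and d.size:
            self.frequency = float(1.0 / np.median(d))
        if self.total_duration is None:
            self.total_duration = float(self.pulse_onsets[-1] + self.pulse_width)

    @classmethod
    def single_pulse(cls, onset: float = 0.1, pulse_width: float = 1e-3,
                     intensity: float = 16.0) -> "StimProtocol":
        """The brief full-field mapping stimulus (16 mW, 1 ms by default)."""
        return cls(np.array([onset]), pulse_width, intensity)

    @classmethod
    def train(cls, start: float, frequency: float, duration: float,
              pulse_width: float = 10e-3, intensity: float = 16.0) -> "StimProtocol":
        """A pulse train, e.g. the 10 s @ 10 Hz, 10 ms, 16 mW protocol."""
        n = int(round(frequency * duration))
        onsets = start + np.arange(n) / frequency
        return cls(onsets, pulse_width, intensity, frequency=frequency,
                   total_duration=duration)

    @property
    def n_pulses(self) -> int:
        return self.pulse_onsets.size

    @property
    def light_on_span(self) -> tuple[float, float]:
        """(first onset, last offset) in seconds."""
        return float(self.pulse_onsets[0]), float(self.pulse_onsets[-1] + self.pulse_width)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pulse_onsets"] = [float(x) for x in self.pulse_onsets]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimProtocol":
        return cls(np.asarray(d["pulse_onsets"], dtype=float),
                   d["pulse_width"], d["intensity"],
                   frequency=d.get("frequency"),
                   total_duration=d.get("total_duration"),
                   wavelength_nm=d.get("wavelength_nm", 473.0))


# ---------------------------------------------------------------------------
# Trace I/O: two-column text and an HDF5 container with metadata.

def save_trace_text(trace: Trace, path) -> None:
    """Write a trace as two-column text (time_s, current_pA)."""
    arr = np.column_stack([trace.times, trace.data])
    header = f"time_s\t{trace.units}\tdt={trace.dt!r}\tlabel={trace.label}"
    np.savetxt(path, arr, delimiter="\t", header=header)


def load_trace_text(path) -> Trace:
    arr = np.loadtxt(path, delimiter="\t")
    t, y = arr[:, 0], arr[:, 1]
    dt = float(np.median(np.diff(t)))
    return Trace(y, dt, t0=float(t[0]))


def save_trace_hdf5(trace: Trace, path, name: str = "trace", **metadata) -> None:
    import h5py

    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=trace.data)
        ds.attrs["dt"] = trace.dt
        ds.attrs["t0"] = trace.t0
        ds.attrs["units"] = trace.units
        ds.attrs["label"] = trace.label
        for k, v in metadata.items():
            ds.attrs[k] = json.dumps(v) if isinstance(v, (dict, list)) else v


def load_trace_hdf5(path, name: str = "trace") -> Trace:
    import h5py

    with h5py.File(path, "r") as f:
        ds = f[name]
        return Trace(ds[...], float(ds.attrs["dt"]), t0=float(ds.attrs["t0"]),
                     units=str(ds.attrs.get("units", "pA")),
                     label=str(ds.attrs.get("label", "")))
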