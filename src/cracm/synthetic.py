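"""Synthetic voltage-clamp recordings with ground truth.

Everything downstream of acquisition — event detection, photocurrent
subtraction, kinetics, latency-window classification — can be exercised on
the recordings produced here, with the injected events available as ground
truth.  The generative model:

* synaptic currents are difference-of-exponentials kernels
  ``w(t) ∝ exp(-t/τ_decay) - exp(-t/τ_rise)``, unit peak, zero before onset;
* the opsin photocurrent rises mono-exponentially to a plateau given by a
  Hill function of light intensity ``A(I) = A_max · I^h / (I^h + K^h)`` and
  decays mono-exponentially after light off;
* spontaneous events form a homogeneous Poisson train; optically evoked
  events follow each light pulse with a truncated-Gaussian latency drawn
  from a direct/delayed mixture;
* recording noise is white Gaussian (default 3 pA RMS at 20 kHz).

One global integer seed is expanded into independent per-component streams
with :func:`numpy.random.SeedSequence.spawn`, in the fixed order
(photocurrent, spontaneous, evoked, noise, misc), so the event lists for a
given (config, seed) pair are bit-reproducible.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .core import StimProtocol, Trace

__all__ = [
    "SynapticEventParams", "PhotocurrentParams", "ConnectivityParams",
    "PharmacologyCondition", "BehaviorGenParams", "GroundTruthEvent",
    "RecordingBundle", "RecordingConfig", "BehaviorLog", "Bout",
    "generate_psc_waveform", "biexp_peak_time", "biexp_descriptors",
    "design_biexp_params", "generate_photocurrent", "generate_event_train",
    "generate_evoked_latencies", "synthesize_recording", "apply_pharmacology",
    "generate_potentiation_session", "generate_behavior_log",
    "PRESETS", "get_preset", "split_seed",
]


# ---------------------------------------------------------------------------
# Parameter records

@dataclass
class SynapticEventParams:
    """Generative shape and amplitude statistics of one synaptic input class.

    Time constants in ms, amplitudes in pA (positive magnitudes; the sign is
    applied through ``polarity``).
    """

    tau_rise: float
    tau_decay: float
    amplitude_mean: float
    amplitude_cv: float = 0.2
    polarity: str = "inward"
    transmitter: str = "glutamate"

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.amplitude_mean < 0:
            raise ValueError("amplitude_mean must be non-negative")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")
        if self.transmitter not in ("glutamate", "GABA", "glycine"):
            raise ValueError("unknown transmitter")

    @property
    def sign(self) -> float:
        return -1.0 if self.polarity == "inward" else 1.0


@dataclass
class PhotocurrentParams:
    """Opsin photocurrent model: Hill intensity-amplitude curve with
    mono-exponential on/off kinetics.  ``max_amplitude`` in pA,
    ``half_saturation_intensity`` in mW, time constants in ms."""

    max_amplitude: float
    half_saturation_intensity: float = 1.0
    hill_exponent: float = 1.0
    tau_on: float = 5.0
    tau_off: float = 10.0
    polarity: str = "inward"

    def __post_init__(self) -> None:
        for name in ("max_amplitude", "half_saturation_intensity",
                     "hill_exponent", "tau_on", "tau_off"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def plateau(self, intensity_mw: float) -> float:
        """Steady-state photocurrent magnitude (pA) at a given intensity."""
        if intensity_mw < 0:
            raise ValueError("intensity must be non-negative")
        if intensity_mw == 0:
            return 0.0
        ih = intensity_mw ** self.hill_exponent
        kh = self.half_saturation_intensity ** self.hill_exponent
        return self.max_amplitude * ih / (ih + kh)


@dataclass
class ConnectivityParams:
    """Optically evoked input statistics: per-pulse release probability and a
    direct/delayed latency mixture (ms)."""

    connection_probability: float = 1.0
    release_probability: float = 0.9
    direct_latency_mean: float = 6.0
    direct_latency_sd: float = 1.0
    delayed_latency_mean: float = 15.0
    delayed_latency_sd: float = 4.0
    direct_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("connection_probability", "release_probability",
                     "direct_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.delayed_latency_mean <= self.direct_latency_mean:
            raise ValueError("delayed latency mean must exceed direct latency mean")
        if self.direct_latency_sd < 0 or self.delayed_latency_sd < 0:
            raise ValueError("latency SDs must be non-negative")


_PHARMA_LABELS = ("control", "CNQX", "CNQX+bicuculline",
                  "CNQX+bicuculline+strychnine")


@dataclass
class PharmacologyCondition:
    """Bath-application condition.  ``gaba_block_fraction`` is the per-cell
    fraction of the GABA-mediated amplitude removed by bicuculline."""

    label: str = "control"
    gaba_block_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in _PHARMA_LABELS:
            raise ValueError(f"unknown pharmacology label {self.label!r}")
        if not 0 <= self.gaba_block_fraction <= 1:
            raise ValueError("gaba_block_fraction must lie in [0, 1]")


@dataclass
class BehaviorGenParams:
    """Generative statistics of the photostimulation-evoked nocifensive
    response: per-region onset latencies (truncated Gaussians, s) and the
    expected summed bout duration (s)."""

    region_latency_means: dict = field(default_factory=lambda: {
        "paw": 1.25, "limb": 26.42, "back": 40.83, "tail": 59.29})
    region_latency_sds: dict = field(default_factory=lambda: {
        "paw": 0.76, "limb": 31.56, "back": 37.34, "tail": 63.46})
    mean_total_duration: float = 45.0
    decay_time: float = 30.0
    response_probability: float = 1.0

    def __post_init__(self) -> None:
        means = self.region_latency_means
        order = ["paw", "limb", "back", "tail"]
        present = [r for r in order if r in means]
        vals = [means[r] for r in present]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("latency means must be ordered paw < limb < back < tail")
        if any(v <= 0 for v in means.values()):
            raise ValueError("latency means must be positive")
        if any(v < 0 for v in self.region_latency_sds.values()):
            raise ValueError("latency SDs must be non-negative")
        if self.mean_total_duration <= 0 or self.decay_time <= 0:
            raise ValueError("durations must be positive")
        if not 0 <= self.response_probability <= 1:
            raise ValueError("response_probability must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Behaviour log containers (shared with cracm.behavior)

@dataclass
class Bout:
    onset_s: float
    duration_s: float
    region: str = "other"
    code: str = "groom"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("bout duration must be positive")
        if self.region not in ("paw", "limb", "back", "tail", "other"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class BehaviorLog:
    """Timestamped coded bouts relative to a stimulation onset."""

    bouts: list
    stim_onset: float
    session_length: float

    def __post_init__(self) -> None:
        self.bouts = sorted(
            (b if isinstance(b, Bout) else Bout(*b) for b in self.bouts),
            key=lambda b: b.onset_s)
        for b in self.bouts:
            if b.onset_s < 0 or b.onset_s + b.duration_s > self.session_length + 1e-9:
                raise ValueError("bout extends outside the session")


# ---------------------------------------------------------------------------
# Ground-truth bookkeeping

@dataclass
class GroundTruthEvent:
    time: float           # s, kernel onset
    amplitude: float      # pA, signed peak
    transmitter: str
    origin: str           # spontaneous | direct | delayed

    def __post_init__(self) -> None:
        if self.origin not in ("spontaneous", "direct", "delayed"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class RecordingBundle:
    """A synthesized recording plus everything that went into it."""

    trace: Trace | None
    protocol: StimProtocol | None
    ground_truth_events: list
    ground_truth_photocurrent: Trace | None
    seed: int
    config: "RecordingConfig | None" = None

    @property
    def event_times(self) -> np.ndarray:
        return np.array([e.time for e in self.ground_truth_events])

    def events_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            [{"time_s": e.time, "amplitude_pA": e.amplitude,
              "transmitter": e.transmitter, "origin": e.origin}
             for e in self.ground_truth_events]).to_csv(path, index=False)


@dataclass
class RecordingConfig:
    """Everything needed to synthesize one voltage-clamp sweep."""

    duration: float = 0.5                 # s
    dt: float = 5e-5                      # s (20 kHz)
    protocol: StimProtocol | None = None
    photocurrent: PhotocurrentParams | None = None
    spontaneous_rate: float = 0.0         # Hz
    spontaneous_params: SynapticEventParams | None = None
    evoked: ConnectivityParams | None = None
    evoked_params: SynapticEventParams | None = None
    noise_rms: float = 3.0                # pA

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")
        if self.spontaneous_rate < 0:
            raise ValueError("spontaneous_rate must be non-negative")
        if self.spontaneous_rate > 0 and self.spontaneous_params is None:
            raise ValueError("spontaneous_params required when spontaneous_rate > 0")
        if self.evoked is not None and self.evoked_params is None:
            raise ValueError("evoked_params required with evoked connectivity")
        if self.protocol is not None:
            if self.protocol.light_on_span[1] > self.duration:
                raise ValueError("protocol extends past the recording duration")

    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                if isinstance(x, StimProtocol):
                    return x.to_dict()
                return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, np.ndarray):
                return [float(v) for v in x]
            return x
        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingConfig":
        d = dict(d)
        if d.get("protocol"):
            d["protocol"] = StimProtocol.from_dict(d["protocol"])
        for key, typ in (("photocurrent", PhotocurrentParams),
                         ("spontaneous_params", SynapticEventParams),
                         ("evoked_params", SynapticEventParams),
                         ("evoked", ConnectivityParams)):
            if d.get(key):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RecordingConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Seed handling

_STREAMS = ("photocurrent", "spontaneous", "evoked", "noise", "misc")


def split_seed(seed: int) -> dict:
    """Expand one integer seed into named independent generators.

    Child streams are spawned from ``np.random.SeedSequence(seed)`` in the
    fixed order photocurrent, spontaneous, evoked, noise, misc.
    """
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# Kernel mathematics

def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form peak time (ms) of exp(-t/τd) - exp(-t/τr)."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("require 0 < tau_rise < tau_decay")
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * np.log(tau_decay / tau_rise)


def _biexp_unit(t, tau_rise, tau_decay):
    tp = biexp_peak_time(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    return (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / peak


def biexp_descriptors(tau_rise: float, tau_decay: float) -> dict:
    """Analytic 10-90% rise time, half-width, peak time and unit-kernel
    integral (all ms) of the normalised difference-of-exponentials kernel,
    found by bracketed root-finding on the closed form."""
    tp = biexp_peak_time(tau_rise, tau_decay)
    w = lambda t: _biexp_unit(t, tau_rise, tau_decay)
    lo = tau_rise * 1e-9
    t10 = brentq(lambda t: w(t) - 0.1, lo, tp)
    t90 = brentq(lambda t: w(t) - 0.9, lo, tp)
    h_lo = brentq(lambda t: w(t) - 0.5, lo, tp)
    hi = tp
    while w(hi) > 0.5:
        hi *= 2
    h_hi = brentq(lambda t: w(t) - 0.5, tp, hi)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    return {"rise_time_10_90": t90 - t10, "half_width": h_hi - h_lo,
            "peak_time": tp, "integral": (tau_decay - tau_rise) / peak}


def design_biexp_params(rise_time: float | None = None,
                        half_width: float | None = None,
                        decay_rise_ratio: float = 5.0,
                        **kwargs) -> SynapticEventParams:
    """Time constants whose analytic rise time *or* half-width matches a
    target value (ms), at a fixed τ_decay/τ_rise shape ratio.

    Exactly one of ``rise_time`` / ``half_width`` must be given.  Both
    descriptors scale linearly with τ_rise at fixed ratio, so the solve is a
    single rescaling of the unit-τ_rise kernel (whose descriptors are
    themselves obtained by root-finding).
    """
    if (rise_time is None) == (half_width is None):
        raise ValueError("specify exactly one of rise_time or half_width")
    ref = biexp_descriptors(1.0, decay_rise_ratio)
    if rise_time is not None:
        scale = rise_time / ref["rise_time_10_90"]
    else:
        scale = half_width / ref["half_width"]
    kwargs.setdefault("amplitude_mean", 1.0)
    return SynapticEventParams(tau_rise=scale, tau_decay=scale * decay_rise_ratio,
                               **kwargs)


# ---------------------------------------------------------------------------
# Generators

def generate_psc_waveform(params: SynapticEventParams, dt: float,
                          duration: float | None = None) -> np.ndarray:
    """Unit-peak synaptic kernel sampled at ``dt`` ms over ``duration`` ms.

    The waveform is ``(exp(-t/τd) - exp(-t/τr))`` normalised to unit peak
    magnitude; zero before onset (t = 0 is the first sample).  ``duration``
    defaults to 8 τ_decay, and must cover at least 5 τ_decay.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration is None:
        duration = 8.0 * params.tau_decay
    if duration < 5.0 * params.tau_decay:
        raise ValueError("duration must cover at least 5 tau_decay")
    t = np.arange(0.0, duration, dt)
    return _biexp_unit(t, params.tau_rise, params.tau_decay)


def generate_photocurrent(protocol: StimProtocol, params: PhotocurrentParams,
                          dt: float = 5e-5, duration: float | None = None) -> Trace:
    """Deterministic opsin photocurrent trace for a pulse protocol.

    During each light pulse the current relaxes toward the Hill-curve
    plateau with time constant ``tau_on``; after light off it decays with
    ``tau_off``.  Relaxation is computed segment-by-segment, so trains of
    pulses accumulate correctly.  Inward polarity gives negative samples.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration is None:
        duration = protocol.light_on_span[1] + 10 * params.tau_off * 1e-3
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    target = params.plateau(protocol.intensity)
    tau_on = params.tau_on * 1e-3
    tau_off = params.tau_off * 1e-3

    # light-state breakpoints: (time, state after this edge)
    edges = []
    for on in protocol.pulse_onsets:
        edges.append((float(on), True))
        edges.append((float(on + protocol.pulse_width), False))
    y = np.zeros(n)
    level = 0.0
    seg_start = 0.0
    light = False
    for edge_t, light_next in edges + [(duration, False)]:
        i0 = int(np.ceil(seg_start / dt - 1e-9))
        i1 = int(np.ceil(edge_t / dt - 1e-9))
        i1 = min(i1, n)
        if i1 > i0:
            tt = t[i0:i1] - seg_start
            if light:
                y[i0:i1] = target + (level - target) * np.exp(-tt / tau_on)
            else:
                y[i0:i1] = level * np.exp(-tt / tau_off)
        # state at the segment end becomes the next starting level
        span = edge_t - seg_start
        if light:
            level = target + (level - target) * np.exp(-span / tau_on)
        else:
            level = level * np.exp(-span / tau_off)
        seg_start = edge_t
        light = light_next
    sign = -1.0 if params.polarity == "inward" else 1.0
    return Trace(sign * y, dt, label="photocurrent")


def generate_event_train(rate: float, duration: float,
                         rng: np.random.Generator | int) -> np.ndarray:
    """Homogeneous Poisson event times in [0, duration), sorted."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _trunc_gauss(rng, mean, sd, size):
    """Gaussian draws re-sampled until strictly positive."""
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def generate_evoked_latencies(conn: ConnectivityParams, protocol: StimProtocol,
                              rng: np.random.Generator | int) -> list:
    """Per-pulse evoked event times (s).

    For a connected cell, each pulse releases with ``release_probability``;
    the latency is drawn from the direct Gaussian with probability
    ``direct_fraction`` and from the delayed Gaussian otherwise, re-sampled
    if non-positive.  Returns a list of (time_s, origin) pairs.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    events = []
    if rng.uniform() >= conn.connection_probability:
        return events
    for onset in protocol.pulse_onsets:
        if rng.uniform() >= conn.release_probability:
            continue
        if rng.uniform() < conn.direct_fraction:
            lat = _trunc_gauss(rng, conn.direct_latency_mean,
                               max(conn.direct_latency_sd, 1e-12), 1)[0]
            origin = "direct"
        else:
            lat = _trunc_gauss(rng, conn.delayed_latency_mean,
                               max(conn.delayed_latency_sd, 1e-12), 1)[0]
            origin = "delayed"
        events.append((float(onset + lat * 1e-3), origin))
    return events


def _add_kernel(data: np.ndarray, dt: float, onset_s: float, amplitude: float,
                params: SynapticEventParams) -> None:
    kern = generate_psc_waveform(params, dt * 1e3)
    i0 = int(round(onset_s / dt))
    if i0 >= data.size:
        return
    i1 = min(i0 + kern.size, data.size)
    data[i0:i1] += amplitude * kern[: i1 - i0]


def synthesize_recording(config: RecordingConfig, seed: int) -> RecordingBundle:
    """Build one sweep: photocurrent + spontaneous + evoked PSCs + noise.

    The returned bundle carries the injected events (time, signed amplitude,
    transmitter, origin) and the noise-free photocurrent as ground truth.
    """
    rngs = split_seed(seed)
    n = int(round(config.duration / config.dt))
    data = np.zeros(n)
    events: list[GroundTruthEvent] = []

    photo = None
    if config.photocurrent is not None:
        if config.protocol is None:
            raise ValueError("photocurrent requires a stimulation protocol")
        photo = generate_photocurrent(config.protocol, config.photocurrent,
                                      config.dt, duration=config.duration)
        data += photo.data
    else:
        photo = Trace(np.zeros(n), config.dt, label="photocurrent")

    def draw_amp(rng, params):
        amp = params.amplitude_mean
        if params.amplitude_cv > 0 and amp > 0:
            amp = abs(rng.normal(amp, params.amplitude_cv * amp))
        return amp * params.sign

    if config.spontaneous_rate > 0:
        sp = config.spontaneous_params
        times = generate_event_train(config.spontaneous_rate, config.duration,
                                     rngs["spontaneous"])
        for tev in times:
            amp = draw_amp(rngs["spontaneous"], sp)
            events.append(GroundTruthEvent(float(tev), amp, sp.transmitter,
                                           "spontaneous"))
    if config.evoked is not None:
        if config.protocol is None:
            raise ValueError("evoked input requires a stimulation protocol")
        ev = config.evoked_params
        for tev, origin in generate_evoked_latencies(config.evoked,
                                                     config.protocol,
                                                     rngs["evoked"]):
            if tev >= config.duration:
                raise ValueError("evoked event falls outside the recording; "
                                 "lengthen duration")
            amp = draw_amp(rngs["evoked"], ev)
            events.append(GroundTruthEvent(float(tev), amp, ev.transmitter, origin))

    for e in sorted(events, key=lambda e: e.time):
        params = (config.spontaneous_params if e.origin == "spontaneous"
                  else config.evoked_params)
        if e.amplitude != 0.0:
            _add_kernel(data, config.dt, e.time, e.amplitude, params)

    if config.noise_rms > 0:
        data += rngs["noise"].normal(0.0, config.noise_rms, size=n)

    # drop zero-amplitude events from ground truth (pharmacologically silenced)
    events = [e for e in sorted(events, key=lambda e: e.time) if e.amplitude != 0.0]
    trace = Trace(data, config.dt, label="synthetic")
    return RecordingBundle(trace, config.protocol, events, photo, seed, config)


def apply_pharmacology(config: RecordingConfig,
                       condition: PharmacologyCondition) -> RecordingConfig:
    """Return a config with synaptic amplitudes scaled by the bath condition.

    CNQX zeroes glutamatergic amplitudes; adding bicuculline scales GABA
    amplitudes by (1 - gaba_block_fraction); adding strychnine silences all
    synaptic events.  The photocurrent is untouched by any condition.
    """
    new = copy.deepcopy(config)
    if condition.label == "control":
        return new

    def scale(params: SynapticEventParams | None) -> None:
        if params is None:
            return
        if params.transmitter == "glutamate":
            params.amplitude_mean = 0.0
        elif params.transmitter == "GABA":
            if condition.label in ("CNQX+bicuculline",
                                   "CNQX+bicuculline+strychnine"):
                params.amplitude_mean *= (1.0 - condition.gaba_block_fraction)
            if condition.label == "CNQX+bicuculline+strychnine":
                params.amplitude_mean = 0.0
        elif params.transmitter == "glycine":
            if condition.label == "CNQX+bicuculline+strychnine":
                params.amplitude_mean = 0.0

    scale(new.spontaneous_params)
    scale(new.evoked_params)
    if new.spontaneous_params is not None and new.spontaneous_params.amplitude_mean == 0.0:
        new.spontaneous_rate = 0.0
    return new


# ---------------------------------------------------------------------------
# Longer sessions: rate potentiation

@dataclass
class PotentiationConfig:
    """Layout of an extended-photostimulation session (times in s)."""

    baseline_rate: float = 20.0
    pre_duration: float = 30.0
    stim_duration: float = 10.0
    post_duration: float = 60.0
    stim_frequency: float = 10.0
    pulse_width: float = 10e-3
    intensity: float = 16.0
    evoked_per_pulse_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        for name in ("pre_duration", "stim_duration", "post_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_potentiation_session(config: PotentiationConfig | None = None,
                                  potentiation_factor: float = 1.0,
                                  decay_time: float = 20.0,
                                  seed: int = 0) -> RecordingBundle:
    """Spontaneous-event session around an extended photostimulation train.

    Pre window: homogeneous Poisson at the baseline rate r0.  Stimulation:
    baseline plus one evoked event per pulse with probability
    ``evoked_per_pulse_prob``.  Post window: inhomogeneous Poisson with rate
    ``r0 · (1 + (factor - 1) · exp(-t/decay_time))`` (t from stimulation
    offset), sampled by thinning.  The bundle carries event times only; a
    trace can be rendered separately if needed.
    """
    if config is None:
        config = PotentiationConfig()
    if potentiation_factor < 1:
        raise ValueError("potentiation_factor must be >= 1")
    if decay_time <= 0:
        raise ValueError("decay_time must be positive")
    rngs = split_seed(seed)
    r0 = config.baseline_rate
    t_stim = config.pre_duration
    t_post = t_stim + config.stim_duration
    t_end = t_post + config.post_duration

    events: list[GroundTruthEvent] = []
    pre = generate_event_train(r0, config.pre_duration, rngs["spontaneous"])
    events += [GroundTruthEvent(float(t), -20.0, "glutamate", "spontaneous")
               for t in pre]
    during = t_stim + generate_event_train(r0, config.stim_duration,
                                           rngs["spontaneous"])
    events += [GroundTruthEvent(float(t), -20.0, "glutamate", "spontaneous")
               for t in during]

    protocol = StimProtocol.train(t_stim, config.stim_frequency,
                                  config.stim_duration,
                                  pulse_width=config.pulse_width,
                                  intensity=config.intensity)
    ev_rng = rngs["evoked"]
    for onset in protocol.pulse_onsets:
        if ev_rng.uniform() < config.evoked_per_pulse_prob:
            lat = _trunc_gauss(ev_rng, 6.0, 1.0, 1)[0] * 1e-3
            events.append(GroundTruthEvent(float(onset + lat), -20.0,
                                           "glutamate", "direct"))

    # post window by thinning against the peak rate
    rate = lambda t: r0 * (1.0 + (potentiation_factor - 1.0)
                           * np.exp(-(t - t_post) / decay_time))
    rmax = rate(t_post)
    if rmax > 0:
        cand = t_post + generate_event_train(rmax, config.post_duration,
                                             rngs["misc"])
        keep = rngs["misc"].uniform(size=cand.size) < rate(cand) / rmax
        events += [GroundTruthEvent(float(t), -20.0, "glutamate", "spontaneous")
                   for t in cand[keep]]

    events.sort(key=lambda e: e.time)
    return RecordingBundle(None, protocol, events, None, seed)


# ---------------------------------------------------------------------------
# Behaviour logs

def generate_behavior_log(params: BehaviorGenParams | None = None,
                          seed: int = 0,
                          stim_onset: float = 300.0,
                          session_length: float = 610.0) -> BehaviorLog:
    """Nocifensive-response log: one bout per responding body region.

    Region onsets are stimulation onset + truncated-Gaussian latency; bout
    durations are Gamma draws whose per-region means are weighted by
    ``exp(-latency_mean/decay_time)`` and sum to ``mean_total_duration``, so
    earlier-recruited regions carry more of the response.
    """
    if params is None:
        params = BehaviorGenParams()
    rng = split_seed(seed)["misc"]
    regions = list(params.region_latency_means)
    weights = np.array([np.exp(-params.region_latency_means[r] / params.decay_time)
                        for r in regions])
    mean_durs = params.mean_total_duration * weights / weights.sum()
    bouts = []
    for r, mdur in zip(regions, mean_durs):
        if rng.uniform() >= params.response_probability:
            continue
        lat = _trunc_gauss(rng, params.region_latency_means[r],
                           max(params.region_latency_sds.get(r, 0.0), 1e-12), 1)[0]
        onset = stim_onset + lat
        shape_k = 4.0
        dur = rng.gamma(shape_k, mdur / shape_k)
        dur = max(dur, 1e-3)
        if onset >= session_length:
            continue
        dur = min(dur, session_length - onset)
        bouts.append(Bout(onset, dur, region=r, code="nocifensive"))
    return BehaviorLog(bouts, stim_onset=stim_onset, session_length=session_length)


# ---------------------------------------------------------------------------
# Presets carrying the study's printed group values as generative targets

def _oepsc_kernel(amplitude: float) -> SynapticEventParams:
    # shape tuned so the analytic 10-90% rise matches the CR-ChR2 oEPSC value
    return design_biexp_params(rise_time=2.68, amplitude_mean=amplitude,
                               amplitude_cv=0.2, polarity="inward",
                               transmitter="glutamate")


PRESETS: dict = {
    # Photocurrent plateaus for the two opsin-expressing lineages (pA)
    "photocurrent_excitatory": PhotocurrentParams(max_amplitude=233.66),
    "photocurrent_inhibitory": PhotocurrentParams(max_amplitude=459.72),
    # Action-potential recruitment delay (ms): mean, SEM, n as printed
    "recruitment_excitatory": {"mean": 3.29, "sem": 0.21, "n": 29,
                               "sd_between": 0.21 * np.sqrt(29)},
    "recruitment_excitatory_alt": {"mean": 3.29, "sem": 0.38, "n": 29,
                                   "sd_between": 0.38 * np.sqrt(29)},
    "recruitment_inhibitory": {"mean": 2.39, "sem": 0.21, "n": 13,
                               "sd_between": 0.21 * np.sqrt(13)},
    # Group oEPSC response descriptors (ms / pA / pA·s), mean ± SEM, n
    "CR-ChR2 oEPSC": {"latency_mean": 8.61, "latency_sem": 1.23, "n": 12,
                      "latency_sd_between": 1.23 * np.sqrt(12),
                      "amplitude": 87.59, "rise_time": 2.68,
                      "half_width": 4.90, "charge": 0.66,
                      "kernel": _oepsc_kernel(87.59)},
    "plexus oEPSC": {"latency_mean": 4.75, "latency_sem": 0.59, "n": 11,
                     "latency_sd_between": 0.59 * np.sqrt(11),
                     "amplitude": 51.42, "rise_time": 2.89, "half_width": 5.40,
                     "charge": 0.52, "kernel": _oepsc_kernel(51.42)},
    "dorsal oEPSC": {"latency_mean": 7.34, "latency_sem": 1.06, "n": 13,
                     "latency_sd_between": 1.06 * np.sqrt(13),
                     "amplitude": 126.72, "rise_time": 3.22, "half_width": 6.61,
                     "charge": 1.93, "kernel": _oepsc_kernel(126.72)},
    "PN oEPSC": {"latency_mean": 7.95, "latency_sem": 1.38, "n": 13,
                 "latency_sd_between": 1.38 * np.sqrt(13),
                 "amplitude": 70.68, "rise_time": 5.54, "half_width": 10.82,
                 "charge": 1.35, "kernel": _oepsc_kernel(70.68)},
    # Direct/delayed evoked-latency mixtures (fractions as printed)
    "latency_mix_cr_chr2": ConnectivityParams(direct_fraction=0.35),
    "latency_mix_plexus": ConnectivityParams(direct_fraction=0.75),
    "latency_mix_dorsal": ConnectivityParams(direct_fraction=0.57),
    # Bicuculline-block mixtures: (P(GABA-dominant), GABA block range,
    # mixed block range, P(glycine-dominant), glycine block range)
    "inhibition_mix_excitatory_cr_chr2": {
        "gaba_fraction": 0.72, "gaba_block": (0.85, 0.98),
        "mixed_block": (0.30, 0.70), "glycine_fraction": 0.0,
        "glycine_block": (0.02, 0.15), "control_amplitude": 146.43,
        "control_amplitude_cv": 0.3},
    "inhibition_mix_plexus": {
        "gaba_fraction": 0.65, "gaba_block": (0.85, 0.98),
        "mixed_block": (0.30, 0.70), "glycine_fraction": 0.06,
        "glycine_block": (0.02, 0.15), "control_amplitude": 237.16,
        "control_amplitude_cv": 0.3},
    "inhibition_mix_dorsal": {
        "gaba_fraction": 0.58, "gaba_block": (0.85, 0.98),
        "mixed_block": (0.30, 0.70), "glycine_fraction": 0.08,
        "glycine_block": (0.02, 0.15), "control_amplitude": 224.87,
        "control_amplitude_cv": 0.3},
    # Behaviour
    "behavior_default": BehaviorGenParams(),
    # Extended-photostimulation session
    "potentiation_default": PotentiationConfig(),
}


def get_preset(name: str):
    """Fetch a preset by name (see ``PRESETS`` for the catalogue)."""
    try:
        item = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return copy.deepcopy(item)
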