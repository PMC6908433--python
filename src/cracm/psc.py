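"""Trial averaging, photocurrent subtraction and PSC kinetics.

All response descriptors reported by group tables in optogenetic mapping
studies are measured here from averaged, photocurrent-subtracted traces:
onset latency, peak amplitude, 10-90% rise time, half-width, single-
exponential decay constant over the 90-10% decay phase, and charge.
Charge is reported in pA·s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import StimProtocol, Trace
from .detection import estimate_baseline

__all__ = ["PSCMetrics", "FrequencySeries", "average_trials",
           "subtract_photocurrent", "measure_photocurrent",
           "measure_psc_kinetics", "epoch_frequency"]


@dataclass
class PSCMetrics:
    """Per-response kinetics record (ms / pA / pA·s).  All fields are None
    when no response clears the 3 × baseline-SD floor."""

    latency: float | None = None
    peak_amplitude: float | None = None
    rise_time_10_90: float | None = None
    half_width: float | None = None
    decay_tau: float | None = None
    charge: float | None = None

    @property
    def is_response(self) -> bool:
        return self.peak_amplitude is not None


@dataclass
class FrequencySeries:
    """Event frequency per fixed-width epoch (default 100 ms, i.e. the
    count in each epoch times 10 gives Hz)."""

    epoch_starts: np.ndarray   # s
    frequency: np.ndarray      # Hz
    epoch_width: float = 0.1   # s

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.epoch_starts.shape != self.frequency.shape:
            raise ValueError("epoch_starts and frequency must align")
        if np.any(self.frequency < 0):
            raise ValueError("frequencies must be non-negative")

    def window_mean(self, window: tuple[float, float]) -> float:
        lo, hi = window
        m = (self.epoch_starts >= lo) & (self.epoch_starts + self.epoch_width <= hi + 1e-12)
        if not m.any():
            raise ValueError("no complete epochs inside window")
        return float(self.frequency[m].mean())


def average_trials(traces: list[Trace]) -> Trace:
    """Pointwise mean of episodically captured sweeps (typically 10)."""
    if not traces:
        raise ValueError("need at least one trace")
    n = traces[0].n_samples
    dt = traces[0].dt
    for tr in traces[1:]:
        if tr.n_samples != n or abs(tr.dt - dt) > 1e-15:
            raise ValueError("traces must share length and sampling interval")
    data = np.mean([tr.data for tr in traces], axis=0)
    return Trace(data, dt, t0=traces[0].t0, units=traces[0].units,
                 label=f"avg({len(traces)})")


def subtract_photocurrent(response: Trace, isolated_photocurrent: Trace,
                          scale: float | None = None) -> Trace:
    """Remove the opsin photocurrent by scaled subtraction.

    The isolated photocurrent (recorded after glutamatergic block) is scaled
    so its peak matches the pre-drug response at the same sample, then
    subtracted, leaving the synaptic component.  Supply ``scale`` to
    override the peak-ratio estimate.
    """
    if response.n_samples != isolated_photocurrent.n_samples or \
            abs(response.dt - isolated_photocurrent.dt) > 1e-15:
        raise ValueError("traces must be aligned with equal dt and length")
    iso = isolated_photocurrent.data
    k = int(np.argmax(np.abs(iso)))
    iso_peak = iso[k]
    if iso_peak == 0:
        raise ValueError("isolated photocurrent has zero peak")
    if scale is None:
        scale = response.data[k] / iso_peak
    out = response.data - scale * iso
    return Trace(out, response.dt, t0=response.t0, units=response.units,
                 label=response.label + "-photo")


def measure_photocurrent(trace: Trace, protocol: StimProtocol,
                         baseline_window_s: float = 0.05) -> float:
    """Photocurrent amplitude: |steady state - baseline| in pA.

    The steady-state window is the last 20% of the light-on span; baseline
    is the median over the window immediately preceding light onset.
    """
    if protocol is None:
        raise ValueError("stimulation protocol required")
    on, off = protocol.light_on_span
    span = off - on
    ss = trace.slice(off - 0.2 * span, off).data
    bl_lo = max(trace.t0, on - baseline_window_s)
    if on - bl_lo >= 50 * trace.dt:
        level, _ = estimate_baseline(trace, (bl_lo, on))
    else:
        level = float(np.median(trace.slice(bl_lo, on).data))
    return float(abs(np.mean(ss) - level))


def _interp_crossing(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where y crosses ``level`` between i-1 and i."""
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def measure_psc_kinetics(trace: Trace, stim_onset: float,
                         polarity: str = "inward",
                         baseline_window_s: float = 0.05,
                         onset_fraction: float = 0.05,
                         response_floor_sd: float = 3.0) -> PSCMetrics:
    """Measure the descriptors of a single dominant PSC.

    Expects an averaged, photocurrent-subtracted trace.  Onset is the first
    crossing of ``onset_fraction`` (default 5%) of the peak, searched
    backwards from the peak; latency is onset minus stimulus onset (ms).
    Rise time spans the 10% and 90% crossings of the rising limb,
    half-width the span above 50%, and the decay constant is a single
    exponential fitted between 90% and 10% of the falling limb.  Charge is
    the trapezoidal integral from onset to return-to-baseline in pA·s.  A
    peak below ``response_floor_sd`` baseline SDs returns an all-None
    record.
    """
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    sign = -1.0 if polarity == "inward" else 1.0
    bl_lo = max(trace.t0, stim_onset - baseline_window_s)
    if stim_onset - bl_lo >= 50 * trace.dt:
        level, sd = estimate_baseline(trace, (bl_lo, stim_onset))
    else:
        seg = trace.slice(trace.t0, stim_onset).data if stim_onset > trace.t0 \
            else trace.data[:1]
        level, sd = float(np.median(seg)), float(np.std(seg))

    i_stim = trace.index_of(stim_onset)
    y = sign * (trace.data - level)
    t = trace.times
    post = y[i_stim:]
    if post.size < 3:
        raise ValueError("trace ends at the stimulus onset")
    # response present?  judged on a 0.5 ms boxcar-smoothed copy so single
    # noise samples cannot clear the floor; kinetics are measured on the
    # raw trace around the smoothed peak
    k = max(int(round(5e-4 / trace.dt)), 1)
    smooth = np.convolve(post, np.ones(k) / k, mode="same")
    i_sm = int(np.argmax(smooth))
    if smooth[i_sm] <= response_floor_sd * sd or smooth[i_sm] <= 0:
        return PSCMetrics()
    lo = max(i_sm - k, 0)
    hi = min(i_sm + k + 1, post.size)
    i_peak = i_stim + lo + int(np.argmax(post[lo:hi]))
    peak = y[i_peak]
    if peak <= 0:
        return PSCMetrics()

    # onset: search backwards from the peak for the 5%-of-peak crossing
    thr = onset_fraction * peak
    j = i_peak
    while j > i_stim and y[j - 1] >= thr:
        j -= 1
    t_onset = _interp_crossing(t, y, j, thr) if j > i_stim else t[i_stim]
    latency_ms = (t_onset - stim_onset) * 1e3

    # rising-limb 10% / 90% crossings (searched backwards from the peak so
    # noise before onset cannot capture them)
    def rising_crossing(level_frac: float) -> float:
        lv = level_frac * peak
        j = i_peak
        while j > i_stim and y[j - 1] >= lv:
            j -= 1
        return _interp_crossing(t, y, j, lv)

    t10, t90 = rising_crossing(0.1), rising_crossing(0.9)
    rise_ms = (t90 - t10) * 1e3

    # half-width: last forward crossing below 50% after the peak
    def falling_crossing(level_frac: float) -> float | None:
        lv = level_frac * peak
        j = i_peak
        while j < y.size - 1 and y[j + 1] > lv:
            j += 1
        if j >= y.size - 1:
            return None
        return _interp_crossing(t, y, j + 1, lv)

    t_half_rise = rising_crossing(0.5)
    t_half_fall = falling_crossing(0.5)
    half_width_ms = None if t_half_fall is None else (t_half_fall - t_half_rise) * 1e3

    # decay constant: single exponential between 90% and 10% of the decay
    t90_f, t10_f = falling_crossing(0.9), falling_crossing(0.1)
    decay_tau_ms = None
    if t90_f is not None and t10_f is not None and t10_f > t90_f:
        i0 = trace.index_of(t90_f)
        i1 = trace.index_of(t10_f) + 1
        tt = (t[i0:i1] - t[i0]) * 1e3
        yy = y[i0:i1]
        if yy.size >= 3 and np.all(np.isfinite(yy)):
            # log-linear start, refined by nonlinear least squares
            pos = yy > 0
            if pos.sum() >= 3:
                slope, intercept = np.polyfit(tt[pos], np.log(yy[pos]), 1)
                tau0 = -1.0 / slope if slope < 0 else (tt[-1] - tt[0])
                try:
                    popt, _ = curve_fit(
                        lambda x, a, tau: a * np.exp(-x / tau), tt, yy,
                        p0=[float(np.exp(intercept)), float(abs(tau0))],
                        maxfev=2000)
                    decay_tau_ms = float(abs(popt[1]))
                except RuntimeError:
                    decay_tau_ms = float(abs(tau0))

    # charge: integral from onset to return-to-baseline (first crossing of
    # the onset threshold after the peak, or trace end)
    j_end = i_peak
    while j_end < y.size - 1 and y[j_end + 1] > thr:
        j_end += 1
    i_on = trace.index_of(t_onset)
    charge_pa_s = float(np.trapezoid(y[i_on:j_end + 1], t[i_on:j_end + 1]))

    return PSCMetrics(latency=latency_ms, peak_amplitude=float(peak),
                      rise_time_10_90=rise_ms, half_width=half_width_ms,
                      decay_tau=decay_tau_ms, charge=charge_pa_s)


def epoch_frequency(event_times, span: tuple[float, float],
                    epoch_width: float = 0.1) -> FrequencySeries:
    """Event frequency per fixed epoch: count × (1/width) Hz.

    With the default 100 ms epochs this is the count multiplied by 10.  A
    partial trailing epoch is dropped.
    """
    if epoch_width <= 0:
        raise ValueError("epoch_width must be positive")
    lo, hi = span
    if hi <= lo:
        raise ValueError("empty span")
    times = np.sort(np.asarray(event_times, dtype=float))
    n_epochs = int(np.floor((hi - lo) / epoch_width + 1e-9))
    starts = lo + np.arange(n_epochs) * epoch_width
    counts = np.histogram(times, bins=np.append(starts, starts[-1] + epoch_width))[0] \
        if n_epochs else np.array([])
    return FrequencySeries(starts, counts / epoch_width, epoch_width)
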