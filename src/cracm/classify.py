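"""Circuit-mapping decision rules.

The rules implemented here turn measured latencies, amplitudes and rates
into circuit-level labels: monosynaptic latency windows built from
action-potential recruitment delays, direct/delayed assignment,
GABA/glycine dominance from bicuculline block, the 4-SD spontaneous-rate
potentiation criterion, spike fidelity, and the discharge-pattern taxonomy
(tonic firing, initial bursting, delayed firing, single spiking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psc import FrequencySeries

__all__ = ["RecruitmentStats", "LatencyWindow", "InhibitionThresholds",
           "RateChangeParams", "per_pulse_delays", "recruitment_delay",
           "spike_fidelity", "monosynaptic_window", "classify_latency",
           "classify_inhibition", "detect_rate_change",
           "classify_firing_pattern"]


@dataclass
class RecruitmentStats:
    """Photostimulation-to-first-spike delay statistics (ms).

    ``delays`` holds one mean delay per cell; mean/sd/sem summarise the
    per-cell sample (sd with n-1 degrees of freedom)."""

    delays: np.ndarray
    mean: float | None = None
    sd: float | None = None
    sem: float | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        n = self.delays.size
        if n:
            self.mean = float(self.delays.mean())
            if n > 1:
                self.sd = float(self.delays.std(ddof=1))
                self.sem = self.sd / np.sqrt(n)

    @property
    def n(self) -> int:
        return self.delays.size


@dataclass
class LatencyWindow:
    """Monosynaptic acceptance window (ms): recruitment mean plus a fixed
    conduction+synaptic delay, ± 2 dispersions."""

    center: float
    halfwidth: float
    conduction_synaptic_delay: float = 2.5

    def __post_init__(self) -> None:
        if self.halfwidth < 0:
            raise ValueError("halfwidth must be non-negative")

    @property
    def lower(self) -> float:
        return self.center - self.halfwidth

    @property
    def upper(self) -> float:
        return self.center + self.halfwidth


@dataclass
class InhibitionThresholds:
    """Bicuculline-block decision boundaries: block ≥ 0.80 is GABA-dominant,
    block < 0.20 glycine-dominant, otherwise mixed."""

    gaba_dominant_min_block: float = 0.80
    glycine_dominant_max_block: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.glycine_dominant_max_block < self.gaba_dominant_min_block < 1:
            raise ValueError("require 0 < glycine threshold < gaba threshold < 1")


@dataclass
class RateChangeParams:
    """Windows (s) and SD multiplier for the rate-potentiation test."""

    k_sd: float = 4.0
    pre_window: tuple = (0.0, 30.0)
    test_window: tuple = (40.0, 45.0)
    min_pre_epochs: int = 10

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        a, b = self.pre_window
        c, d = self.test_window
        if not (b > a and d > c):
            raise ValueError("windows must be non-empty")
        if max(a, c) < min(b, d):
            raise ValueError("pre and test windows must be disjoint")


# ---------------------------------------------------------------------------

def per_pulse_delays(spike_times, pulse_onsets,
                     response_window_ms: float = 10.0) -> np.ndarray:
    """First-spike delay (ms) after each pulse; NaN where no spike falls in
    the response window.  A spike exactly at the onset counts as delay 0."""
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    out = np.full(len(pulse_onsets), np.nan)
    w = response_window_ms * 1e-3
    for i, onset in enumerate(np.asarray(pulse_onsets, dtype=float)):
        j = np.searchsorted(spikes, onset, side="left")
        if j < spikes.size and spikes[j] <= onset + w:
            out[i] = (spikes[j] - onset) * 1e3
    return out


def recruitment_delay(spike_times_per_cell, pulse_onsets,
                      response_window_ms: float = 10.0) -> RecruitmentStats:
    """Group recruitment-delay statistics over cells.

    ``spike_times_per_cell`` is a sequence of spike-time arrays (one per
    cell, in s) responding to the shared ``pulse_onsets``.  Each cell
    contributes the mean of its per-pulse first-spike delays; cells with no
    spike in any response window are dropped.
    """
    delays = []
    for spikes in spike_times_per_cell:
        d = per_pulse_delays(spikes, pulse_onsets, response_window_ms)
        d = d[~np.isnan(d)]
        if d.size:
            delays.append(d.mean())
    return RecruitmentStats(np.asarray(delays))


def spike_fidelity(pulse_onsets, spike_times, window_ms: float = 10.0) -> float:
    """Fraction of pulses followed by at least one spike within the window."""
    onsets = np.asarray(pulse_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one pulse")
    ipi = np.diff(onsets)
    if ipi.size and window_ms * 1e-3 >= ipi.min():
        raise ValueError("window must be shorter than the inter-pulse interval")
    d = per_pulse_delays(spike_times, onsets, window_ms)
    return float(np.mean(~np.isnan(d)))


def monosynaptic_window(recruit: RecruitmentStats, delay_ms: float = 2.5,
                        dispersion: str = "sd") -> LatencyWindow:
    """Monosynaptic window: recruitment mean + conduction/synaptic delay,
    ± 2 × the chosen dispersion ("sd" or "sem") of the recruitment sample."""
    if recruit.mean is None or not np.isfinite(recruit.mean):
        raise ValueError("recruitment mean unavailable")
    if dispersion not in ("sd", "sem"):
        raise ValueError("dispersion must be 'sd' or 'sem'")
    disp = recruit.sd if dispersion == "sd" else recruit.sem
    if disp is None:
        raise ValueError("dispersion unavailable (need at least two cells)")
    return LatencyWindow(center=recruit.mean + delay_ms, halfwidth=2.0 * disp,
                         conduction_synaptic_delay=delay_ms)


def classify_latency(latency_ms: float, window: LatencyWindow) -> str:
    """Direct (monosynaptic) if the latency does not exceed the window's
    upper bound, else delayed.  Latencies below the lower bound are direct:
    a response cannot be faster than monosynaptic."""
    if latency_ms < 0:
        raise ValueError("latency must be non-negative")
    return "direct" if latency_ms <= window.upper else "delayed"


def classify_inhibition(control_amp: float, bicuculline_amp: float,
                        thresholds: InhibitionThresholds | None = None,
                        tol: float = 0.05) -> str:
    """GABA/glycine dominance from the bicuculline-blocked fraction.

    ``block = 1 - bicuculline/control``; block of 80% or greater is
    GABA-dominant, a decrease of less than 20% is glycine-dominant, and
    intermediate sensitivity is mixed.  Small apparent potentiation in
    bicuculline (up to ``tol`` relative) is tolerated and classed by the
    same rule.
    """
    if thresholds is None:
        thresholds = InhibitionThresholds()
    if control_amp <= 0:
        raise ValueError("control amplitude must be positive")
    if bicuculline_amp < 0 or bicuculline_amp > control_amp * (1 + tol):
        raise ValueError("bicuculline amplitude outside the plausible range")
    block = 1.0 - bicuculline_amp / control_amp
    eps = 1e-12  # keep exact printed boundaries stable under round-off
    if block >= thresholds.gaba_dominant_min_block - eps:
        return "GABA-dominant"
    if block < thresholds.glycine_dominant_max_block - eps:
        return "glycine-dominant"
    return "mixed"


def detect_rate_change(series: FrequencySeries,
                       params: RateChangeParams | None = None) -> tuple[bool, float]:
    """The 4-SD rate-potentiation test.

    Flags a session when the mean test-window epoch frequency exceeds the
    mean pre-window frequency by more than ``k_sd`` times the SD of the
    pre-window epoch frequencies.  Returns (flag, mean frequency change in
    Hz).  Requires at least ``min_pre_epochs`` complete pre-window epochs.
    """
    if params is None:
        params = RateChangeParams()
    lo, hi = params.pre_window
    m_pre = (series.epoch_starts >= lo) & \
            (series.epoch_starts + series.epoch_width <= hi + 1e-12)
    if m_pre.sum() < params.min_pre_epochs:
        raise ValueError(f"need at least {params.min_pre_epochs} pre-window epochs")
    pre = series.frequency[m_pre]
    test_mean = series.window_mean(params.test_window)
    pre_mean = float(pre.mean())
    pre_sd = float(pre.std(ddof=1))
    flag = test_mean > pre_mean + params.k_sd * pre_sd
    return bool(flag), float(test_mean - pre_mean)


def classify_firing_pattern(spike_times, step_onset: float,
                            step_duration: float,
                            df_latency_ms: float = 100.0,
                            tonic_span_fraction: float = 0.8,
                            burst_window_fraction: float = 0.2) -> str:
    """Discharge-pattern taxonomy for a depolarising current step.

    Deterministic precedence: SS (exactly one spike), then DF (first-spike
    latency above ``df_latency_ms``), then TF (spikes spanning at least
    ``tonic_span_fraction`` of the step), then IB (repetitive firing
    confined to the early step).  No spikes → "NF" (non-firing).
    """
    if step_duration <= 0:
        raise ValueError("step_duration must be positive")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    spikes = spikes[(spikes >= step_onset) &
                    (spikes <= step_onset + step_duration)]
    if spikes.size == 0:
        return "NF"
    if spikes.size == 1:
        return "SS"
    first_latency_ms = (spikes[0] - step_onset) * 1e3
    if first_latency_ms > df_latency_ms:
        return "DF"
    span = spikes[-1] - spikes[0]
    if span >= tonic_span_fraction * step_duration:
        return "TF"
    return "IB"
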