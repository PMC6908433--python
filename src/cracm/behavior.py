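"""Scoring of timestamped behaviour logs.

Peristimulus histograms of time-in-behaviour (5 s bins), response latency
and total duration, per-body-region onset latencies, simplified up-down
(SUDO) von Frey thresholds, and place-preference dwell times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BehaviorLog, Bout

__all__ = ["BehaviorLog", "Bout", "PeristimulusHistogram",
           "peristimulus_histogram", "response_metrics",
           "region_onset_latencies", "sudo_session_score", "sudo_threshold",
           "time_in_zone", "DEFAULT_FILAMENTS", "log_from_csv", "log_to_csv"]

# Standard von Frey filament forces in grams (0.008-2 g set), ordered by
# index; the SUDO score is a (possibly fractional) position on this scale.
DEFAULT_FILAMENTS = (0.008, 0.02, 0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0)


@dataclass
class PeristimulusHistogram:
    """Per-bin proportion of time spent in behaviour."""

    bin_edges: np.ndarray       # s, len = n_bins + 1
    proportion: np.ndarray      # [0, 1] per bin

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.proportion = np.asarray(self.proportion, dtype=float)
        if self.bin_edges.size != self.proportion.size + 1:
            raise ValueError("need n_bins + 1 edges")
        if np.any(self.proportion < -1e-12) or np.any(self.proportion > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total_time(self) -> float:
        """Total in-behaviour time across the analysis span (s)."""
        return float(np.sum(self.proportion * np.diff(self.bin_edges)))

    def heat_colors(self) -> np.ndarray:
        """Linear black→red colour map of the proportions, as RGB rows."""
        p = np.clip(self.proportion, 0, 1)
        return np.column_stack([p, np.zeros_like(p), np.zeros_like(p)])


def peristimulus_histogram(log: BehaviorLog, bin_s: float = 5.0,
                           span: tuple[float, float] | None = None) -> PeristimulusHistogram:
    """Proportion of each bin covered by bouts.

    Bins tile the analysis span (default: the whole session, aligned to the
    session start); bouts straddling a bin edge contribute to each bin in
    proportion to their overlap.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    if span is None:
        span = (0.0, log.session_length)
    lo, hi = span
    n_bins = int(np.ceil((hi - lo) / bin_s - 1e-9))
    edges = lo + np.arange(n_bins + 1) * bin_s
    covered = np.zeros(n_bins)
    # coverage is the union of bout intervals: bouts at different body
    # regions overlap in time and a bin can only be 100% in-behaviour
    for b0, b1 in _merge_intervals([(b.onset_s, b.onset_s + b.duration_s)
                                    for b in log.bouts]):
        covered += np.maximum(
            np.minimum(edges[1:], b1) - np.maximum(edges[:-1], b0), 0.0)
    widths = np.diff(edges)
    return PeristimulusHistogram(edges, np.clip(covered / widths, 0.0, 1.0))


def _merge_intervals(intervals):
    """Union of (start, stop) intervals as a sorted disjoint list."""
    merged: list[list[float]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def response_metrics(log: BehaviorLog) -> tuple[float | None, float]:
    """(latency_s, total_duration_s) of the post-stimulus response.

    Latency is the first post-stimulus bout onset minus the stimulation
    onset (None when there is none); total duration sums bout durations of
    bouts starting at or after the stimulation onset.
    """
    post = [b for b in log.bouts if b.onset_s >= log.stim_onset]
    if not post:
        return None, 0.0
    latency = post[0].onset_s - log.stim_onset
    return float(latency), float(sum(b.duration_s for b in post))


def region_onset_latencies(log: BehaviorLog) -> dict:
    """First post-stimulus bout latency (s) per body region; None where a
    region never responded."""
    out = {r: None for r in ("paw", "limb", "back", "tail")}
    for b in log.bouts:
        if b.onset_s < log.stim_onset or b.region not in out:
            continue
        lat = b.onset_s - log.stim_onset
        if out[b.region] is None or lat < out[b.region]:
            out[b.region] = float(lat)
    return out


# ---------------------------------------------------------------------------
# SUDO von Frey

def sudo_session_score(responses, start_index: int,
                       n_filaments: int = len(DEFAULT_FILAMENTS)) -> float:
    """Adjusted filament position after one five-stimulus up-down session.

    The walk starts at ``start_index``; a withdrawal (True) steps one
    filament down, no withdrawal steps one up, clamped to the filament set.
    The score is the position of the fifth stimulus, minus 0.5 if it evoked
    a withdrawal, plus 0.5 otherwise.
    """
    responses = [bool(r) for r in responses]
    if len(responses) != 5:
        raise ValueError("a SUDO session is exactly five response/no-response trials")
    if not 0 <= start_index < n_filaments:
        raise ValueError("start_index outside the filament set")
    pos = start_index
    for r in responses[:-1]:
        pos = pos - 1 if r else pos + 1
        pos = min(max(pos, 0), n_filaments - 1)
    return pos - 0.5 if responses[-1] else pos + 0.5


def sudo_threshold(sessions, filament_table=DEFAULT_FILAMENTS) -> float:
    """Withdrawal threshold in grams from repeated SUDO sessions.

    ``sessions`` is a sequence of (start_index, responses) pairs, one per
    testing day.  Scores are averaged across sessions and the mean
    (fractional) position is converted to grams by interpolation on the
    log-force filament scale, extrapolating linearly in log force beyond
    the set's ends.
    """
    forces = np.asarray(filament_table, dtype=float)
    if forces.ndim != 1 or forces.size < 2 or np.any(np.diff(forces) <= 0):
        raise ValueError("filament table must be increasing forces in grams")
    scores = [sudo_session_score(resp, start, forces.size)
              for start, resp in sessions]
    mean_pos = float(np.mean(scores))
    logf = np.log10(forces)
    idx = np.arange(forces.size, dtype=float)
    if mean_pos <= 0:
        val = logf[0] + (logf[1] - logf[0]) * mean_pos
    elif mean_pos >= forces.size - 1:
        val = logf[-1] + (logf[-1] - logf[-2]) * (mean_pos - (forces.size - 1))
    else:
        val = float(np.interp(mean_pos, idx, logf))
    return float(10.0 ** val)


# ---------------------------------------------------------------------------
# Place-preference dwell time

def time_in_zone(track, zones, session_end: float | None = None) -> dict:
    """Total dwell time (s) per zone from a (timestamp, zone) track.

    Each sample marks entry into a zone that lasts until the next sample
    (or ``session_end``, default the last timestamp).  Zone times partition
    the tracked span exactly.
    """
    track = list(track)
    if not track:
        raise ValueError("empty track")
    times = np.asarray([t for t, _ in track], dtype=float)
    labels = [z for _, z in track]
    if np.any(np.diff(times) < 0):
        raise ValueError("timestamps must be increasing")
    unknown = set(labels) - set(zones)
    if unknown:
        raise ValueError(f"unknown zone labels: {sorted(unknown)}")
    if session_end is None:
        session_end = float(times[-1])
    if session_end < times[-1]:
        raise ValueError("session_end precedes the last sample")
    out = {z: 0.0 for z in zones}
    bounds = np.append(times, session_end)
    for z, t0, t1 in zip(labels, bounds[:-1], bounds[1:]):
        out[z] += float(t1 - t0)
    return out


# ---------------------------------------------------------------------------
# CSV I/O

def log_to_csv(log: BehaviorLog, path) -> None:
    pd.DataFrame([{"onset_s": b.onset_s, "duration_s": b.duration_s,
                   "region": b.region, "code": b.code}
                  for b in log.bouts]).to_csv(path, index=False)


def log_from_csv(path, stim_onset: float, session_length: float) -> BehaviorLog:
    df = pd.read_csv(path)
    bouts = [Bout(r.onset_s, r.duration_s, r.region, r.code)
             for r in df.itertuples()]
    return BehaviorLog(bouts, stim_onset=stim_onset, session_length=session_length)
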