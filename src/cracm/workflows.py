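"""End-to-end analysis chains over simulated cohorts.

These functions wire the generator and the analysis stages together the way
a circuit-mapping study would run them: simulate a cohort of cells, isolate
the photocurrent pharmacologically, subtract it, average trials, measure
kinetics, and summarise across cells.  They are also what the worked
examples and the reproduction script call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classify import RecruitmentStats, classify_inhibition, recruitment_delay
from .core import StimProtocol
from .psc import average_trials, measure_psc_kinetics, subtract_photocurrent
from .synthetic import (ConnectivityParams, PharmacologyCondition,
                        PhotocurrentParams, RecordingConfig,
                        SynapticEventParams, _trunc_gauss, apply_pharmacology,
                        get_preset, split_seed, synthesize_recording)

__all__ = ["tuned_waveform_kinetics", "simulate_oepsc_cell",
           "oepsc_cohort_latency", "simulate_recruitment_cohort",
           "simulate_pharmacology_series", "classify_pharmacology_series"]


def tuned_waveform_kinetics(rise_time: float | None = None,
                            half_width: float | None = None,
                            sampling_khz: float = 100.0,
                            amplitude: float = 87.59):
    """Measure kinetics on a noiseless biexponential tuned to one target.

    Root-finds time constants whose analytic 10-90% rise time *or*
    half-width equals the target (ms), renders the waveform noiselessly at
    the given sampling rate, and runs the kinetics measurement on it.
    Returns the measured :class:`~cracm.psc.PSCMetrics`.
    """
    from .core import Trace
    from .synthetic import design_biexp_params, generate_psc_waveform

    params = design_biexp_params(rise_time=rise_time, half_width=half_width,
                                 amplitude_mean=amplitude)
    dt = 1e-3 / sampling_khz
    w = generate_psc_waveform(params, dt * 1e3)
    stim_onset = 0.05
    i0 = int(round(stim_onset / dt))
    data = np.zeros(i0 + w.size + int(0.02 / dt))
    data[i0:i0 + w.size] = -amplitude * w
    return measure_psc_kinetics(Trace(data, dt), stim_onset, "inward")


def simulate_oepsc_cell(latency_ms: float, kernel: SynapticEventParams,
                        seed: int, n_trials: int = 10,
                        noise_rms: float = 3.0,
                        photocurrent: PhotocurrentParams | None = None,
                        trial_jitter_ms: float = 0.3,
                        duration: float = 0.3,
                        stim_onset: float = 0.1) -> dict:
    """Simulate one cell's control and CNQX sweeps for a brief mapping pulse.

    Each of the ``n_trials`` control sweeps holds the photocurrent plus one
    evoked PSC at ``stim_onset + latency`` (with a small trial-to-trial
    jitter); the CNQX sweeps hold the photocurrent and noise only.  Returns
    the sweeps, the protocol and the ground-truth latency.
    """
    if photocurrent is None:
        photocurrent = get_preset("photocurrent_excitatory")
    protocol = StimProtocol.single_pulse(onset=stim_onset, intensity=16.0)
    conn = ConnectivityParams(
        connection_probability=1.0, release_probability=1.0,
        direct_latency_mean=latency_ms,
        direct_latency_sd=max(trial_jitter_ms, 1e-9),
        delayed_latency_mean=latency_ms + 1e3,  # unused: direct_fraction 1
        direct_fraction=1.0)
    base = RecordingConfig(duration=duration, protocol=protocol,
                           photocurrent=photocurrent,
                           evoked=conn, evoked_params=kernel,
                           noise_rms=noise_rms)
    cnqx_cfg = apply_pharmacology(base, PharmacologyCondition("CNQX"))
    trial_seeds = np.random.SeedSequence(seed).generate_state(2 * n_trials) % (2 ** 31)
    control = [synthesize_recording(base, int(s)) for s in trial_seeds[:n_trials]]
    cnqx = [synthesize_recording(cnqx_cfg, int(s)) for s in trial_seeds[n_trials:]]
    return {"control": control, "cnqx": cnqx, "protocol": protocol,
            "stim_onset": stim_onset, "true_latency_ms": latency_ms}


def oepsc_cohort_latency(preset_name: str = "CR-ChR2 oEPSC",
                         n_cells: int | None = None, n_trials: int = 10,
                         noise_rms: float = 3.0, seed: int = 0) -> dict:
    """Full chain: simulate → subtract photocurrent → average → measure.

    Per-cell generative latencies are truncated-Gaussian draws around the
    preset's group mean with its between-cell SD.  For each cell the CNQX
    average is scaled and subtracted from the control average and the
    onset latency measured; the grand mean over cells is returned together
    with the per-cell values and the generative SEM.
    """
    preset = get_preset(preset_name)
    if n_cells is None:
        n_cells = preset["n"]
    rng = split_seed(seed)["misc"]
    cell_latencies = _trunc_gauss(rng, preset["latency_mean"],
                                  preset["latency_sd_between"], n_cells)
    cell_seeds = np.random.SeedSequence([seed, 1]).generate_state(n_cells) % (2 ** 31)
    measured = []
    for lat, cs in zip(cell_latencies, cell_seeds):
        cell = simulate_oepsc_cell(float(lat), preset["kernel"], int(cs),
                                   n_trials=n_trials, noise_rms=noise_rms)
        avg_control = average_trials([b.trace for b in cell["control"]])
        avg_cnqx = average_trials([b.trace for b in cell["cnqx"]])
        synaptic = subtract_photocurrent(avg_control, avg_cnqx)
        metrics = measure_psc_kinetics(synaptic, cell["stim_onset"],
                                       polarity="inward")
        if metrics.latency is not None:
            measured.append(metrics.latency)
    measured = np.asarray(measured)
    return {"per_cell_latency_ms": measured,
            "grand_mean_ms": float(measured.mean()),
            "generative_mean_ms": preset["latency_mean"],
            "generative_sem_ms": preset["latency_sem"],
            "n_cells": int(measured.size)}


def simulate_recruitment_cohort(preset_name: str = "recruitment_excitatory",
                                n_cells: int | None = None,
                                n_pulses: int = 10, seed: int = 0,
                                within_cell_jitter_ms: float = 0.3) -> RecruitmentStats:
    """Simulated spike responses to brief pulses, scored by the recruitment
    operation.

    Per-cell delays are truncated-Gaussian draws around the preset mean with
    its between-cell SD; each pulse elicits one spike at the cell's delay
    plus a small within-cell jitter.
    """
    preset = get_preset(preset_name)
    if n_cells is None:
        n_cells = preset["n"]
    rng = split_seed(seed)["misc"]
    cell_delays = _trunc_gauss(rng, preset["mean"], preset["sd_between"], n_cells)
    onsets = np.arange(n_pulses) * 0.2 + 0.1
    spike_trains = []
    for d in cell_delays:
        jit = _trunc_gauss(rng, d, max(within_cell_jitter_ms, 1e-9), n_pulses)
        spike_trains.append(onsets + jit * 1e-3)
    return recruitment_delay(spike_trains, onsets)


def simulate_pharmacology_series(mix_preset: str = "inhibition_mix_excitatory_cr_chr2",
                                 n_series: int = 100, noise_rms: float = 2.0,
                                 seed: int = 0) -> list:
    """Control/bicuculline oIPSC amplitude pairs from a block-fraction mixture.

    Per-cell bicuculline block fractions are drawn from the preset mixture
    (GABA-dominant / mixed / glycine-dominant components); the control
    amplitude is log-normal around the preset group mean and the measured
    amplitudes carry additive Gaussian noise.  Returns (control_pA,
    bicuculline_pA, true_block) triples.
    """
    preset = get_preset(mix_preset)
    rng = split_seed(seed)["misc"]
    out = []
    for _ in range(n_series):
        u = rng.uniform()
        if u < preset["gaba_fraction"]:
            block = rng.uniform(*preset["gaba_block"])
        elif u < preset["gaba_fraction"] + preset["glycine_fraction"]:
            block = rng.uniform(*preset["glycine_block"])
        else:
            block = rng.uniform(*preset["mixed_block"])
        mu = preset["control_amplitude"]
        cv = preset["control_amplitude_cv"]
        sigma = np.sqrt(np.log(1 + cv ** 2))
        ctrl = mu * np.exp(rng.normal(-0.5 * sigma ** 2, sigma))
        bic = ctrl * (1 - block)
        ctrl_meas = max(ctrl + rng.normal(0, noise_rms), 1e-6)
        bic_meas = max(bic + rng.normal(0, noise_rms), 0.0)
        out.append((float(ctrl_meas), float(bic_meas), float(block)))
    return out


def classify_pharmacology_series(series) -> dict:
    """Class counts and percentages over (control, bicuculline, ...) pairs."""
    # apparent potentiation in bicuculline (noise) is treated as zero block
    labels = [classify_inhibition(c, min(b, c)) for c, b, *_ in series]
    n = len(labels)
    counts = {k: labels.count(k) for k in
              ("GABA-dominant", "mixed", "glycine-dominant")}
    return {"counts": counts,
            "percent": {k: 100.0 * v / n for k, v in counts.items()},
            "n": n}
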