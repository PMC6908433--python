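"""Decision rules: recruitment delay, spike fidelity, monosynaptic windows,
latency and inhibition classification, 4-SD rate change, firing patterns."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cracm.classify import (InhibitionThresholds, LatencyWindow,
                            RateChangeParams, RecruitmentStats,
                            classify_firing_pattern, classify_inhibition,
                            classify_latency, detect_rate_change,
                            monosynaptic_window, per_pulse_delays,
                            recruitment_delay, spike_fidelity)
from cracm.psc import epoch_frequency
from cracm.synthetic import (generate_evoked_latencies,
                             generate_potentiation_session, get_preset)
from cracm.workflows import simulate_recruitment_cohort


class TestRecruitmentDelay:
    def test_spike_at_onset_zero_delay(self):
        d = per_pulse_delays([1.0], [1.0])
        assert d[0] == 0.0

    def test_constant_injected_delay(self):
        onsets = np.arange(10) * 0.2
        stats = recruitment_delay([onsets + 0.004, onsets + 0.004], onsets)
        assert np.isclose(stats.mean, 4.0)
        assert stats.sd == 0.0

    def test_no_spikes_empty_stats(self):
        stats = recruitment_delay([[], []], [0.1, 0.3])
        assert stats.n == 0 and stats.mean is None

    def test_excitatory_preset_group_mean(self):
        # 29 simulated cells around the 3.29 ms excitatory recruitment mean
        stats = simulate_recruitment_cohort(seed=5)
        preset = get_preset("recruitment_excitatory")
        assert stats.n == 29
        assert abs(stats.mean - preset["mean"]) < 2 * preset["sem"]


class TestSpikeFidelity:
    def test_extremes(self):
        onsets = np.arange(10) * 0.1
        assert spike_fidelity(onsets, []) == 0.0
        assert spike_fidelity(onsets, onsets + 0.002) == 1.0

    def test_refractory_neuron_frequency_dependence(self):
        # absolute refractory period 60 ms: follows 10 Hz, drops ~half at 20 Hz
        def spikes_for(freq):
            onsets = np.arange(20) / freq
            out, last = [], -np.inf
            for t in onsets:
                if t + 0.002 - last >= 0.060:
                    out.append(t + 0.002)
                    last = t + 0.002
            return onsets, out

        onsets, sp = spikes_for(10.0)
        assert spike_fidelity(onsets, sp) == 1.0
        onsets, sp = spikes_for(20.0)
        assert abs(spike_fidelity(onsets, sp) - 0.5) <= 0.05

    def test_no_pulses_rejected(self):
        with pytest.raises(ValueError):
            spike_fidelity([], [0.1])


class TestMonosynapticWindow:
    def test_excitatory_center_arithmetic(self):
        stats = RecruitmentStats(np.array([3.29, 3.29, 3.29]) +
                                 np.array([-0.1, 0.0, 0.1]))
        w = monosynaptic_window(stats, delay_ms=2.5)
        assert np.isclose(w.center, 5.79, atol=1e-9)

    def test_inhibitory_center_arithmetic(self):
        stats = RecruitmentStats([2.29, 2.39, 2.49])
        w = monosynaptic_window(stats)
        assert np.isclose(w.center, 4.89)

    def test_degenerate_window_at_zero_sd(self):
        w = monosynaptic_window(RecruitmentStats([3.0, 3.0]))
        assert w.halfwidth == 0.0
        assert w.lower == w.upper == w.center

    def test_single_cell_dispersion_unavailable(self):
        with pytest.raises(ValueError):
            monosynaptic_window(RecruitmentStats([3.0]))

    def test_sem_option_narrows_window(self):
        stats = RecruitmentStats([2.0, 3.0, 4.0, 5.0])
        w_sd = monosynaptic_window(stats, dispersion="sd")
        w_sem = monosynaptic_window(stats, dispersion="sem")
        assert w_sem.halfwidth == pytest.approx(w_sd.halfwidth / 2.0)


class TestClassifyLatency:
    def _window(self):
        return LatencyWindow(center=5.79, halfwidth=2.26)

    def test_below_lower_bound_is_direct(self):
        w = self._window()
        assert classify_latency(w.lower - 1.0, w) == "direct"

    def test_boundary(self):
        w = self._window()
        assert classify_latency(w.upper, w) == "direct"
        assert classify_latency(w.upper + 1e-9, w) == "delayed"

    def test_scale_consistency(self):
        # re-expressing all times in seconds leaves every label unchanged
        w_ms = self._window()
        w_s = LatencyWindow(center=w_ms.center * 1e-3,
                            halfwidth=w_ms.halfwidth * 1e-3)
        for lat in (0.5, 5.0, 8.0, 8.1, 20.0):
            assert classify_latency(lat, w_ms) == classify_latency(lat * 1e-3, w_s)

    def test_mixture_fractions_recovered(self):
        # the CR-ChR2 mixture is 35% direct / 65% delayed; the window built
        # from the recruitment preset must recover those proportions
        from cracm.core import StimProtocol
        conn = get_preset("latency_mix_cr_chr2")
        proto = StimProtocol.train(0.0, 10.0, 200.0, pulse_width=1e-3)
        rng = np.random.default_rng(21)
        recruit = get_preset("recruitment_excitatory")
        window = LatencyWindow(center=recruit["mean"] + 2.5,
                               halfwidth=2 * recruit["sd_between"])
        lats, origins = [], []
        for t, o in generate_evoked_latencies(conn, proto, rng):
            k = np.searchsorted(proto.pulse_onsets, t) - 1
            lats.append((t - proto.pulse_onsets[k]) * 1e3)
            origins.append(o)
        labels = [classify_latency(l, window) for l in lats]
        frac_direct = np.mean([lb == "direct" for lb in labels])
        assert abs(frac_direct - 0.35) < 3 * np.sqrt(0.35 * 0.65 / len(labels))

    def test_label_recovery_accuracy(self):
        # separated presets: >= 90% agreement with generative origins
        from cracm.core import StimProtocol
        conn = get_preset("latency_mix_cr_chr2")
        sep = (conn.delayed_latency_mean - conn.direct_latency_mean) / \
            np.hypot(conn.direct_latency_sd, conn.delayed_latency_sd)
        assert sep > 2.0
        proto = StimProtocol.train(0.0, 10.0, 100.0, pulse_width=1e-3)
        rng = np.random.default_rng(4)
        recruit = get_preset("recruitment_excitatory")
        window = LatencyWindow(center=recruit["mean"] + 2.5,
                               halfwidth=2 * recruit["sd_between"])
        correct = total = 0
        for t, o in generate_evoked_latencies(conn, proto, rng):
            k = np.searchsorted(proto.pulse_onsets, t) - 1
            lat = (t - proto.pulse_onsets[k]) * 1e3
            correct += (classify_latency(lat, window) == o)
            total += 1
        assert correct / total >= 0.90


class TestClassifyInhibition:
    def test_printed_rule_examples(self):
        assert classify_inhibition(100.0, 15.0) == "GABA-dominant"   # 85% block
        assert classify_inhibition(100.0, 90.0) == "glycine-dominant"  # 10%
        assert classify_inhibition(100.0, 50.0) == "mixed"

    def test_boundary_semantics_as_printed(self):
        # "80% or greater" is GABA-dominant; "less than 20%" is glycine
        assert classify_inhibition(100.0, 20.0) == "GABA-dominant"
        assert classify_inhibition(100.0, 80.0) == "mixed"

    def test_invalid_control_rejected(self):
        with pytest.raises(ValueError):
            classify_inhibition(0.0, 0.0)
        with pytest.raises(ValueError):
            classify_inhibition(10.0, 12.0)

    @settings(derandomize=True, max_examples=200)
    @given(b1=st.floats(0.0, 1.0), b2=st.floats(0.0, 1.0))
    def test_monotone_in_block_fraction(self, b1, b2):
        # more block never moves the label toward glycine-dominant
        order = {"glycine-dominant": 0, "mixed": 1, "GABA-dominant": 2}
        lo, hi = sorted([b1, b2])
        c_lo = classify_inhibition(100.0, 100.0 * (1 - lo))
        c_hi = classify_inhibition(100.0, 100.0 * (1 - hi))
        assert order[c_hi] >= order[c_lo]


class TestDetectRateChange:
    def test_stationary_null_not_flagged(self):
        flags = []
        for s in range(50):
            b = generate_potentiation_session(potentiation_factor=1.0, seed=s)
            fs = epoch_frequency(b.event_times, (0.0, 100.0))
            flags.append(detect_rate_change(fs)[0])
        assert np.mean(flags) < 0.05

    def test_potentiated_session_flagged(self):
        b = generate_potentiation_session(potentiation_factor=5.0, seed=1)
        fs = epoch_frequency(b.event_times, (0.0, 100.0))
        flag, delta = detect_rate_change(fs)
        assert flag and delta > 0

    def test_insufficient_pre_epochs_rejected(self):
        fs = epoch_frequency([0.05], (0.0, 50.0))
        params = RateChangeParams(pre_window=(0.0, 0.5), test_window=(40.0, 45.0))
        with pytest.raises(ValueError):
            detect_rate_change(fs, params)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            RateChangeParams(pre_window=(0.0, 30.0), test_window=(20.0, 45.0))


class TestFiringPattern:
    def test_single_spike_near_onset(self):
        assert classify_firing_pattern([0.12], 0.1, 1.0) == "SS"

    def test_delayed_firing(self):
        spikes = 0.1 + 0.3 + np.arange(8) * 0.05
        assert classify_firing_pattern(spikes, 0.1, 1.0) == "DF"

    def test_tonic_firing_spans_step(self):
        spikes = 0.1 + np.arange(0.01, 1.0, 0.05)
        assert classify_firing_pattern(spikes, 0.1, 1.0) == "TF"

    def test_initial_bursting_confined_to_start(self):
        spikes = 0.1 + np.array([0.01, 0.04, 0.07, 0.095])
        assert classify_firing_pattern(spikes, 0.1, 1.0) == "IB"

    def test_no_spikes_non_firing(self):
        assert classify_firing_pattern([], 0.1, 1.0) == "NF"
        # spikes outside the step do not count
        assert classify_firing_pattern([0.05, 1.5], 0.1, 1.0) == "NF"
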