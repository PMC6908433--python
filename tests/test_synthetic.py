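"""Generator correctness: kernel shape, photocurrent model, event trains,
pharmacology rules, seed determinism."""

import numpy as np
import pytest

from cracm.core import StimProtocol, Trace
from cracm.synthetic import (ConnectivityParams, PharmacologyCondition,
                             PhotocurrentParams, RecordingConfig,
                             SynapticEventParams, apply_pharmacology,
                             biexp_descriptors, biexp_peak_time,
                             design_biexp_params, generate_behavior_log,
                             generate_event_train, generate_evoked_latencies,
                             generate_photocurrent,
                             generate_potentiation_session,
                             generate_psc_waveform, get_preset,
                             synthesize_recording)


class TestPscWaveform:
    def test_unit_peak_and_zero_start(self, kernel_params):
        w = generate_psc_waveform(kernel_params, dt=0.01)
        assert w[0] == 0.0
        assert np.isclose(np.max(w), 1.0)
        assert np.all(w >= 0)

    def test_peak_time_matches_closed_form(self):
        # t_peak = (τr·τd/(τd-τr))·ln(τd/τr); for τr=1, τd=5 this is
        # 1.25·ln5 = 2.0118 ms
        p = SynapticEventParams(1.0, 5.0, 1.0)
        w = generate_psc_waveform(p, dt=0.001)
        assert np.isclose(np.argmax(w) * 0.001, 2.011797, atol=0.002)
        assert np.isclose(biexp_peak_time(1.0, 5.0), 2.011797, atol=1e-5)

    def test_rise_time_against_dense_grid_oracle(self):
        # brute-force threshold crossing on a 1 µs grid
        p = SynapticEventParams(1.0, 5.0, 1.0)
        w = generate_psc_waveform(p, dt=0.001)
        i10 = np.argmax(w >= 0.1)
        i90 = np.argmax(w >= 0.9)
        oracle_rise = (i90 - i10) * 0.001
        analytic = biexp_descriptors(1.0, 5.0)["rise_time_10_90"]
        assert np.isclose(analytic, oracle_rise, atol=0.003)

    def test_zero_amplitude_scaling(self, kernel_params):
        w = generate_psc_waveform(kernel_params, dt=0.05)
        assert np.all(0.0 * w == 0.0)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            SynapticEventParams(5.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            SynapticEventParams(2.0, 2.0, 10.0)

    def test_duration_must_cover_decay(self, kernel_params):
        with pytest.raises(ValueError):
            generate_psc_waveform(kernel_params, dt=0.05, duration=3.0)

    @pytest.mark.parametrize("target,which", [(2.68, "rise_time_10_90"),
                                              (4.90, "half_width")])
    def test_design_biexp_hits_target(self, target, which):
        kw = {"rise_time": target} if which == "rise_time_10_90" else \
             {"half_width": target}
        p = design_biexp_params(**kw)
        assert np.isclose(biexp_descriptors(p.tau_rise, p.tau_decay)[which],
                          target, rtol=1e-9)


class TestPhotocurrent:
    def test_zero_intensity_gives_zero_trace(self):
        proto = StimProtocol.single_pulse(intensity=0.0)
        params = get_preset("photocurrent_excitatory")
        tr = generate_photocurrent(proto, params)
        assert np.allclose(tr.data, 0.0)

    def test_plateau_matches_hill_formula(self):
        params = PhotocurrentParams(max_amplitude=400.0,
                                    half_saturation_intensity=2.0,
                                    hill_exponent=1.5, tau_on=2.0)
        for intensity in (0.039, 1.0, 16.0):
            expected = 400.0 * intensity**1.5 / (intensity**1.5 + 2.0**1.5)
            assert np.isclose(params.plateau(intensity), expected)
            # long pulse reaches the plateau
            proto = StimProtocol(np.array([0.01]), pulse_width=0.1,
                                 intensity=intensity)
            tr = generate_photocurrent(proto, params, dt=1e-4)
            i_end = int(0.11 / 1e-4) - 1
            assert np.isclose(abs(tr.data[i_end]), expected, rtol=1e-3)

    def test_plateau_monotone_in_intensity_and_bounded(self):
        params = get_preset("photocurrent_inhibitory")
        grid = np.geomspace(0.039, 16.0, 25)
        plateaus = [params.plateau(i) for i in grid]
        assert np.all(np.diff(plateaus) >= 0)
        assert plateaus[-1] > plateaus[0]
        assert max(plateaus) <= params.max_amplitude

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            StimProtocol.single_pulse(intensity=-1.0)
        with pytest.raises(ValueError):
            get_preset("photocurrent_excitatory").plateau(-2.0)


class TestEventTrain:
    def test_zero_rate_empty(self):
        assert generate_event_train(0.0, 100.0, 0).size == 0

    def test_support_and_sorting(self, rng):
        t = generate_event_train(10.0, 50.0, rng)
        assert np.all((t >= 0) & (t < 50.0))
        assert np.all(np.diff(t) >= 0)

    def test_rate_estimator_unbiased(self):
        # mean count over >=500 seeds within 3 standard errors of rate*T
        rate, duration, n_seeds = 10.0, 100.0, 500
        counts = [generate_event_train(rate, duration, s).size
                  for s in range(n_seeds)]
        expected = rate * duration
        tol = 3.0 * np.sqrt(expected / n_seeds)
        assert abs(np.mean(counts) - expected) < tol

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_event_train(-1.0, 10.0, 0)


class TestEvokedLatencies:
    def test_unconnected_cell_silent(self):
        conn = ConnectivityParams(connection_probability=0.0)
        proto = StimProtocol.train(0.1, 10.0, 1.0)
        assert generate_evoked_latencies(conn, proto, 0) == []

    def test_plexus_direct_fraction(self):
        # the plexus mixture is 75% direct / 25% delayed
        conn = get_preset("latency_mix_plexus")
        proto = StimProtocol.train(0.0, 10.0, 100.0, pulse_width=1e-3)
        rng = np.random.default_rng(7)
        origins = []
        for _ in range(10):
            origins += [o for _, o in generate_evoked_latencies(conn, proto, rng)]
        frac = np.mean([o == "direct" for o in origins])
        assert len(origins) > 5000
        assert abs(frac - 0.75) < 3 * np.sqrt(0.75 * 0.25 / len(origins))

    def test_latency_mean_recovered(self):
        conn = ConnectivityParams(direct_fraction=1.0, release_probability=1.0,
                                  direct_latency_mean=6.0, direct_latency_sd=1.0)
        proto = StimProtocol.train(0.0, 10.0, 200.0, pulse_width=1e-3)
        ev = generate_evoked_latencies(conn, proto, 11)
        lats = np.array([t for t, _ in ev]) - proto.pulse_onsets
        lats_ms = lats * 1e3
        assert abs(lats_ms.mean() - 6.0) < 3.0 / np.sqrt(lats_ms.size)


class TestSynthesizeRecording:
    def test_flat_baseline_when_empty(self):
        cfg = RecordingConfig(duration=0.2, noise_rms=0.0)
        b = synthesize_recording(cfg, 0)
        assert np.allclose(b.trace.data, 0.0)
        assert b.ground_truth_events == []

    def test_zero_noise_superposition_oracle(self, kernel_params):
        # trace equals an independently computed sum of shifted kernels
        cfg = RecordingConfig(duration=2.0, spontaneous_rate=8.0,
                              spontaneous_params=kernel_params, noise_rms=0.0)
        b = synthesize_recording(cfg, 42)
        kern = generate_psc_waveform(kernel_params, cfg.dt * 1e3)
        expected = np.zeros(b.trace.n_samples)
        for e in b.ground_truth_events:
            i0 = int(round(e.time / cfg.dt))
            i1 = min(i0 + kern.size, expected.size)
            expected[i0:i1] += e.amplitude * kern[: i1 - i0]
        peak = np.abs(expected).max()
        assert np.abs(b.trace.data - expected).max() <= 1e-9 * peak

    def test_ground_truth_bookkeeping(self, kernel_params):
        cfg = RecordingConfig(duration=1.0, spontaneous_rate=5.0,
                              spontaneous_params=kernel_params)
        b = synthesize_recording(cfg, 3)
        n_expected = generate_event_train(
            5.0, 1.0, __import__("cracm").synthetic.split_seed(3)["spontaneous"]).size
        assert len(b.ground_truth_events) == n_expected
        assert np.all(b.event_times < 1.0)
        assert b.trace.n_samples == b.ground_truth_photocurrent.n_samples

    def test_seed_determinism(self, kernel_params):
        cfg = RecordingConfig(duration=0.5, spontaneous_rate=10.0,
                              spontaneous_params=kernel_params)
        a = synthesize_recording(cfg, 99)
        b = synthesize_recording(cfg, 99)
        assert np.array_equal(a.trace.data, b.trace.data)
        assert [(e.time, e.amplitude) for e in a.ground_truth_events] == \
               [(e.time, e.amplitude) for e in b.ground_truth_events]
        c = synthesize_recording(cfg, 100)
        assert not np.array_equal(a.trace.data, c.trace.data)

    def test_config_json_roundtrip(self, kernel_params, tmp_path):
        cfg = RecordingConfig(duration=0.3,
                              protocol=StimProtocol.single_pulse(),
                              photocurrent=get_preset("photocurrent_excitatory"),
                              spontaneous_rate=2.0,
                              spontaneous_params=kernel_params)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        back = RecordingConfig.from_json(path)
        assert back.spontaneous_params.tau_decay == kernel_params.tau_decay
        assert np.allclose(back.protocol.pulse_onsets, cfg.protocol.pulse_onsets)


class TestPharmacology:
    def _base(self):
        glu = SynapticEventParams(0.5, 4.0, 20.0, transmitter="glutamate")
        gaba = SynapticEventParams(1.0, 20.0, 30.0, transmitter="GABA",
                                   polarity="outward")
        return RecordingConfig(duration=0.5,
                               protocol=StimProtocol.single_pulse(),
                               photocurrent=get_preset("photocurrent_excitatory"),
                               spontaneous_rate=5.0, spontaneous_params=glu,
                               evoked=ConnectivityParams(),
                               evoked_params=gaba)

    def test_control_is_identity(self):
        cfg = self._base()
        out = apply_pharmacology(cfg, PharmacologyCondition("control"))
        assert out.spontaneous_params.amplitude_mean == 20.0
        assert out.evoked_params.amplitude_mean == 30.0

    def test_cnqx_silences_glutamate_only(self):
        out = apply_pharmacology(self._base(), PharmacologyCondition("CNQX"))
        assert out.spontaneous_params.amplitude_mean == 0.0
        assert out.spontaneous_rate == 0.0
        assert out.evoked_params.amplitude_mean == 30.0

    def test_bicuculline_scales_gaba(self):
        cond = PharmacologyCondition("CNQX+bicuculline", gaba_block_fraction=0.9)
        out = apply_pharmacology(self._base(), cond)
        assert np.isclose(out.evoked_params.amplitude_mean, 3.0)

    def test_full_cocktail_leaves_photocurrent_only(self):
        cond = PharmacologyCondition("CNQX+bicuculline+strychnine")
        out = apply_pharmacology(self._base(), cond)
        assert out.evoked_params.amplitude_mean == 0.0
        assert out.photocurrent.max_amplitude == 233.66
        b = synthesize_recording(out, 5)
        residual = b.trace.data - b.ground_truth_photocurrent.data
        assert residual.std() < 2 * out.noise_rms  # noise only

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            PharmacologyCondition("TTX")


class TestPotentiationSession:
    def test_factor_one_pre_post_rates_match(self):
        pre_rates, post_rates = [], []
        for s in range(30):
            b = generate_potentiation_session(potentiation_factor=1.0, seed=s)
            t = b.event_times
            spont = np.array([e.time for e in b.ground_truth_events
                              if e.origin == "spontaneous"])
            pre_rates.append(np.sum(spont < 30.0) / 30.0)
            post_rates.append(np.sum(spont >= 40.0) / 60.0)
        assert abs(np.mean(pre_rates) - np.mean(post_rates)) < 1.0

    def test_decayed_rate_matches_formula(self):
        # at t = 60 s after stimulation the excess is (factor-1)·e^{-60/20}
        factor, decay = 5.0, 20.0
        target = 20.0 * (1 + (factor - 1) * np.exp(-50.0 / decay))
        counts = []
        for s in range(200):
            b = generate_potentiation_session(potentiation_factor=factor,
                                              decay_time=decay, seed=s)
            t = b.event_times
            counts.append(np.sum((t >= 88.0) & (t < 92.0)) / 4.0)
        mean_rate = np.mean(counts)
        # window-averaged expectation over [48, 52) s post-stim
        tt = np.linspace(48, 52, 400)
        expected = np.mean(20.0 * (1 + (factor - 1) * np.exp(-tt / decay)))
        se = np.sqrt(expected / (4.0 * 200))
        assert abs(mean_rate - expected) < 4 * se

    def test_pulse_count(self):
        b = generate_potentiation_session(seed=0)
        assert b.protocol.n_pulses == 100


class TestBehaviorGeneration:
    def test_zero_response_probability_empty(self):
        from cracm.synthetic import BehaviorGenParams
        p = BehaviorGenParams(response_probability=0.0)
        log = generate_behavior_log(p, seed=1)
        assert log.bouts == []

    def test_median_onset_ordering(self):
        lats = {r: [] for r in ("paw", "limb", "back", "tail")}
        from cracm.behavior import region_onset_latencies
        for s in range(201):
            log = generate_behavior_log(seed=s)
            for r, v in region_onset_latencies(log).items():
                if v is not None:
                    lats[r].append(v)
        med = {r: np.median(v) for r, v in lats.items()}
        assert med["paw"] < med["limb"] < med["back"] < med["tail"]

    def test_mean_total_duration(self):
        from cracm.behavior import response_metrics
        totals = [response_metrics(generate_behavior_log(seed=s))[1]
                  for s in range(500)]
        assert abs(np.mean(totals) - 45.0) / 45.0 < 0.10

    def test_determinism(self):
        a = generate_behavior_log(seed=7)
        b = generate_behavior_log(seed=7)
        assert [(x.onset_s, x.duration_s, x.region) for x in a.bouts] == \
               [(x.onset_s, x.duration_s, x.region) for x in b.bouts]
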