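# cracm

Analysis toolkit for **channelrhodopsin-assisted circuit mapping (CRACM)**
in spinal dorsal-horn microcircuits — and for any preparation where
opsin-expressing neurons are photostimulated while postsynaptic currents
are recorded under voltage clamp.

Mapping experiments of this kind face a chain of analysis problems that
this package implements end to end:

1. **Synthetic data with ground truth** (`cracm.synthetic`): voltage-clamp
   sweeps containing an opsin photocurrent (Hill intensity–amplitude curve
   `A(I) = A_max·I^h/(I^h+K^h)` with mono-exponential on/off kinetics),
   biexponential synaptic currents `w(t) ∝ e^{−t/τ_d} − e^{−t/τ_r}`,
   Poisson spontaneous event trains, pharmacology conditions
   (CNQX / bicuculline / strychnine), extended-photostimulation sessions
   with decaying rate potentiation, and timestamped nocifensive-behaviour
   logs. Everything is seeded and every injected event is recorded.
2. **Event detection** (`cracm.detection`): the classical sliding-template
   matched filter — at each offset the template is least-squares fitted in
   scale and offset and the detection criterion is `scale/SE` — plus
   multi-component onset resolution and robust baseline estimation.
3. **PSC measurement** (`cracm.psc`): trial averaging, scaled photocurrent
   subtraction, and kinetics (onset latency, peak amplitude, 10–90% rise,
   half-width, exponential decay constant over the 90–10% decay phase,
   charge), and 100 ms epoch frequencies.
4. **Circuit classification** (`cracm.classify`): monosynaptic latency
   windows (recruitment delay + 2.5 ms conduction/synaptic delay ± 2
   dispersions), direct/delayed assignment, GABA/glycine dominance from
   bicuculline block (≥ 80% / < 20% rules), the 4-SD spontaneous-rate
   potentiation criterion, spike fidelity, and the TF/IB/DF/SS discharge
   taxonomy.
5. **Behaviour scoring** (`cracm.behavior`): 5 s peristimulus histograms,
   response latency/duration, per-region onset latencies, SUDO von Frey
   withdrawal thresholds, place-preference dwell times.
6. **Reporting** (`cracm.reporting`): incidence percentages and
   n/mean/SD/SEM group tables.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

Simulate one cell's mapping experiment — ten control sweeps (photocurrent
+ evoked EPSC + 3 pA noise at 20 kHz) and ten sweeps under glutamatergic
block — then subtract the isolated photocurrent and measure the response
(this is `examples/02_photocurrent_and_kinetics.py`):

```python
from cracm import average_trials, measure_psc_kinetics, subtract_photocurrent
from cracm.synthetic import get_preset
from cracm.workflows import simulate_oepsc_cell

preset = get_preset("CR-ChR2 oEPSC")
cell = simulate_oepsc_cell(latency_ms=8.61, kernel=preset["kernel"], seed=3)

avg_control = average_trials([b.trace for b in cell["control"]])
avg_blocked = average_trials([b.trace for b in cell["cnqx"]])
synaptic = subtract_photocurrent(avg_control, avg_blocked)
m = measure_psc_kinetics(synaptic, stim_onset=cell["stim_onset"])
```

Output:

```
true latency    : 8.61 ms
measured latency: 8.37 ms
peak amplitude  : 80.0 pA
10-90% rise     : 3.20 ms
half-width      : 14.31 ms
decay tau       : 12.79 ms
charge          : 1337.694 pA·ms  (1.33769 pA·s)
```

The measured latency recovers the generative 8.61 ms to within the onset
threshold bias and trial jitter; the amplitude and rise reflect the
87.59 pA kernel broadened by 0.3 ms latency jitter across the ten averaged
trials; the decay constant matches the kernel's τ_d ≈ 12.1 ms.

The other example scripts cover detection against ground truth
(`examples/01`), window/inhibition/rate-change classification
(`examples/03`) and behaviour scoring (`examples/04`); each prints a short
interpretation of its numbers.

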