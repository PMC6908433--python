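# Methods

`cracm` implements the analysis chain used in channelrhodopsin-assisted
circuit mapping (CRACM) of spinal dorsal-horn interneuron networks:
synthetic voltage-clamp data with ground truth, matched-filter synaptic
event detection, photocurrent subtraction, postsynaptic-current (PSC)
kinetics, latency-window connectivity classification, pharmacological
decomposition of inhibition, spontaneous-rate potentiation detection, and
peristimulus behaviour scoring. This note records the models, the defaults
that matter, and the choices made where the methodology was genuinely open.

## Generative model (`cracm.synthetic`)

**Synaptic kernel.** Events are difference-of-exponentials currents
`w(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise)`, normalised to unit peak, zero
before onset. The closed-form peak time is
`t_p = (τ_r τ_d/(τ_d − τ_r))·ln(τ_d/τ_r)`; the 10–90% rise time and
half-width are obtained from the closed form by bracketed root-finding
(`biexp_descriptors`). At a fixed shape ratio τ_d/τ_r both descriptors
scale linearly with τ_r, which is how `design_biexp_params` solves for
time constants matching one target descriptor. Note an intrinsic
constraint of this family: the half-width/rise ratio is bounded below at
≈ 4.3 (the alpha-function limit τ_r → τ_d), so a single biexponential
cannot exhibit, e.g., rise 2.68 ms together with half-width 4.90 ms;
waveforms tuned to match measured descriptors are therefore tuned to one
descriptor at a time. The default shape ratio is 5.

**Photocurrent.** The opsin current follows a Hill intensity–amplitude
curve `A(I) = A_max·I^h/(I^h + K^h)` with mono-exponential relaxation
toward the plateau during light (τ_on, default 5 ms) and mono-exponential
decay after light-off (τ_off, default 10 ms), computed segment-by-segment
so pulse trains accumulate correctly. Desensitisation transients are
omitted: the quantity the analysis consumes is the baseline-to-steady-state
amplitude, and this is the simplest model that reproduces it. Half
saturation K defaults to 1 mW with h = 1, which places the 0.039–16 mW
stimulation range across the curve's rising and saturating regions.

**Stochastic structure.** Spontaneous events form a homogeneous Poisson
train; optically evoked events occur per pulse with a release probability
and draw latencies from a two-component (direct/delayed) Gaussian mixture,
re-sampled when non-positive (truncation). Recording noise is white
Gaussian, default 3 pA RMS at 20 kHz sampling. Real recordings are
low-pass filtered (5–10 kHz) and carry 1/f and line components; white noise
is an assumption, so detector operating points measured here (false-positive
rates, recall) characterise the algorithm, not any particular rig.

**Seeding.** One integer seed expands through
`np.random.SeedSequence(seed).spawn()` into named streams
(photocurrent, spontaneous, evoked, noise, misc) in fixed order; event
lists for a given (config, seed) pair are bit-reproducible.

**Presets.** Named presets carry the published group statistics of the
system this emulates as generative targets: photocurrent plateaus for the
excitatory (233.66 pA) and inhibitory (459.72 pA) opsin-expressing
lineages; recruitment delays 3.29 ms (excitatory; the source reports both
±0.21 and ±0.38 SEM, and both are carried, with the n = 29/±0.21 version
the default) and 2.39 ms (inhibitory); oEPSC group descriptors (e.g.
latency 8.61 ± 1.23 ms SEM, n = 12, amplitude 87.59 pA, rise 2.68 ms —
the source prints both 2.67 and 2.68 for this quantity and the presets use
2.68); direct/delayed mixtures of 35/65 (interconnected opsin population),
75/25 (plexus) and 57/43 (dorsal); and a bicuculline-block mixture giving
72% GABA-dominant / 28% mixed / 0% glycine-dominant inhibition. Printed
dispersions are SEMs, so between-cell SDs are reconstructed as SEM·√n.
Block-fraction components are Uniform(0.85, 0.98) for GABA-dominant and
Uniform(0.30, 0.70) for mixed cells — clear of the 0.80/0.20 decision
boundaries so that measurement noise (2 pA on ~150 pA amplitudes) rarely
flips a class; the composition itself, not the margins, is the published
quantity.

**Potentiation sessions.** An extended-photostimulation session is 30 s of
baseline, a 10 s/10 Hz/10 ms pulse train (100 pulses), and 60 s post
window whose spontaneous rate is `r0·(1 + (f − 1)·exp(−t/τ))` with decay
τ = 20 s, sampled by thinning. The baseline rate default is 20 Hz,
representing the dense spontaneous excitatory drive of the interconnected
excitatory population this models; at markedly lower baseline rates the
4-SD criterion (below) becomes very conservative because the epoch-count
noise grows relative to the mean. These sessions carry ground-truth event
times; a trace is not materialised unless requested, since the rate
analysis operates on event times.

**Behaviour logs.** One nocifensive bout per responding body region, onset
= stimulation onset + truncated-Gaussian latency (defaults from the
published region means: paw 1.25 s, limb 26.4 s, back 40.8 s, tail 59.3 s,
SDs reconstructed as SEM·√12), durations Gamma-distributed with per-region
means weighted by `exp(−latency/decay)` and summing to 45 s. The generator
does not model repeated bouts per region, grooming unrelated to
stimulation, or observer coding error.

## Event detection (`cracm.detection`)

The detector is the classical scaled-template matched filter: at every
offset the template `p` is fitted to the data segment `d` by least squares
in scale and offset, and the detection criterion is
`scale / sqrt(SSE/(N−2))`. Rolling sums (cumulative sums plus one FFT
correlation) give the whole profile in O(n log n); tests verify equality
with a brute-force per-offset least-squares oracle to 1e−9. The SSE is
floored at `(1e−9·max(1, max|d|))²·N` so that exactly flat segments give a
criterion near zero instead of 0/0, while a perfect noiseless match still
scores enormously; on any trace with real noise the floor is ~17 orders of
magnitude below the SSE.

Numerical/operating choices:

- **Threshold** default 3.5 (criterion units), a standard operating point
  for this detector family; exposed per call.
- **Peak picking.** The criterion profile around one event is a broad hump
  with low-prominence noise wiggles on its flanks. Detections are local
  maxima above threshold with prominence ≥ threshold/2 and separation ≥
  the template rise time; this keeps one detection per event while a
  genuine overlapping second event (whose peak rises from the saddle
  between the two) survives.
- **Template length** defaults to 5 τ_decay: longer fit windows span
  neighbouring events and degrade the fit around close pairs.
- **Onset** is the template-alignment position; amplitude is the fitted
  scale (signed by polarity), i.e. measured against the locally fitted
  baseline.
- At the default operating point (3 pA RMS noise, events ≥ 5× RMS) the
  measured recall is ≥ 0.95 with false discovery ≤ 0.05, and the residual
  misses are close pairs within a few ms of each other. The original
  procedure this models is semi-automated (an operator curates candidate
  events); this implementation is fully automatic, which is the main
  behavioural difference.

`detect_components` resolves multi-component evoked responses on averaged,
subtracted traces: local peaks of the polarity-corrected response with
amplitude floor 3 × baseline SD and minimum separation 3 ms; each
component's onset is a 5% threshold crossing above the preceding trough.
`estimate_baseline` reports median and 1.4826·MAD.

## PSC analysis (`cracm.psc`)

Trials are averaged pointwise (10 is the conventional count, not a
requirement). Photocurrent subtraction scales the pharmacologically
isolated photocurrent so its peak matches the pre-drug response at the
same sample, then subtracts; supplying an explicit scale overrides the
peak-ratio estimate.

Kinetics on the averaged, subtracted trace (`measure_psc_kinetics`):

- **Response present?** judged on a 0.5 ms boxcar-smoothed copy of the
  polarity-corrected trace against 3 × baseline SD — a raw-sample maximum
  always exceeds 3 SD on pure noise, so the decision must be made on a
  smoothed statistic. Kinetics are then measured on the raw trace around
  the smoothed peak. No response → all-null record.
- **Onset** = first crossing of 5% of peak, searched backwards from the
  peak (the onset of a measured PSC is not defined more precisely in
  common practice; the fraction is configurable). Latency = onset −
  stimulus onset. This definition carries a small positive bias (the 5%
  crossing trails the true kernel onset by ~0.1 ms for the default
  shapes).
- **Rise** = 10%→90% crossings of the rising limb, linearly interpolated;
  **half-width** = interpolated span above 50%.
- **Decay constant**: "10–90% of the decay phase" is read as a single
  exponential fitted (log-linear start, nonlinear refinement) to the
  segment where the response falls from 90% to 10% of peak. For τ_d ≫ τ_r
  this recovers the generative τ_d within 2%.
- **Charge** = trapezoidal integral from onset to return-to-baseline
  (first crossing of the onset threshold after the peak), reported in
  pA·s. The 5% thresholds exclude the extreme tails, so the measured
  charge sits a few percent below the full analytic kernel integral; group
  tables in the source literature are inconsistent between pA·ms and pA·s,
  and this package uses pA·s everywhere.
- Baseline window: 50 ms immediately before the stimulus.

`epoch_frequency` counts events in fixed 100 ms epochs and multiplies by
10 to give Hz; a partial trailing epoch is dropped.

## Decision rules (`cracm.classify`)

- **Recruitment delay**: per-pulse first-spike delay within a 10 ms
  response window; per-cell mean; group mean/SD/SEM over cells.
- **Monosynaptic window**: centre = recruitment mean + 2.5 ms (conduction
  + synaptic delay from paired-recording literature), half-width = 2 ×
  dispersion. The dispersion is the SD of the per-cell delay sample by
  default, with an SEM option: the methodology this follows says
  "standard deviations" while reporting ± values consistent with SEM, and
  both readings are supported.
- **Latency classification**: direct iff latency ≤ window upper bound.
  Latencies below the lower bound are classified direct — a synaptic
  response cannot be faster than monosynaptic, so the lower tail is
  attributed to jitter rather than to a different circuit.
- **Inhibition**: block = 1 − bic/ctrl; block ≥ 0.80 → GABA-dominant,
  block < 0.20 → glycine-dominant, else mixed. Boundary semantics follow
  the printed wording exactly ("80% or greater", "less than 20%"), with a
  1e−12 epsilon so exact boundaries are stable under round-off. Small
  apparent potentiation in bicuculline (≤ 5% relative) is treated as zero
  block.
- **Rate change (4-SD rule)**: flag when the mean test-window epoch
  frequency exceeds the pre-window mean by more than k·SD (k = 4) of the
  *pre-window epoch frequencies* — the SD is over 100 ms epochs, which is
  the natural reading when frequency itself is defined per epoch. Default
  windows: pre 0–30 s, test = first 5 s post-stimulation. Measured under
  the default session preset: null false-positive rate < 5% (it is
  essentially zero — the rule is very conservative) and power > 0.95 at
  potentiation factor 5.
- **Firing patterns**: precedence SS (exactly one spike) → DF (first-spike
  latency > 100 ms) → TF (spikes spanning ≥ 80% of the step) → IB
  (residual: repetitive firing that stops before spanning the step; the
  canonical case is spikes confined to the first ~20%). The source
  taxonomy is qualitative; the 100 ms / 80% / 20% thresholds are decided
  here and exposed as arguments.

## Behaviour scoring (`cracm.behavior`)

Peristimulus histograms report, per 5 s bin, the proportion of bin time
covered by the *union* of bout intervals (bouts at different body regions
overlap in time; a bin cannot be more than 100% in-behaviour). This makes
conservation exact — Σ(proportion × width) equals total in-behaviour time —
and splitting any bout into contiguous parts changes nothing. Response
latency/duration and per-region onset latencies consider bouts starting at
or after the stimulation onset. Logs are assumed to be in real-time
seconds (coding from slowed video playback must be rescaled upstream).

SUDO von Frey: five stimuli, down on withdrawal / up on no-withdrawal,
clamped to the filament set; score = fifth-stimulus position ∓ 0.5 by the
fifth response; scores averaged over sessions and converted to grams by
interpolation on the log-force scale of the standard 0.008–2 g set
(linear extrapolation in log force beyond the ends). Place-preference
dwell times partition the tracked span exactly.

## Reporting (`cracm.reporting`)

Incidence percentages use half-up rounding (printed style); group tables
give n/mean/SD/SEM with SD at n−1 degrees of freedom. Inferential
statistics are deliberately not re-implemented.

## Problem sizes

The shipped test-suite and reproduction-script sizes are the study's own:
12 cells × 10 trials for the oEPSC latency chain, 29 cells for recruitment,
100 pharmacology series, and 1000/200 Monte-Carlo sessions for the 4-SD
rule's null/power calibration. Detector operating-point checks use ~10
seeds × 5–10 s of 20 kHz data. With between-cell SDs reconstructed as
SEM·√n, recovered group means scatter around the generative values with
exactly the published SEM, so agreement is assessed in units of that SEM.

## Known limitations

- White-noise recordings and stylised photocurrent kinetics (no
  desensitisation, no access-resistance artefacts).
- The detector is fully automatic where the emulated procedure allowed
  manual curation; overlapping events closer than ~the kernel rise time
  are reported as one.
- `measure_psc_kinetics` assumes a single dominant response; convergent
  multi-component responses should be sent to `detect_components` first.
- The behaviour generator emits at most one bout per region and does not
  model spontaneous grooming; classifier-free scoring only.
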