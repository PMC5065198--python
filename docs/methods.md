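# Model and methods

## The network

`gammamux` simulates a two-area spiking network that decomposes a synthetic
visual scene and transmits it downstream under two cross-frequency
multiplexing regimes:

* **F-multiplexing** (communication-through-coherence with a slow reset):
  within each slow-oscillation cycle a single item — the most salient — is
  selected and transmitted repeatedly at gamma frequency;
* **LJ-multiplexing** (theta/alpha–gamma coding): items are transmitted
  sequentially, one per gamma cycle, ordered by salience, and the sequence
  repeats every slow cycle.

Which regime the network adopts is controlled by the amplitude of *global*
(all-to-one/one-to-all) feedback inhibition in the lower versus the higher
area; this is the package's central, swept parameter pair.

### Cells

All cells are conductance-based leaky integrate-and-fire units,

    C dV/dt = g_leak (E_leak − V) + g_exc (E_exc − V) + g_inh (E_inh − V),

with a spike registered and V reset when V crosses threshold after the Euler
update.  Excitatory cells: C = 280 pF, g_leak = 17.5 nS (τ_m = 16 ms),
E_leak = −66 mV, V_th = −55 mV, V_reset = −60 mV.  Inhibitory (including
global) cells: C = 50 pF, g_leak = 12.5 nS (τ_m = 4 ms), E_leak = −70 mV,
V_th = −40 mV, V_reset = −70 mV.  E_exc = 0 mV, E_inh = −75 mV everywhere.
Local and global interneurons receive a 7 nS tonic depolarising conductance;
higher-area excitatory cells 1.75 nS.  Synapses are step-increase
conductances decaying exponentially (analytically, one multiplicative factor
per step): lower area E-E 1.2 nS / 2 ms, E-I 0.68 / 2, I-E 0.62 / 3,
E-G 0.1 / 2, G-E 0–30 / 4 (swept), feedforward 0.11 / 1 (see *Calibrations*),
higher area E-G 6 / 2, G-E 0–30 / 3.

### Stimulus frontend

The lower area is a retinotopic bank of simple cells: 4 orientations ×
4 spatial phases × n spatial scales, with the grid side halving and the
receptive field doubling per scale (128×128 … 16×16 at full geometry;
348,160 orientation-selective units).  Receptive fields are zero-mean Gabor
kernels, base side 9 px, envelope σ = side/4, wavelength = side/2,
normalised to unit L1 norm so that contrast sensitivity is equal at every
scale.  The drive of a unit is the rectified correlation of its kernel with
the luminance image (linear in the deviation from the mid-gray background),
scaled once per bank so that the optimal unit for a full-contrast reference
object receives exactly 7.5 nS at gain 1, then multiplied by a per-quadrant
gain.  Colour-selective units (conjunction variant) respond to the Gaussian-
blurred positive deviation of their colour plane, normalised the same way.

Stimuli: rectangles (39×9 px at grid 128, interior 0.5 + 0.5c, single-pixel
outline 0.5 − 0.5c on a 0.5 background), per-pixel uniform [0, 1] white
noise, and striped colour patches for the conjunction network.

### Wiring

Lateral excitation couples same-scale excitatory units as the product of
three Gaussians: alignment of the connecting line with the presynaptic and
postsynaptic orientation preference (σ = 2°, with the presynaptic tolerance
sharpening with distance) and distance decay (σ_d = 4 px, cutoff 12 px).
At zero distance (different layers, same position) the orientation factors
are taken as 1; self-connections are excluded.  The sharp 2° tolerance is
dynamically necessary: broadening it to the orientation-spacing scale (45°)
produces runaway recurrent excitation at the 1.2 nS amplitude.

A 128×128 interneuron sheet provides local inhibition; coupling to and from
every excitatory layer (orientation and colour alike) is a spatial Gaussian
with σ = 4 cells (peak = the table amplitude, cutoff 3σ), with coarse scales
registered to the sheet by centre-aligned upsampling.  There are no I→I
connections.  One global interneuron per area receives from and projects to
all excitatory cells of that area.

The quadrant variant's higher area is 4 cells, each pooling every lower
unit whose receptive-field centre lies in one quadrant (afferent sets
partition the population).  The conjunction variant has 4×3 cells, each
pooling one orientation channel plus one colour channel over the full field.

### Simulation

Forward Euler, 1 ms step (0.1 ms supported); spikes propagate with a
one-step latency.  Lower-area excitatory cells receive per-step Gaussian
conductance noise (SD 1 nS at the reference step; scaled by sqrt(dt) so
noise power per unit time is step-size invariant) and, optionally, the slow
oscillation: per-cell Poisson barrages of small unitary inhibitory events
(0.05 nS, τ = 3 ms) whose rate follows a raised cosine at 9 Hz.  All
randomness derives from a master seed via per-repeat, per-stream
SeedSequences; records are bit-reproducible.

## Calibrations

Three quantities are fixed by documented calibration procedures rather than
by a table value, in this order; each is calibrated once and frozen.

1. **Slow-oscillation amplitude.**  `calibrate_slow_amplitude` finds (by
   doubling + bisection) the smallest peak event rate that leaves zero
   lower-area spikes within ±10 ms of the oscillation peak under maximal
   stimulus drive.  Protocols run at 1.5× this minimal rate: the margin must
   exceed 1 (complete suppression with noise headroom) and stay below 2
   (the halved-amplitude protocols must leave the most strongly driven
   cells unsuppressed), and it places the per-ensemble release times on the
   steep limb of the cosine, which orders ensemble onsets by drive — the
   transform of salience into phase that both regimes rely on.
2. **Feedforward amplitude.**  With our frontend the per-volley ensemble
   bursts are smaller than the per-connection table value assumes, so the
   feedforward amplitude carries a per-geometry factor (2.0 at full, 3.0 at
   desk, on top of the convergence compensation below) calibrated so that in
   the default state (no global inhibition) the higher-area cells operate at
   the scale the state indices assume — the selected cell near 3 spikes per
   slow cycle, which is the saturation constant of the A index.
3. **Conjunction feedforward.**  `calibrate_feedforward` records the
   afferent spike series a conjunction cell would receive from each input
   channel on the canonical stimulus.  Orientation channels carry ~2-3×
   larger volleys than colour channels, so the colour-synapse amplitude is
   first set to the measured volley-size ratio (each channel then
   contributes equally — the per-cell synaptic tuning the conjunction
   selectivity requires).  The volley statistic is the median over slow
   cycles of the dominant 2 ms volley per channel.  Bisection on a template
   volley then locates the largest amplitude at which a concentrated
   tail-sized (1.4× median) single-channel volley stays subthreshold and
   the smallest at which a typical dual-channel volley fires; their
   geometric midpoint is the operating amplitude.

## Scaled-down (desk) geometry

The full geometry is impractical for routine runs, so a calibrated desk
preset (grid 48, 2 scales, objects scaled proportionally) preserves the full
model's dynamics rather than its raw parameters.  Time constants and the
7.5 nS drive ceiling are unchanged.  Because ensembles lie along object
contours, per-volley cell counts shrink roughly linearly with the grid, and
four quantities are compensated:

| quantity | factor | rationale |
|---|---|---|
| local E↔I amplitudes | 1.5 | calibrated so desk gamma peaks match the full model's (59/50 vs 63/51 Hz at contrasts 1.0/0.8) |
| lower E→G amplitude | (128/48) × 1.5 | per-volley conductance at the global cell preserved |
| feedforward amplitude | (128/48) × 1.5 × 3.0 | per-volley conductance at higher cells, plus the operating-scale factor above |
| noise SD | 0.5 | ensemble-level signal-to-noise of burst timing preserved (volleys ~4× smaller → 1/√4) |

What the desk preset preserves: PING gamma in the 40–65 Hz band with
contrast-monotone frequency; the three state-map corner classifications
(poor separation / F / LJ); the slow-oscillation phase ordering.  What it
does not: absolute spike counts, the smoothness of population traces, and
fine phase statistics, all of which are noisier with ~40-spike volleys.

## Analysis

PSTHs are per-cell firing probabilities per 1 ms bin averaged over repeats
(higher area) or mean rates over participating cells (lower area), smoothed
with a 2 ms Gaussian.  Gamma peak frequency: pooled spike histogram of all
activated lower-area cells, 2 ms-smoothed, mean-subtracted, Hann-windowed,
zero-padded to 1 Hz resolution, per-repeat power spectra averaged, argmax in
20–100 Hz.  Phase histograms bin spike phases against the 9 Hz oscillation
(phase 0 = inhibition peak) with circular smoothing.

State indices: S (temporal-segregation failure) is the mean pairwise shared
area (integral of the pointwise minimum) of the 3 ms-smoothed higher-area
traces, normalised to the value of the stored no-global-inhibition reference
state and clipped to [0, 1]; for the conjunction network S is instead the
false-conjunction spike count per slow cycle / 3, clipped at 1.  A =
selected-cell spikes per slow cycle / 3; B = mean other-cell spikes per slow
cycle / 2; colours: Green = S, Blue = (1−S)B, Red = (1−S)(A−B) clipped at 0.
Near-coincidence fraction: share of higher-area spikes followed by a spike
of a *different* cell within (0, 3] ms (cross-cell simultaneity counts);
pooled over repeats.

## Numerical and design choices

* Forward Euler with threshold test after the update; conductances decay
  analytically, so synaptic dynamics carry no integration error.
* One-step spike latency: simultaneous coupling is ill-defined under Euler
  and no axonal delays are specified.
* No refractory period beyond the reset.
* Noise is a transient per-step sample (it does not persist as a synaptic
  event); the total excitatory conductance is floored at zero.
* Zero-distance lateral coupling uses orientation factors of 1 (the
  connecting-line orientation is undefined at d = 0).
* Silent records give S = 0, keeping the colour map black at low rates.
* The coincidence window is (0, 3] with cross-cell simultaneity included —
  simultaneous firing of two cells is the paradigmatic separation failure.
* The "literal" reading of the lateral-weight formula (tolerance widening
  with distance) is available via
  `LateralWeightParams(formula="literal")` for comparison.

## Known limitations

* The emergent gamma frequencies run ~20% above the 51/43 Hz (contrast
  1.0/0.8) that the underlying study reports: 63/51 Hz at the full geometry,
  59/50 Hz at desk.  The contrast dependence and its slope reproduce.  The
  gap traces to ensemble size: with this frontend ~150 cells fire per volley
  at full geometry, which leaves the local interneuron sheet unsaturated and
  the PING loop faster; no choice of the open frontend parameters closed the
  gap without contradicting the fixed synaptic amplitudes.
* F-mode item exclusion is good but not absolute (the non-selected cells
  retain ~10–25% of the selected cell's rate at desk scale).  Two timing
  limits cause the leakage: the global-interneuron veto acts two Euler
  steps after the first higher-area spike, so cells crossing threshold in
  the same or the following 1 ms step escape it, and volley sizes fluctuate
  enough at the scaled geometry that occasional single-channel volleys of
  the conjunction network reach threshold on their own.  The LJ state,
  which separates items by a full gamma cycle in the lower area, suppresses
  false conjunctions essentially completely; the F state only partially.
* Contrast-ordered multi-item cycling (local-inhibition τ = 20 ms) resolves
  at the full geometry; at desk scale the ~2 ms onset offsets between
  ensembles are at the veto-latency floor and the ordering scrambles.
  With the default τ = 3 ms the weakest ensemble is attenuated but not
  fully excluded (our gamma runs faster than the original's, so the slow
  firing window holds more gamma sub-cycles and the third item finds one).
* Without the slow oscillation, a blank pre-stimulus leaves all cells at
  rest, so the three ensembles' first post-onset volleys are nearly
  simultaneous and early near-coincidences are slightly *more* frequent
  than with a randomising noise pre-stimulus (25.7% vs 23.6% of spikes
  followed within 3 ms at 40 repeats) — the opposite ordering of the two
  protocols' selectivity costs from what larger-ensemble networks show.
* The higher area is small and near-threshold by design, so its statistics
  are all-or-nothing per gamma burst; protocols therefore average over many
  repeats.
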