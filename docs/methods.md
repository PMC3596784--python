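# Methods

## Neuron and noise model

Neurons follow the two-variable quadratic spiking model

    dv/dt = 0.04 v² + 5 v + 140 − u + I_syn + g · I_noise
    du/dt = a (b v − u)

with the discontinuous reset `v ≥ v_peak → v ← c, u ← u + d`.  The spike
cut-off defaults to `v_peak = 40 mV` (the value the network model uses); the
canonical 30 mV is available through `SimulationConfig.v_peak`.  Two firing
families are implemented, mixed 75%/25% and parameterised by an independent
uniform draw r ∈ [0, 1] per neuron:

* excitatory / regular-spiking: a = 0.02, b = 0.2, c = −65 + 15r², d = 8 − 6r²
  (r = 0 is classic regular spiking, r = 1 leans to bursting);
* inhibitory / fast-spiking: a = 0.02 + 0.08r, b = 0.25 − 0.05r, c = −65, d = 2.

`I_noise` is a per-neuron Ornstein–Uhlenbeck process with correlation
length τ = 1 ms, stationary mean 25 and SD 9 (units labelled pA), integrated
with the Euler–Maruyama recursion

    I ← I − (I/τ) dt + (m/τ) dt + s √(2dt/τ) ξ.

At dt = 0.1 ms this recursion is an AR(1) whose exact stationary SD is
`s·√(2dt/τ)/√(1−(1−dt/τ)²) ≈ 1.026 s` — about 2.6% above the nominal s, the
expected first-order discretisation bias.  Tests assert the empirical
moments against the recursion's own stationary values and confirm the bias
stays below 3%.

### The noise-coupling constant g

The quadratic model's rheobase is ≈ 4 current units; a mean drive of 25
units injected directly would make every neuron fire tonically at ~50 Hz
and the coupled network at ~140 Hz, a fully asynchronous regime with no
discrete network events at any detection threshold (and synchrony
*decreasing* with size).  Sparse background spiking with episodic
network-wide bursts — the regime these circuits actually exhibit — requires
the mean drive to sit slightly **below** rheobase so that spikes are
noise-driven and collective events are ignition cascades.  The model
therefore couples the OU current into the voltage equation through a
dimensionless gain `g` (`SimulationConfig.noise_gain`), a capacitance-like
conversion between the labelled pA and the equation's current scale.  The
OU process itself keeps its stated 25/9 moments.

`g` is calibrated (see `scripts/calibrate.py`): the shipped default
`g = 0.0795` puts the effective mean drive at 2.0 units (≈ half rheobase,
SD 0.72), producing ~1–3 Hz background firing and burst rates that grow
linearly from ~0.02 Hz at 90 neurons to ~0.11 Hz at 520 neurons, with a
rate-vs-total-cells slope near 1.5×10⁻⁴ Hz/cell.  The transition is sharp:
g ≤ 0.07 silences the networks, g ≥ 0.09 drives them tonic.

## Network model

Directed graphs are grown by preferential attachment using the efficient
repeated-endpoint-list construction (`networkx.barabasi_albert_graph`):
each added node creates `m` edges biased toward high-degree endpoints; the
undirected simple graph is then oriented by flipping a fair coin per edge
(never both directions), giving the adjacency a_ij (row = postsynaptic).
Self-connections never occur.  Weight magnitudes are i.i.d. N(10, 3.5)
(non-positive draws redrawn); outgoing weights of fast-spiking neurons are
negated — the sign convention is a package choice (a Dale-type convention),
as only the magnitude distribution is specified by the model.

`m` is not dictated by the model; the calibrated default is **m = 5**,
chosen so the fitted degree-distribution exponents land on the observed
anchors (see below) while keeping the bursting calibration attainable.

Synaptic transmission is pulse coupling: when j fires at step k, s_ij is
added to v_i before the Euler update of step k+1.  No conduction delays.

### Degree-distribution fit

`fit_power_law` regresses log(count) on log(degree) over the raw histogram
of observed degree values (zero bins drop out; degree 0 excluded) and
reports the signed slope.  The package's degree convention is the
**in-degree** (number of presynaptic inputs, the row sums of a_ij): with
m = 5 the mean exponent runs from ≈ −1.0 at 90 nodes to ≈ −1.6 at 520
nodes, strictly decreasing across the seven study sizes.  Total-degree
histograms of the same graphs are substantially steeper (≈ −1.7 at 520
nodes for every m), which is why the shallower in-degree convention is the
default; `ConnectivityGraph.degrees(mode=...)` exposes all three.

## Simulation engine and numerics

Forward Euler with dt = 0.1 ms for both equations (10-kHz sampling);
the original split-step integrator is not used.  The run loop is a
numba-compiled kernel; a pure-NumPy reference engine executes the identical
operation order and the test suite asserts bit-identical rasters between
the two.  Noise is drawn in chunks from one PCG64 stream per neuron, keyed
by (seed, neuron id), and initial conditions are drawn per neuron the same
way (v ~ U[c, −60] mV, u = b·v, I = m): a network with zero weights
therefore decomposes *exactly* into independent single-neuron simulations,
and rasters are byte-identical across repeated runs.  Integration aborts
with a diagnostic (neuron, time) when |v| exceeds 10³ mV before reset —
a genuine divergence, never silently clipped.  Statistics downstream of the
simulator discard the first 5 s as an initial transient.

## Network-event detection

The population instantaneous firing rate uses 100-ms bins, tracking both
spike counts and the fraction of neurons active per bin.  A network event
is a maximal run of bins with active fraction ≥ 0.2, merging runs whose
gaps are under 200 ms.  There is no single standard definition of a network
burst, so both constants are package choices, exposed as parameters and
validated in the calibration script.  In the calibrated regime the sparse
background (a ~2-Hz neuron is active in ~18% of 100-ms bins, but
between-burst bins rarely have 20% of the *population* active at once)
separates cleanly from bursts, in which the active fraction approaches 1.  Event rates exclude events starting in the 5-s transient.
For comparison with measured circuits, simulated neuron counts map to
total cells as 1.5 × n (2:1 neuron-to-glia ratio); the factor is applied
only on the regression axis, never stored.

## Calcium-event detection

Per trace F (59-Hz default): first differences ΔF are summed over sliding
1-s windows (the sum telescopes to F[j+w] − F[j], making the processed
signal exactly baseline-independent).  The noise SD σ comes from a
zero-centred Gaussian fitted to the histogram of the processed signal —
Freedman–Diaconis bins over the central 95% of values, which keeps sparse
transients from inflating σ (tested: 1% contamination moves σ by < 10%).
Candidate events are runs of ≥ 5 consecutive samples above 3σ; runs of one
neuron closer than one integration window are merged, since a single
transient can dip briefly below threshold.  Onset and offset are the 5%
and 95% crossings of a four-parameter logistic fitted to F over the padded
candidate window.  Taking the 95% crossing of the *rising* sigmoid places
the offset near the transient peak; this literal convention is the
default, and both crossings follow in closed form from the fitted midpoint
and steepness (t₀ ± τ·ln 19).

Detection is invariant to trace offset (exact, by construction) and to
positive rescaling (the processed signal, its histogram binning, and σ all
scale together).

The synthetic generator renders events as peak-normalised double
exponentials (rise 0.05 s, decay 1 s — somatic OGB-1/Fluo-4-like) plus
i.i.d. Gaussian frame noise.  Its "peak SNR" is defined on the detection
statistic: amplitude over the processed-signal noise SD (√2 × frame-noise
SD), the matched-filter sense; at frame-level SNR the same rule would
operate at only ~3.5σ of its own statistic and no threshold choice could
meet the stated recovery rates.  The generator does not model
photobleaching drift (an optional linear-drift mode stresses the shift
invariance), dye saturation, or movement artefacts — passing round-trip
tests demonstrates correctness of the chain, not performance on raw movies.

## Functional connectivity

For each ordered pair (j, k), every onset of j contributes the signed lag
to the nearest onset of k within ±500 ms (one lag per source onset — the
specific lag-collection rule is a package choice).  A pair with ≥ 5 lags is
tested twice: a one-sample t-test against zero mean (excludes synchronous,
Gaussian-centred-at-zero pairs) and a KS test against uniformity on the lag
window (excludes uncorrelated pairs); an edge j→k requires both rejections
at α = 0.05 and a positive mean lag.  Each unordered pair is evaluated
once, so at most one direction survives; time-reversing the data exactly
reverses every edge.  No correction for multiple comparisons is applied by
default (matching the source analysis); `alpha` is a parameter, and a
practitioner running many pairs may pass a Benjamini–Hochberg-adjusted
level.

Cross-correlograms operate on onset series binarised at the frame period.
The printed correlogram formula lacks a normalisation that would make the
autocorrelation equal 1, so the implementation divides by the overlap count
and the two SDs, giving CC ∈ [−1, 1] (the usage — "positive
cross-correlation", cross-neuron comparisons — assumes this).  Sign
convention: CC_ab(τ) pairs a_t with b_{t+τ}, so **positive τ_max means a
leads b**; early-recruited neurons have positive ⟨τ_max⟩.  ⟨CC_max⟩ and
⟨τ_max⟩ average over partners with positive peak correlation; neurons with
no such partner are flagged, not silently zeroed.

## Evoked responses and wavelet detection

PSTHs use 4-ms bins over (−100, +400) ms (125 bins), per channel and
pooled.  Evoked intensity is the spike count in the 200 ms after each
pulse; when pulses are closer than the window, the window truncates at the
next pulse (with a warning).  Pulse-1 vs pulse-2 and before/after contrasts
use the Mann–Whitney U test.

The spike detector computes the undecimated (stationary) Haar wavelet
transform — PyWavelets, periodic extension, symmetric padding to a
multiple of 2^L — and thresholds the absolute level-6 detail at
k × SD(level-1 detail), the SD estimated block-wise over 1-s windows.
Suprathreshold samples within one filter support (2⁶ samples) merge into a
single event timestamped at the detail maximum; a single spike's level-6
response spans ~2.6 ms at 25 kHz, so grouping by the 1-ms refractory alone
would split it into echoes.  k is calibrated on the synthetic benchmark
(asymmetric 1-ms biphasic templates at peak SNR 8 in white noise, 25 kHz):
k = 5.0 gives recall 1.0 at 0 false positives/min; k = 4 floods the output
with noise crossings.  The 16-bit fixed-point mode quantises the input and
every level's coefficients to a signed integer grid (full scale tracking
the √2-per-level coefficient growth), emulating integer hardware; it
reproduces ≥ 99% of floating-point detections at SNR 8.  Thresholding is
scale-invariant, so detections ignore signal gain.  Band-pass helpers
(MUA 800 Hz–3 kHz, LFP 1–300 Hz, zero-phase Butterworth) are provided for
preprocessing; artifact-suppression and peak-tracking detectors from the
wider literature are intentionally out of scope.

## Problem sizes used by the shipped checks

The end-to-end rate-vs-size computation simulates the seven study sizes for
300 s each (3 seeds), half the full 600-s protocol; event rates are time
densities and stable in duration, while seed averaging controls the
dominant variance.  Degree-exponent summaries average 20 graphs per size.
The OU stationarity check integrates 10⁶ steps.  Calcium, connectivity and
wavelet benchmarks use minutes-long synthetic recordings with fixed seeds.

## Known limitations

* The bursting regime depends sharply on the noise coupling g; the shipped
  value is a calibration, not a first-principles constant, and burst rates
  at fixed size vary noticeably across network realisations (seed averaging
  is built into the headline regression).
* The simulator is a software reference: real-time guarantees, conductance
  synapses, plasticity and spatially structured or multi-cluster
  connectivity are out of scope.
* The calcium chain starts from extracted traces; segmentation of imaging
  movies is not addressed.
* Functional-connectivity edges are statistical, not anatomical; transitive
  edges (A→C behind A→B→C) are expected and not pruned.

## Seed summary for the rate–size fit

Burst rates of individual network realisations are heavy-tailed at small
sizes: an occasional 90-neuron graph/weight draw lands in a continuously
bursting regime an order of magnitude above the typical rate.  The
per-size summary across seeds is therefore the **median** of the per-seed
rates (3 seeds by default); with a mean, one such realisation dominates
the whole regression.
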