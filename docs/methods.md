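# Methods

This note documents the models, calibrations and numerical choices behind
`arcophys`, and what the synthetic-data machinery does and does not
establish about real recordings.

## The resurgent Na⁺ current model

The resurgent current is a single conductance gated by two independent
first-order particles, an activating particle *s* and an inactivating
particle *f*:

    I_NaR = g_NaR · s · f · (V − E_NaR),        E_NaR = +67 mV

with, for each particle *x*,

    τ_x = 1 / (α_x + β_x),    x∞ = α_x · τ_x,    dx/dt = (x∞ − x)/τ_x,

integrated by first-order forward Euler with a default step of 0.03 ms
(the dynamic-clamp loop rate).  Gating variables are clamped to [0, 1]
after every step; if `dt/τ` ever exceeds 1 a warning is logged once per
run.  Currents follow the physiology sign convention (inward negative);
`g_NaR` is in µS and currents in nA.

### The synthetic rate-constant set

The shipped parameter file
(`arcophys/params/resurgent_rates_synthetic.yaml`) is a synthetic,
package-calibrated set, not a transcription of any published numeric
table.  Two constants are fixed by the published model description and are
never refit: the exponential-term denominator of the *s* opening rate
(K = −1.0 mV) and the multiplier of the *s* closing rate (A = 0.05 ms⁻¹).
The remaining constants were calibrated once, before any acceptance
checking, against the published behaviour of the modelled current:

* the simulated resurgent-protocol I–V peaks at the −45 mV test level;
* the post-peak decay is single-exponential with voltage-dependent τ
  inside the reported 2–45 ms envelope over −75…−15 mV (realized:
  3.5–43 ms, monotone with depolarization).  The calibration targets were
  set strictly inside the envelope (2.5 ms at −75 mV, 40 ms at −15 mV)
  after an earlier endpoint-targeted calibration left the −15 mV value on
  the boundary;
* the current is elicited only by a depolarization followed by
  repolarization: at rest the *s* particle is closed, during the
  conditioning step *s* opens (τ ≈ 1 ms) while *f* shuts, and on
  repolarization *f* reopens (τ ≈ 3.3 ms, the rising phase) while *s*
  slowly closes (τ_s = 1/β_s, the decay phase).

Functional forms are restricted to three families (exponential, linoid,
sigmoid), all scaled by a multiplicative temperature factor Q (default 1
at the ~24 °C reference).  The linoid form's removable singularity at
V = V₀ is evaluated as its limit A·K.

The default conductance `g_NaR = 0.0112 µS` is the adult calibration: it
puts the peak I_NaR/I_NaT ratio of the simulated adult protocol at 0.28,
the recorded adult anchor.  The juvenile calibration (`0.0005 µS`) leaves
the normalized resurgent current below 0.05 at every test level,
mirroring its near-absence in pre-song juveniles.

## The transient Na⁺ current

I_NaT is phenomenological, assembled from the three published fitted
pieces: a Boltzmann conductance I–V
(g_max, V_rev, V_half, k), a power-law activation (1 − e^(−t/τ_a))^N, and
single-exponential inactivation e^(−t/τ_h).  Two presets are shipped
(`adult_24C`: 174 nS, 66.5 mV, −44.6 mV, 6.6 mV, τ_a 0.10 ms, N 10.7,
τ_h 0.33 ms; `juvenile_20dph_24C`: 95 nS, 60.0 mV, −30.7 mV, 7.3 mV,
0.15 ms, 3.7, 0.58 ms) with measured onset latencies of 0.11 and 0.17 ms.

For multi-segment protocols the same parameters drive a gate ODE: an
N-th-power first-order activation gate (identical to the power law at
fixed voltage) and a first-order inactivation gate.  The steady-state
inactivation curve is not part of the published fits; the voltage-clamp
default (midpoint −80 mV, slope 5 mV) is a calibration choice that keeps
steady window currents below ~2 % of peak so that the −60 mV resurgent
measurement is not contaminated (the recorded persistent Na⁺ current is
~1 % of peak).

## Voltage-clamp protocol and measurement

The resurgent protocol holds at −90 mV, conditions at +30 mV for 10 ms,
then steps to +15…−75 mV (−15 mV decrements) for 100 ms; sweeps are
sampled at 40 kHz by default and treated as independent (the 2 s
intersweep interval fully re-equilibrates the channel).  The transient
peak is the most negative sample of the conditioning window; the
resurgent peak is the most negative sample of the test window starting
0.5 ms after the transition (the settle interval excludes capacitive or
residual transient artifacts; the source protocol does not state a
window, so this is a package convention).  Decay fits are least-squares
single exponentials with an explicit failure flag (a segment that does
not decay is never silently assigned a τ).  Onset latency is the first
post-stimulus sample deviating from a line fitted to ≥ 2 ms of baseline
by more than 3 baseline SDs for 2 consecutive samples (the "3σ/2-sample"
constants are a stated choice).

P/4 subtraction uses four subsweeps at one-quarter command amplitude from
a hyperpolarized subtraction holding (−120 mV); all traces are zeroed on
their pre-stimulus baseline before subtraction, which annihilates linear
leak and capacitive components exactly (machine precision on a linear
cell) and recovers a superposed nonlinear current by linearity.

The power-law onset fit estimates the asymptote I_max from the settled
tail of the rise (mean of the final decile) rather than a single noisy
extremum, then fits (τ_a, N) on the window from onset to ~40 % of peak.
The (τ_a, N) pair is intrinsically ridge-correlated on such a window;
tolerances under noise are validated in the acceptance suite.

## Current-clamp analysis

* Spike threshold: voltage at the first sample whose dV/dt reaches
  10 V/s on the ascent (configurable; the walk-back starts at the
  upstroke's dV/dt maximum so a flat spike peak cannot fool it).
* Amplitude: peak − threshold.  Half-width: time above
  threshold + amplitude/2, with sub-sample interpolation of both
  crossings.
* Derivatives are centered differences without smoothing, so phase-plane
  plots are faithful to the raw trace.
* Train metrics: spikes/s = count/window; the instantaneous firing
  frequency is the reciprocal of the first interspike interval (a
  per-pair IFF series is also available); amplitude and max-rate
  adaptation ratios compare later spikes to the first.
* The membrane-potential residence distribution is a normalized histogram
  (default 1 mV bins).
* Passive properties from a hyperpolarizing step (default −150 pA):
  R_in = ΔV_ss/ΔI; τ_m from a single-exponential fit of the onset
  (decimated to ≤ ~1500 points for speed; the relaxation is slow);
  C_m = 10³·τ_m/R_in (pF from ms and MΩ); sag = |V_peak − V_ss|.
* The capacitive peak-current estimate is I = C_m · max dV/dt
  (pF · V/s = pA).  Note the printed summary-table legend attributes this
  to the repolarization rate, but every tabulated value reproduces
  C_m × max *depolarization* rate, which is also what the defining
  equation uses; the package follows the equation.

No liquid-junction-potential correction is applied by default (the
reference recordings were uncorrected); a constant offset option exists.

## The surrogate neuron and in-silico dynamic clamp

The surrogate is a single-compartment conductance model
(C dV/dt = −g_L(V−E_L) − I_NaT − I_K − I_h + I_inj + I_dc) integrated by
forward Euler at the clamp step (0.03 ms).  Passive values are taken
directly from the recorded group means (juvenile: R_in 422 MΩ,
C_m 103.3 pF; adult: 190.2 MΩ, 114.3 pF).  Active conductances are
calibrated so evoked spike features land within ±30 % of the group means,
with these documented exceptions:

* **Activation midpoint.**  The voltage-clamp Boltzmann midpoints
  describe the distributed (axon-initial-segment dominated) current; used
  raw in a somatic point model they produce nA-scale standing window
  currents at −70 mV and an apparent threshold near −70 mV.  The
  surrogate shifts the midpoint by +22 mV (adult) / +12 mV (juvenile).
* **Inactivation midpoint.**  With h∞ centered at −65 mV the gate closes
  during the slow approach to threshold and the model cannot spike at the
  recorded thresholds; the presets use −54 mV (adult) and −48 mV
  (juvenile), slope 6 mV.  Inactivation recovery is voltage dependent
  (τ_h ≈ 0.33/0.58 ms depolarized, 2 ms/60 ms hyperpolarized for
  adult/juvenile); the slow juvenile recovery produces the cumulative
  amplitude and upstroke-rate decline seen in juvenile trains.
* **Juvenile repolarization rate.**  The juvenile preset's maximum
  repolarization rate calibrates to ~63 V/s against a 42.8 V/s target
  (+47 %): any weaker or slower K⁺ current sends the model into
  depolarization block.  A single-compartment trade-off, accepted.
* **Spontaneous rate.**  Both presets pace much faster than the recorded
  5–9 Hz (a window-current pacemaker cannot pace at ~10 Hz while also
  producing the required upstroke speeds).  Spontaneous-rate statistics
  are therefore validated through the template generator, not the
  surrogate.

The adult preset includes a slow HCN-like sag conductance calibrated so a
−150 pA step on the passive configuration shows the recorded ~5 mV sag.

The clamp loop reads V each step, advances the s/f gates, and injects
I_dc = −I_NaR (add) or +I_NaR (subtract); with zero conductance the
trajectory equals the unclamped one bitwise.  Rate constants are
evaluated directly each step (no lookup tables).  The published clamp
conductances are labelled "mS", dimensionally implausible for a ~100 pF
cell; the package maps those printed numbers onto its µS scale through
one calibration constant (0.038 µS per printed unit), chosen once so
that add-mode clamping of the juvenile surrogate raises the first-pair
IFF by 15–20 % on average across the four printed conductances
(7–27 % individually, monotone in conductance; a single linear constant
cannot place each conductance separately in the band because the
surrogate's response does not saturate).  Only directions and this band
are asserted; absolute ON/OFF feature values from real neurons are not
reproduced.

## The synthetic cohort generator

The generator draws per-cell parameters from the per-group
(mean, SEM, N) tables with per-cell SD = SEM·√N, under these rules:

* **Symmetric truncation.**  Draws are truncated at
  min(3 SD, distance to the nearest physical bound) on *both* sides, so
  bounds (positivity; thresholds in (−75, −15) mV; spontaneous rates
  ≥ 0.5 Hz) are respected while the expected value remains exactly the
  group mean.
* **Correlated waveform speed.**  Maximum depolarization rate, maximum
  repolarization rate and amplitude are drawn jointly (correlations
  0.95/0.80), mirroring the dominant principal component of the recorded
  waveforms; marginals are untouched.
* **Half-width = floor + excess.**  Drawing half-width marginally puts
  mass on waveforms impossible at 40 kHz (wide-but-fast combinations).
  Instead each cell's half-width is the representability floor implied by
  its drawn rates plus an excess whose mean is set so the group mean
  equals the table mean exactly; its spread is the floor's natural
  variation plus a residual term.  This also encodes the physical
  anti-correlation between half-width and repolarization speed.
* Rare joint draws that remain unrepresentable (or whose peak would not
  overshoot −10 mV) are redrawn whole; the residual mean shifts are below
  the recovery tolerances (measured in the test suite).

Current-clamp trains are synthesized as analytic spike templates built as
slope profiles on the sample grid: the centered-difference derivative
reads the programmed maximum rates exactly, the 10 V/s criterion lands on
the programmed threshold sample, the peak equals threshold + amplitude
exactly, half-widths match to within half a sample, and spike peaks sit
at exact interspike intervals.  Mapping per-cell feature targets onto the
conductances of the Hodgkin–Huxley surrogate would be an ill-posed
inverse problem; the template path is the right instrument for validating
the *extraction* pipeline, while the surrogate carries the dynamical
experiments.  Passive responses are analytic RC relaxations (ΔV_ss
anchored to R_in·I exactly) with an optional flat-topped sag dip of
specified amplitude placed after the RC transient settles.  Voltage-clamp
families wrap the protocol simulator and add linear leak, capacitive
transients (series resistance 10 MΩ, τ 0.1 ms), Gaussian current noise
and P/4 subsweeps.

Default noise: 2 pA RMS on currents; 0.005 mV RMS on voltages.  The
voltage default is small compared with raw instrument noise because the
template path synthesizes the post-acquisition-filter trace directly,
while the extractor differentiates without smoothing; noise levels are
fully configurable.

The printed (R_in, τ_m, C_m) group means are not mutually consistent with
τ = R·C, so the generator draws R_in and C_m and derives the RC constant;
τ_m is a derived, not an independently recovered, column.  Female groups
print no τ_m/C_m rows; a nominal C_m (100 pF) is used for simulation only
and excluded from recovery targets.  The adult-40 °C group has no printed
passive values and borrows the adult-24 °C ones, flagged as an
extrapolation.

**What passing recovery tests shows.**  Cohort recovery (group means
within 2 SEM at n = 20, averaged over replicate cohorts; within 1 % at
n = 10⁴ for the adult and pre-song juvenile male groups) demonstrates
that the extraction pipeline is unbiased against data whose ground truth
is known and whose waveform idealizations (piecewise-analytic spikes,
white noise, exact RC passives) hold.  It does not establish robustness
to real-recording pathologies: electrode drift, seal instability,
correlated noise, spike-shape change within a train, or filtering
artifacts.

## Problem sizes and tolerances

Acceptance-scale runs use: the 7-sweep resurgent protocol at dt 0.03 ms;
100 seeded replicates for noisy fit round-trips (noise RMS defined as 2 %
of the fitted signal's RMS); 1-second +300 pA clamp comparisons; cohorts
of n = 20 (five replicates, all nine groups) and n = 10⁴ (the two
headline groups).  Fit tolerances: noiseless round-trips < 0.1 %; under
2 % noise V_half ± 1 mV, τ ± 5 %, N ± 15 %.  Euler convergence is checked
by dt-halving (error ratio 2.0 ± 0.1) with both step counts integrated to
a common grid-aligned end time.

## Known limitations

* The rate-constant set is a calibrated stand-in constrained by two
  published override values and published behaviour, not a transcription
  of the original model's full numeric table.
* The surrogate neuron is a single compartment: no axon initial segment,
  so biphasic phase-plane upstrokes are not reproduced by default, and
  the spontaneous-rate / repolarization-rate compromises above apply.
* The generator's spike templates idealize waveform shape; they carry the
  tabulated features, not the full diversity of real spike shapes.
* Temperature enters only as a multiplicative Q factor on rate constants
  and as separate 40 °C group statistics; no Arrhenius modelling.
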