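# Methods

`gecog` implements the complete analysis chain of a DC-coupled
graphene-transistor (g-SGFET) electrocorticography experiment: sensor
calibration and noise figures, brain/motor-state scoring, high-voltage
spindle (HVS) detection, infra-slow phase-amplitude coupling with surrogate
statistics, and event-triggered analyses.  Because no public dataset exists
for this recording modality, the package ships a first-class synthetic
session generator whose defaults encode the recording conditions the
pipeline is meant to recover; every analysis stage is validated against that ground
truth plus closed-form and brute-force oracles.

## Sensor model and calibration

A solution-gated graphene transistor converts the gate (tissue) potential
into a drain–source current through the slope of its stationary
I_ds–V_gs curve.  The curve has a current minimum at the charge neutrality
point (CNP), where the transconductance G_m = dI_ds/dV_gs changes sign.
Calibration inverts the small-signal relation

    V_sig(t) = (I_ds(t) − I_ds(V_bias)) / G_m(V_bias),

using the *signed* slope, so polarity is correct on both the hole
(G_m < 0) and electron branches.

*Transfer-curve fitting.* Each sweep is fitted with a cubic smoothing
spline whose penalty is selected by generalized cross-validation; G_m is
the analytic derivative of the spline.  The CNP is located on the fitted
curve and then refined by a local quadratic fit of the raw sweep points
within ±25 % of the sweep range around the minimum: the curve is smooth
and locally parabolic there, and the vertex estimate is substantially less
noise-sensitive than the spline argmin (95th-percentile error ≈ 2 mV vs
≈ 10 mV under 1 %-of-range current noise on a 50-point sweep).  A minimum
at the sweep boundary marks the channel unusable.  The working-channel
rule is |g_m| ≥ 0.7× the array median; the threshold is configurable.

*Noise figures.* Noise is gate-referred as S_Vgs(f) = S_Ids(f)/G_m²
(Welch PSD: Hann window, 50 % overlap, segments 8× the longest band
period, one-sided density).  The sensitivity figure of merit V_gs-rms over
a band is the root of the integrated S_Vgs.  For 1/f current noise the
band rms is equal in any two bands of equal logarithmic width — the
default report bands 0.05–0.5 Hz and 20–200 Hz are one decade each.

*Frequency response.* The graphene–electrolyte interface attenuates the
transconductance with a fractional power law |g_m|(f) ∝ f^(−α), α ≈ 0.1.
The exponent is fitted by least squares on log|g_m| vs log f (scale
invariant by construction) and corrected in the frequency domain by
dividing the spectrum by f^(−α), unity at 1 Hz, DC bin untouched.
Magnitude-only correction is the default; a measured phase curve can be
applied optionally.

*CNP drift.* Chronic recordings drift; the generator default is a
saturating exponential reaching 50 mV in ~24 h with a ~20 mV/h initial
rate (total/τ with τ = 2.5 h).  `track_cnp` reports per-sweep CNP,
finite-difference rate and accumulated drift, and flags re-biasing when
the accumulated drift exceeds a configurable bound (default 50 mV).

## Spectral estimation

All state logic runs on multitaper spectrograms of AR(1)-prewhitened LFP
(y[t] = x[t] − a·x[t−1], a = lag-1 autocorrelation clipped at 0.999):
4-s windows in 0.5-s steps, DPSS tapers with NW = 3, K = 5 (the taper
parameters are this package's choice), per-window constant detrend,
one-sided density normalization so that band-integrated power matches the
windowed variance.  An infra-slow preset (60-s windows, 5-s steps,
0.015–4 Hz) serves the DC-channel analyses.  Band power sums density bins
whose centres fall in [lo, hi); band *density* (mean across bins) is used
where a ratio of unequal-width bands is formed.

## Motor states and rearing

Head speed is the Euclidean norm of the central-difference derivative of
the 3D head position.  The coordinates are first despiked with a 0.25-s
moving median — applied to the *positions*, not the speed, because median
filtering the speed cannot remove the positive bias that white marker
jitter induces (1 mm of frame-to-frame jitter at 120 Hz alone produces a
median 3D "speed" above 100 mm/s; filtering positions reduces it to
< 10 mm/s and is exact for linear motion).  Dropped frames are linearly
interpolated up to 0.5 s; longer gaps propagate as missing.

Activity: speed > 100 mm/s, then gaps shorter than 5 s are concatenated
and active fragments shorter than 5 s dropped (merging first cannot delete
fragments that would have been absorbed); inactive is the exact
complement.  Rearing events are maximal periods with head elevation above
200 mm, onset/offset linearly interpolated at the threshold crossings;
rears are treated as an overlay of the active state.

## Brain-state machine

Detections on the two reference channels (posterior "theta", frontal
"HVS"; they may coincide in reduced fixtures):

* **SW**: z-score of the summed 1–4 Hz + 10–25 Hz power > −0.1.
* **Theta**: theta (5–9.5 Hz) to delta (2–4 Hz) *mean-density* ratio above
  a threshold.  The protocol leaves the threshold unstated; the default
  here is 4.0, chosen (before any end-to-end runs) as the geometric
  midpoint between the whitened 1/f-background ratio (≈ 2.4 — whitening
  weights density by roughly f², lifting the theta band relative to delta)
  and planted/physiological theta ratios (≥ 15).
* **HVS**: HVS share the theta fundamental band but are strongly
  non-sinusoidal, so the mean 20–50 Hz (harmonic) density is z-scored over
  the whole recording and thresholded at 0.7; candidates shorter than 1 s
  are skipped.  Each candidate's onset/offset are then refined to the
  half-of-peak-power crossings (baseline = series median): a 4-s analysis
  window smears a burst's z-crossings outward by up to half a window
  (≈ +2.6 s duration bias for a boxcar burst), whereas the half-peak
  crossings of the smeared profile sit at the true edges.  The raw
  z-crossing extent is kept as the event *core* (z ≥ 0.7 throughout).
  Events whose mean spectrum lacks a local peak below 12 Hz are rejected
  as artifacts (stand-in for an unspecified post-hoc screen).

Combination rules, in order: HVS extents (core ± 2 s guard) are excised
from the raw SW/Theta streams — an HVS is an overlaid event that does not
interrupt its background state, and its fundamental/harmonics would
otherwise fabricate Theta/SW during immobility.  Gap concatenation (5 s
SW, 10 s Theta) is applied *after* the excision, with excised time off
the clock, so genuine REM theta re-bridges across events of any length;
for the same reason the pipeline defers merging to this stage rather than
merging inside the detectors.  Theta beats SW at overlaps.  Then:

1. SWS = SW ∩ inactive, truncated wherever it falls within an HVS event
   or less than 10 s after one.
2. REM = inactive Theta longer than 5 s directly preceded by SW.  The
   written rule says "within 1 s"; threshold crossings estimated with 4-s
   windows carry up to half a window of edge bias (measured: an
   instantaneous SWS→REM transition yields SW-offset/Theta-onset estimates
   ~1.5 s apart on clean synthetic data), so the pipeline evaluates the
   rule at 1 s + window/2 = 3 s.  `combine_states` itself defaults to the
   literal 1 s.
3. Remaining Theta → AwT; everything else → AwNT.
4. The span each HVS masked is merged into the flanking state when both
   flanks agree, else into the preceding state; IMM = inactive ∩
   (AwT ∪ AwNT).  Each event is assigned the background state at its onset.

The four states partition the scored span exactly; the partition and the
full rule set are checked against an independent dense-mask implementation
on randomized label streams.

## Phase-amplitude coupling

The statistic is the power-weighted mean resultant of the slow phase,
normalized by mean power: M = ⟨P e^{iφ}⟩/⟨P⟩, |M| ∈ [0, 1], arg M the
preferred phase (0° at the slow oscillation's peak, increasing with
time).  Bands come from zero-phase band-pass filters (2nd-order
Butterworth sections run forward–backward; half-power points f₀ ± bw/2;
defaults 0.04 Hz bandwidth for ISA, 0.4 Hz for LFP) and the analytic
signal; infra-slow filtering runs on data decimated to 10 Hz for
numerical stability, with fast-band power block-averaged onto the same
clock.  Power defaults to the squared envelope (the magnitude is
available; the choice affects weighting, never the preferred phase).
Filter edges (~3/bw seconds) are masked.

Significance: surrogates circularly shift the power series by a lag drawn
uniformly from ±[5, 100] s (near-zero lags are excluded so the null is
not contaminated by residual alignment), p = (1 + #{|M_s| ≥ |M_obs|}) /
(n_surr + 1); the grid of one comodulogram is masked by Benjamini–Hochberg
FDR at rate 0.001.  Note the arithmetic coupling: the smallest achievable
p is 1/(n_surr+1), so the surrogate count must exceed (cells / rate) for
any cell to survive — the defaults (1000 surrogates, rate 0.001) suit
single-cell tests, and the calibration suite uses proportionally larger
rates with its reduced surrogate counts.  The surrogate test has no power
against strictly periodic slow signals (a shifted sinusoid is a rotated
copy of itself); real ISA/theta are narrowband noise, and the synthetic
fixtures follow suit.

## Event-triggered analyses

Triggered ensembles align series or spectrogram windows on event times;
trials overlapping the recording edges are dropped and counted.  The
REM-onset contrast compares per-frequency-bin across-trial medians of the
30 s pre vs post windows with a paired permutation null (pre/post label
flips within trials, two-sided, +1-corrected; 1000 permutations).  The
ISA state contrast integrates 0.01–0.1 Hz power per epoch (mean square of
the band-passed, decimated DC trace) and applies the Wilcoxon rank-sum
test per channel with a REM>SWS direction flag; states with fewer than 5
epochs are skipped.  HVS characterisation reports per event the duration,
background state, first-spectral-peak frequency (6–12 Hz search band),
power at that frequency relative to a (−10, −2) s pre-onset baseline, and
per-channel DC transients (extremum of the ≤1 Hz low-passed DC trace
within the event minus the baseline mean), plus IMM-vs-REM rank-sum
contrasts, hourly duration totals and a topographic transient map.
Rear-triggered gamma reports band-resolved triggered power and the median
across trials of post/pre mean power for the 60–70 Hz and 90–200 Hz bands.

## Synthetic sessions

`generate_states` builds a polyphasic schedule over {AwNT-active, AwT,
IMM, SWS, REM} as repeating cycles with log-normal dwell times; REM is
reachable only from SWS.  Event counts are *exact by construction*:
capacity-checked deterministic placement puts the configured number of
HVS inside IMM (566) and REM (92), with log-normal durations of median
5 s, ≥ 11 s spacing and ≥ 10 s margins from state boundaries, and 163
rears inside active wake (heights ~N(250.6, 20) mm clipped above 225,
durations ~N(5.7, 2.8) s).  44 REM episodes (log-normal, median 110 s,
clipped ≥ 70 s) all satisfy the > 40 s inclusion rule.  Flexible
AwNT-active blocks absorb the remaining time so the schedule tiles the
requested duration exactly.  All draws are seed-deterministic
(bit-identical output for equal seeds).

`generate_lfp` superposes, per state: 1–4 Hz slow-wave noise (200 µV rms)
and 10–14 Hz spindle noise (80 µV) in SWS; harmonic-free 7.5 Hz theta
(100 µV) in REM/AwT; sawtooth-like HVS (fundamental 8.5 Hz in IMM, 7.5 Hz
in REM; 1/k harmonics up to 50 Hz, 300 µV, raised-cosine edges centred on
the nominal onset/offset so the half-power extent equals the nominal
duration); narrowband ISA at 0.08 Hz with state-dependent amplitude
(100/300/50 µV in SWS/REM/wake); 60–70 Hz and 90–200 Hz gamma noise, the
high band halved during rears; 1/f background (30 µV) plus a small white
floor.  Default couplings multiply component power by
(1 + depth·cos(φ − φ₀)): ISA→theta in REM (depth 0.8, 340°), ISA→spindle
in SWS (0.6, 180°), theta→high-gamma in REM (0.6, 0°).  Each HVS also
carries an infra-slow DC transient whose sign reverses along the
anterio-posterior axis (+200 µV posterior to −200 µV frontal).  Absolute
amplitudes are order-of-magnitude realistic for rat epicortical
recordings, not measured values.

`sensor_forward` pushes gate traces through the stationary transfer curve
(smooth symmetric softplus-V; saturation slope 2 mS/V × V_ds, width
50 mV, bias 100 mV into the hole branch), adds 1/f and white current
noise, and applies the headstage paths: DC channels wideband with coarse
quantisation, AC channels through a causal first-order 0.15 Hz high-pass
with finer quantisation.  Transfer sweeps are emitted at configurable
timestamps, tracking the drifting CNP.

What the generator does *not* emulate: biophysical LFP forward modelling,
electrode–tissue chemistry, motion artifacts, non-stationary noise,
low-amplitude NREM microstates, EMG, or inter-animal variability.
Passing tests therefore demonstrate that the *analysis chain* implements
its rules correctly and recovers structure it is designed for at
realistic SNR — not that it would score real recordings at any particular
accuracy.

## Problem sizes and numerical choices

The reference fixture is a 24-h session at 250 Hz ephys / 120 Hz motion
with one LFP reference channel serving as both the theta and HVS channel
(the scoring chain uses only the two reference channels, and the
generator plants both signals on every channel); full 64-channel sessions
are exercised at shorter durations.  At 250 Hz the spectral analyses run
to the 125-Hz Nyquist; fixtures that exercise the 90–200 Hz rear-gamma
band use 500 Hz.  Scoring spectrograms are computed to 55 Hz (nothing
above the 20–50 Hz HVS band is consumed) and in chunks of 8192 windows to
bound memory.  Monte-Carlo suite sizes (replicate counts, surrogate
counts, simulation lengths) are chosen so each check resolves its stated
tolerance; all are seeded.

Degenerate inputs: constant traces whiten to zero-mean with a warning and
yield no HVS; zero delta power is floored at 1e−12 in the theta ratio
with a warning; empty interval sets are legal everywhere; channels whose
transfer-curve minimum sits at the sweep edge, or whose |g_m| at bias
falls below a configurable floor (default 0.1× array median), are masked
rather than calibrated.

## Known limitations

* The HVS artifact screen (local spectral peak below 12 Hz) is a stand-in
  for an unspecified manual post-hoc classification.
* Detected rear onsets are threshold crossings and therefore sit inside
  the planted z-excursion, not at its start; counts are exact, onsets are
  biased by a fraction of the excursion duration by construction.
* The theta-ratio threshold and the REM-adjacency window compensation are
  calibrated to prewhitened multitaper estimates with 4-s windows; other
  spectral presets would need both revisited.
* `head_speed` implements ‖p′‖ (speed of the head), not the literal
  "derivative of the modulus of the coordinates" ‖p‖′, which differs on
  curved paths at constant radius.
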