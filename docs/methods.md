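# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data validation does and does
not demonstrate.

## The measurement model

An optoelectronic sensor projects an infrared curtain across the entrance
of a trap; a flying insect partially occludes the beam at its wing-beat
rate, producing an audio-band photocurrent. After analog conditioning
(high-pass at 70 Hz to strip the DC illumination level, low-pass at 5 kHz
as an anti-alias stage, both 6th-order Butterworth with unit passband
gain), the signal is digitized as mono PCM and normalized to [−1, 1].
Absolute amplitude is treated as arbitrary throughout: it depends on
insect size, flight path and gain staging, so all downstream features are
either frequencies or magnitude *ratios*, both invariant to overall scale
(a property the test suite asserts).

The wing-beat signal of a passage is modeled as a harmonic burst: a
fundamental F0 plus components near integer multiples k·F0 with decaying
magnitudes, shaped by a smooth envelope of 0.15–0.45 s. For the two
species handled here the fundamental distributions are taken as
Normal(113.75, 7.97) Hz for *A. fraterculus* and Normal(160.81, 10.71) Hz
for *C. capitata*, with mean fundamental-to-2nd-component magnitude ratios
of 2.26 and 2.05 respectively. (Published magnitude-ratio figures for
these species are not fully consistent across analyses — values of 1.79
and 2.05 also appear with the species assignments swapped; the simulator
keeps the per-species characterization values. Magnitude ratios are not
used for classification in any case, because the two species' ratio
distributions overlap almost completely.)

## Synthetic data generator

`wingbeat.synthetic` generates labeled tracks: harmonic bursts at random
non-overlapping times over a background of white noise, 60 Hz mains hum
and a slow sinusoidal baseline wander standing in for ambient luminosity
fluctuation. Choices worth noting:

* **Component placement.** Components sit at k·F0 plus a small Gaussian
  jitter (default SD 1.5 Hz). Wing-beat harmonics in real recordings are
  near-integer multiples; the jitter keeps the generator from being
  unrealistically exact without destroying harmonicity.
* **Envelope.** A Tukey (cosine-tapered) window with 25 % taper. Real
  passage envelopes vary with flight path; any smooth unimodal envelope
  exercises the detection and windowing logic equally.
* **Amplitudes.** A1/A2 is the species' magnitude ratio; components k ≥ 3
  decay geometrically (factor 0.55). The peak amplitude defaults to 0.5 of
  full scale, comfortably above the default noise floor (SD 0.003) —
  the regime in which the sensor's events were characterized.
* **Event placement.** Event count = rate × length; positions are drawn
  by distributing the free time uniformly between events with a minimum
  gap of 0.3 s. Rates too high for non-overlapping placement are
  rejected rather than silently truncated.
* **Sensor chain.** The analog front end is emulated with causal digital
  Butterworth filters (SOS form) at the analog cut-offs; the low-pass
  stage engages only when the sampling rate exceeds 10 kHz (below that it
  would sit at or above Nyquist, and the band is already limited). An
  ideal 6th-order high-pass at 70 Hz attenuates 60 Hz hum by ≈ 8.7 dB,
  which the tests verify as ≥ 8 dB.
* **Determinism.** One `numpy` Generator seeded from the config drives
  all randomness; identical configs produce bit-identical tracks.

**What the simulator does not emulate:** optical occlusion physics,
phototransistor nonlinearity and the spectral degradation it causes in
the 3rd–5th components of real recordings, amplifier noise beyond
additive white noise, multiple insects in the beam at once, and wing-beat
frequency drift within a passage. Passing the recovery tests therefore
shows the *pipeline* is correct and unbiased under the stated statistical
model — it does not by itself establish field performance, where
component degradation makes higher components unusable (mirrored here
only by the picker's validity flags).

## Detection

The RMS profile uses a 30 ms window advancing by 20 ms ("10 ms overlap"
read as overlap between consecutive windows; a 10 ms hop is available via
config). Events are maximal supra-threshold runs; bounds are resolved at
window granularity with no sub-window refinement, so a core duration is
accurate to roughly one window. A trailing partial window is dropped.

The RMS threshold on normalized signals is installation-dependent, so the
default is automatic: 5 × the median window RMS. The median is robust to
sparse events and tracks the background level; the factor 5 sits midway
(in log terms) between the noise floor and the ≥ 10× event RMS regime the
characterization assumes.

Standard-group criteria: core duration ≥ 100 ms, and a direct passage.
Direct passage was a manual judgment in the original protocol (an
indirect passage shows a mid-event collapse of signal strength); it is
operationalized here as a dip test on the event's RMS profile — a window
counts as a dip when it falls below `dip_fraction` (default 0.5) of the
smaller of the running maxima to its left and right. Defined this way,
any unimodal rise-and-fall profile passes regardless of envelope shape,
while a two-lobed profile whose valley drops below half the flanking
peaks is rejected. (The naive alternative — comparing every interior
window against the global peak — misfires on long tapered events, whose
edge windows are legitimately far below the peak.)

## Feature extraction

* **Windowing.** The 4-term Blackman–Harris window is evaluated directly
  from its cosine-series coefficients (a0 = 0.35875, a1 = 0.48829,
  a2 = 0.14128, a3 = 0.01168); the tests cross-check against the scipy
  implementation and assert the edge (6 × 10⁻⁵) and center (1.0) values
  and symmetry.
* **Autocorrelation.** The raw biased sum r_xx(l), computed via FFT
  (verified against a brute-force lag scan). The lag search is limited to
  70–500 Hz equivalents: the un-normalized autocorrelation always peaks
  at lag 0, so an unbounded search is degenerate, and 70 Hz is the
  front-end's lower cut-off. The estimate is quantized to integer lags —
  at 19.2 kHz and F0 ≤ 200 Hz the induced error is under 1 Hz — and no
  interpolation is applied, matching integer-valued reporting.
* **FFT path.** Zero-padding to a whole second gives 1 Hz bins (events
  longer than 1 s pad to the next whole second and gain resolution).
  Peaks are bin centers; no parabolic interpolation by default.
* **Component picking.** The fundamental is the globally largest in-band
  (70–1000 Hz) magnitude. Candidate components are strict local maxima
  above the fundamental, at least `min_separation` apart (default 10 Hz,
  widened at runtime to the fundamental's mainlobe width ≈ 8/T Hz so the
  windowed mainlobe's skirt cannot register as a component), and at least
  1 % of the fundamental's magnitude (the genuine components of the
  harmonic model are ≥ 7 % even at the 5th; everything below −40 dB is
  sidelobe or noise floor). Missing components are flagged invalid, not
  fabricated.
* **Failure modes.** Both estimators have documented octave-error modes,
  reproduced by construction in the tests: the FFT picker returns 2·F0
  when the 2nd component out-magnitudes the fundamental, and the
  autocorrelation returns F0/2 when subharmonic content makes the full
  pattern repeat at twice the period.

## Characterization

Descriptive measures use the n−1 sample SD; kurtosis is excess and
bias-corrected, skewness bias-corrected (a normal population gives values
near zero, matching the near-zero shape coefficients a correct pipeline
should report). Quartiles use linear interpolation between order
statistics. Cleaning per feature:

1. **Octave gates** (per species, configurable): *A. fraterculus*
   FFT-derived features above 200 Hz, and *C. capitata* outside
   70–280 Hz, are peak-location errors, not biology, and are removed with
   reason recorded. The autocorrelation feature is not gated by default.
2. **Boxplot fences**, applied once (no iteration).
3. **Shapiro–Wilk** at p > 0.05. Failure downgrades to a flag on the
   model rather than aborting: after octave-error removal the features
   are expected to pass, and the flag preserves the diagnostic.

The t-based CI is X̄ ± t₀.₉₇₅,ₙ₋₁ · S/√n; the implementation is verified
against numerical integration of the t density to 4 decimals for the
sample sizes that occur in practice.

## Classification

The per-feature boundary is the root of the quadratic obtained by
equating the two normal log-densities, taking the root strictly between
the means (with equal SDs the quadratic degenerates and the midpoint is
returned directly). This boundary minimizes total equal-prior error,
which a simulation test confirms by showing ±1 SD shifts strictly
increase error. Misclassification probabilities are the normal tails
beyond the boundary. Events are labeled by majority vote of the three
frequency features; ties and boundary hits return "unknown" rather than
forcing a label. A log-likelihood-sum rule is available behind a flag and
agrees with the vote on clear cases.

## Problem sizes and tolerances in the validation suite

The desk-scale working rate is 19 200 samples/s, an integer divisor of
the 192 ksamples/s capture rate, fully sufficient for a 70–1000 Hz
analysis band; 192 k is supported throughout. The end-to-end recovery
experiment simulates 66 *A. fraterculus* and 111 *C. capitata* events —
the standard-group sizes at which the species were characterized — and
requires the recovered mean of each fundamental-frequency feature to fall
within 3 standard errors of the generating mean, and the empirical
two-species classification error (autocorrelation feature, boundary from
the characterized models) to fall within 3 Monte-Carlo standard errors of
the Gaussian-overlap prediction. Oracle-equivalence tests pin the RMS
profile to a brute-force computation at 10⁻¹² relative, the
autocorrelation peak to a direct lag scan exactly, the density
intersection to a grid search at 0.01, and the t quantile to numerical
integration at 10⁻⁴.

## Known limitations

* Real recordings show spectral degradation of the 3rd–5th components
  (phototransistor response); the simulator's geometric decay is cleaner,
  so component validity rates here are optimistic.
* The dip-based direct-passage proxy is this package's operationalization
  of a manual criterion; its agreement with human judgment on real
  signals is untested.
* The event-bound quantization (one RMS window) biases measured core
  durations upward by up to one window length; the 100 ms standard-group
  floor therefore admits slightly shorter true bursts.
* Classification assumes equal priors and per-feature normality; strongly
  unbalanced populations would need posterior weighting.
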