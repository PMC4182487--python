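# Methods

This note documents the models behind `vasmotion`, the parameters that
matter, the deliberate numerical choices, and what the synthetic stages do
and do not capture about a physical audio-visual motion experiment.

## Spherical-head anechoic filters

Individualized measured HRIRs cannot be shipped with a software package,
so the anechoic conditions use a rigid-spherical-head stand-in that
preserves the azimuth-dependent binaural cue structure the experiment
manipulates:

* **Interaural time difference.** Woodworth's formula
  ITD(θ) = a/c · (θ + sin θ), head radius a = 8.75 cm, c = 343 m/s;
  at 90° this is ≈656 µs.  The ITD is split ±ITD/2 around a 2 ms base
  delay and realized as a Hann-windowed-sinc fractional delay (±32
  samples at 48 kHz).
* **Interaural level difference.** A first-order pole/zero head-shadow
  filter per ear, H(s) = (1 + α s/2ω₀)/(1 + s/2ω₀) with ω₀ = c/a and
  α(θ_inc) = 1.05 + 0.95 cos(θ_inc·180/150) as a function of the angle
  between source and ear axis: a ~6 dB high shelf on the bright side
  grading into a deep high-frequency shadow near 150° incidence,
  discretized by the bilinear transform.

At the midline both ears see identical filters, so ITD = 0 and the
broadband ILD vanishes exactly.  The model is front-back symmetric and
has no pinna cues or elevation dependence; it is a cue generator, not an
individualized ear.

## Image-source reverberant filters

The reverberant condition simulates a small listening room as a shoebox
with uniform wall absorption:

* **Geometry.** 3.4 × 2.5 × 2.0 m (17 m³), listener at (1.7, 0.8, 1.2) m,
  sources on a 1 m frontal arc.  Only volume and reverberation time are
  physically constrained; the listener position was chosen so that the
  nearest image source — the ceiling bounce, path length
  √(1 + 1.6²) = 1.887 m — trails the 1 m direct path by 2.59 ms at
  *every* azimuth of the ±90° arc, and no other image ever arrives
  earlier.  This keeps the direct-to-first-reflection gap inside the
  2–3 ms window characteristic of the emulated room at all source
  positions, not just straight ahead.
* **Absorption.** Sabine's formula α = 0.161·V/(S·RT60) sizes a uniform
  energy absorption coefficient from the 200 ms target (α ≈ 0.337 for the
  default room); an α > 1 is reported as an infeasible room.  Arrivals are
  attenuated in *energy* by (1 − α) per wall bounce — amplitude
  √(1 − α)^order — which is the assumption under which Sabine's formula
  holds; squaring the amplitude factor instead would roughly halve the
  achieved decay time.
* **Spatialization.** Every image arrival passes through the
  spherical-head model at its arrival azimuth (rear arrivals folded onto
  the frontal grid by front-back symmetry, which the head model shares),
  delayed by distance/c and scaled by 1/distance.  The direct path and
  first-order reflections use exact fractional delays; the dense late
  field (order ≥ 2) reuses head filters cached on a 1° grid with
  nearest-sample delays — a ≤10.4 µs timing quantization that is
  irrelevant to decay statistics but makes an order-30 render take
  ~0.5 s instead of ~50 s.
* **Defaults.** Image order 3 for rendering filters (enough to populate
  the preserved 21 ms window); order ≈30 when an un-truncated render is
  needed to estimate RT60, since the Schroeder fit needs ~35 dB of decay
  (≈120 ms of dense tail).  The achieved Schroeder RT60 of the default
  room is ~0.225 s against the 0.2 s Sabine target — Sabine is an
  approximation, and the suite only requires agreement within ±25%.

## Sweep measurement chain

The simulated measurement uses the exponential sine sweep
x(t) = sin(2π f₁ L (e^{t/L} − 1)), L = T/ln(f₂/f₁).  The inverse filter
is the amplitude-compensated time-reversed sweep realized by regularized
spectral inversion: conj(S)·W/(|S|² + δ), with δ = 10⁻¹⁰·max|S|², W flat
over [f₁, f₂] with ⅓-octave raised-cosine skirts outside the band, and
the design delay placed at the centre of a buffer long enough
(2·(N + 0.25 s·fs)) that the band-limited delta's ringing never wraps —
so the linear and circular convolutions agree and sweep ∗ inverse is
flat in band to ~10⁻³ worst-case (~10⁻⁵ typical).  Deconvolution takes
lag zero at `len(inverse)//2`; a `pre_roll` option shifts the capture
window ahead of the direct arrival, as a real recording does, so the
band-limitation pre-ring of an early onset is preserved.  Round-tripping
a random ≤21 ms filter through the chain recovers it with in-band
relative L2 error ~3·10⁻⁵.

BRIR truncation keeps 21 ms after the direct onset (1008 samples at
48 kHz; onset = first sample within 20 dB of the peak) and applies a 1 ms
raised-cosine fade at the cut to avoid spectral splatter; the emulated
protocol only states that the tail was discarded, so the fade is this
package's choice.

## Acoustic metrics

* **D/R.** Direct window [peak − 0.5 ms, peak + 1 ms] per channel,
  everything later is reverberant; pair values averaged in dB.  The 1 ms
  direct window sits inside the 2.6 ms first-reflection gap.  Because a
  strongly shadowed contralateral ear's direct arrival can be weaker than
  later reflections, the per-channel direct peak is searched within
  1.5 ms of the pair's common onset rather than taken as the channel
  maximum.
* **RT60.** Schroeder backward integration, least-squares line on the
  −5…−35 dB span, RT60 = −60/slope; less than 35 dB of available decay
  degrades gracefully to the available span with a warning.
* **Reflection census.** Per-channel local maxima above a −20 dB
  threshold relative to the direct peak, ≥0.25 ms apart (so filter
  ringing is not counted), merged across channels.  The contralateral
  ear's delayed *direct* arrival is binaural structure, not a reflection,
  which is why censusing is per channel.

## Carrier and motion rendering

The carrier is white noise shaped by 79 linear-phase bandpass filters
(centres 400…16000 Hz every 200 Hz, nominal 100 Hz bandwidth, Kaiser
60 dB design — the 200 Hz spacing deliberately leaves spectral gaps) under
a common full-depth 20 Hz raised-sine envelope starting at its minimum.
Rate and coherence of the modulation are the specified properties; depth
and phase are this package's choice.  Because all bands share the
envelope, the bank is applied as one summed kernel — mathematically
identical to filtering per band and summing.  Output is RMS-normalized
(default 0.1); the same seed gives a bit-identical carrier.

Motion is rendered by slicing the carrier into per-position dwells of
θ/velocity seconds (boundaries from rounding the cumulative clock, so
drift never reaches one sample), convolving each slice with its azimuth's
filter pair, and overlap-adding every segment's convolution tail onto the
next segment — the exact splice for piecewise time-invariant filtering.
With the same filter at every position the segmented render equals one
full convolution to machine precision, which is the oracle the tests use.
A linear-crossfade splice is available behind `join="crossfade"` for
comparison.

Position counting is inclusive of both endpoints: a −70°…+70° path at 5°
occupies 29 positions, giving 5.8, 2.9 and 1.45 s at 25, 50 and
100 °/s.  At 1° quantization the same trajectory occupies 141 positions
(5.64 s at 25 °/s): endpoint conventions cannot make both grids produce
identical durations, and no equalization is applied — the counting rule
is exposed rather than guessed around.

Offset convention: positive μ = auditory lag = vision leads in space.
`plan_trajectory` displaces the auditory path μ° against the direction of
motion (rightward visual −70…+70 with μ = +10 → auditory −80…+60) and
refuses paths leaving the measured ±90° grid, which bounds usable offsets
at ±20°.

## Observers and the simulated study

Observers are decision-level: they respond on the programmed offset
through ψ(μ) = λ + (1 − 2λ)Φ((μ − PSE)/σ), without an auditory model in
the loop.  Rendered waveforms therefore exercise the acoustics tests, not
the psychophysics — linking the two through a waveform-level observer is
future work, and results about PSE/β recovery say nothing about whether a
human would show those parameters.

The schedule reproduces the design: nine signed offsets per velocity
(25 °/s: 0, ±1.25, ±2.5, ±5, ±10; 50 °/s: 0, ±2.5, ±5, ±7.5, ±10;
100 °/s: 0, ±5, ±10, ±15, ±20), ten repeats = 90 trials per block,
offsets shuffled without replacement within each repeat cycle, direction
strictly alternating (which balances direction across offsets by
construction; whether the original protocol balanced them within blocks
is not stated, so the scheduler's guarantee is the documented choice).

The simulated cohort draws per-subject true parameters from
PSE ~ N(0, 2°), σ log-normal with median ≈3.5° (log-sd 0.3), and
λ ~ U[0, 0.04] — biases of a few degrees and spreads of 2–6°, the
range a practiced observer plausibly occupies on this task.  Under the
null configuration a subject keeps identical parameters in every
condition, mirroring a study whose acoustic manipulations have no
perceptual effect; `condition_shift` injects genuine effects when a
positive control is wanted.

## Psychometric fitting and inference

* ψ is a cumulative Gaussian with symmetric lapse, λ ∈ [0, 0.06].  β is
  reported as the standard-deviation (spread) parameter in degrees — the
  only reading that keeps β in common units across velocities — with β²
  exported alongside for the variance parameterisation.
* Fitting is bounded maximum likelihood (binomial, with the combinatorial
  term included) by L-BFGS-B with an analytic gradient, five
  deterministic restarts around a probit-regression initialiser, ties
  broken toward smaller λ.  Perfectly separated data (all per-offset
  proportions 0 or 1) leave β unidentified below some value; such fits
  are returned flagged rather than rejected.
* Bootstrap CIs are parametric percentile intervals: resample binomial
  counts from the *fitted* ψ at the observed offsets and trial numbers
  (n = 1000 by default), refit each (initialised from the parent fit),
  take the 2.5/97.5 percentiles; intervals are widened if necessary to
  contain the point estimate, and a refit failure rate over 5% attaches a
  warning.  Coverage of the 95% PSE interval at the 90-trial block size
  measures ~0.93–0.95 in simulation.
* The two-way repeated-measures ANOVA is the explicit within-subject
  decomposition: each effect tested against its own subject×factor
  interaction mean square, no sphericity correction, p from the F
  survival function.  Degenerate tables with zero effect variance report
  F = 0, p = 1 (a 0/0 elsewhere).  The implementation is ~30 lines of
  numpy and is cross-checked in the tests against both a brute-force
  mean-decomposition oracle and statsmodels' AnovaRM to 10⁻¹⁰; its
  simulated type-I error under a subjects-only null sits inside
  [0.03, 0.07] at α = 0.05.

## Known limitations

* The head model has no pinna, torso or elevation cues; "anechoic D/R"
  of a synthetic HRIR is essentially unbounded unless the filter is
  passed through the band-limited measurement chain, so only the
  *ordering* (anechoic ≫ reverberant) is meaningful, not the absolute
  values a physical measurement would give.
* Uniform absorption and a bare shoebox make the late field more regular
  than a furnished room's; RT60 is matched in broadband terms only.
* At 100 °/s the offset grid (±5…±20°) is coarse relative to sharp
  observers (σ ≈ 1–3°): only the zero offset is informative, β is biased
  low and a spurious velocity dependence of measured β can appear in
  group summaries.  This is a property of the offset design itself, and
  it is visible in the simulated study's tables.
* Problem sizes in the validation suite are chosen for a desk-scale run:
  100 replicate blocks for recovery, 200 for bootstrap coverage
  (n_boot = 200 there), 1000 null tables for ANOVA calibration, image
  order 30 for RT60 scoring.
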