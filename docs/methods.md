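# Methods

## Gaze geometry and biomechanics

A standing subject's ankles sit at radius *r* = 12.5 cm from the platform
tilt axis; a tilt of θ translates the body vertically by *r* sin θ (±1.31 cm
at ±6°).  With a fixation LED at *d* = 50 cm straight ahead at eye level,
complete compensation requires a vertical eye rotation of
atan(*r* sin θ / *d*) (±1.50° at ±6°), opposite in sign to the translation.
The exact sin/atan forms are used throughout; at 6° they differ from the
small-angle version by < 0.2 %, but exactness costs nothing.  The head is
treated as rigidly coupled to the ankle point: knee/hip compliance shows up
in the simulator as head-pitch drift, not in the geometry.  A single
cyclopean eye at LED height is assumed (no vergence geometry).  Angles are
degrees at all public interfaces, with upward platform rotation positive.

The head–neck segment mass is a fixed fraction of body weight (0.080 for
women, 0.0826 for men).  Its length — eye height minus C7 height — feeds an
inverted-pendulum model whose period 2π√(L/g) is 1.01 s at the cohort mean
L = 25.5 cm, matching the preferred stride rate of ~1 stride/s.

## Stimulus construction

**Experiment A** places five cosine-phase sequences (six full cycles each at
0.8, 1.6, 1.0, 1.4, 1.2 Hz, starting and ending at the +6° hold level) in an
exactly 40.96-s record, separated by 2-s holds at +6°.  The record length
equals 8192 samples at 200 Hz; since the source material does not place the
stimulus within the record, the surplus hold time is split equally into a
leading and trailing flank.  The inter-sequence holds sit at +6° (the
elevated start level), exposed as a configuration choice.

**Experiment B** chains 22 half-cosine excursions between −6° and +6°, the
i-th lasting 1/(2 fᵢ), with frequencies stepping up an 11-value logarithmic
ladder (0.254, 0.308, 0.362, 0.445, 0.529, 0.631, 0.764, 0.927, 1.093,
1.330, 1.589 Hz) and back down the same ladder; each half-cycle is a pure
half-sine at its nominal frequency (a piecewise-frequency chirp).  A
plantarflexion start departs from −6°, a dorsiflexion start from +6°; the
two traces are exact mirrors.  The record carries 6-s lead/tail holds at the
start/end level: the wavelet cone of influence at 0.254 Hz reaches ~5.3 s in
from each record edge, so a recording starting at the first half-cycle would
leave the lowest-frequency windows edge-contaminated.

Both builders record one analysis window per cycle (A: 30) or half-cycle
(B: 22), which is the granularity of all downstream estimates.

## The simulator

Validation rests on parameter recovery, so the simulator injects known
structure.  Inside each window the eye is the gain-scaled, time-shifted
required waveform — the delay is a genuine time shift, not a per-harmonic
phase rotation — with delay and gain cross-faded over 50 ms at window joins
and held at nearest-window values through pauses.  Nuisance terms emulate
video-oculography at 220 Hz:

* **Sensor noise** — Gaussian, sd 0.05° (between the tracker's 0.02°
  resolution and ~0.1° precision), band-limited below 25 Hz.  Video-based
  trackers low-pass their position output through the image-processing
  chain; white noise at the full sample rate would put central-difference
  velocity noise near the 25°/s blink threshold, which contradicts the
  premise of the velocity-based blink rule.
* **Quantization** — 0.02° steps.
* **Blinks** — raised-cosine pulses, amplitude 3–8°, duration 0.1–0.3 s,
  Poisson rate 0.2/s; every pulse's peak velocity exceeds 25°/s, so the
  detector's thresholds are the only property that matters downstream.
* **Head-pitch drift** — a ≤ 0.1 Hz low-passed Gaussian process, scaled to
  0.3° and shaped by an activity envelope that returns toward zero during
  holds and pauses.  The envelope's transition width scales with the slowest
  stimulus window (0.75/f_min) so that the drift stays spectrally below the
  analysis band; postural drift is a slow reaction to the stimulation, and
  an envelope with fast edges would inject artificial power at analyzed
  frequencies.  The drift couples 1:1 into the recorded eye position, and
  its derivative is the simulated head-pitch-velocity channel.

The default response profiles encode the published group-level behaviour
(Experiment A: 0.8 Hz delays 2→37 ms across cycles, 1.6 Hz 72→40 ms, 1.0 Hz
constant 37 ms, gains 0.64 with 1.6 Hz rising 0.57→0.73; Experiment B:
ascending delays linear in log-frequency from −137 ms (dorsiflexion start)
or −19 ms (plantarflexion start) at 0.254 Hz to +40 ms at 0.927 Hz and
above, descending half constant +41 ms, gains 0.74).  The 1.2/1.4 Hz ramps
(60→40 ms) are interpolated defaults — the corresponding per-cycle endpoints
were never published — and are excluded from quantitative acceptance.

The anthropometric cohort draws weight ~ N(67.4, 11.0) kg, 13:7
female:male, head–neck length ~ N(25.5, 2.7) cm and C7 height
~ N(145, 7.9) cm, deriving eye height as C7 + length (the published summary
table is internally inconsistent here: its printed eye/C7 means imply a
15 cm segment; the printed segment length itself, on which the pendulum and
stride results depend, is honored).  Stride frequency lies on a descending
plane, 0.99 − 0.022 (L − 25.5) − 0.045 (m − 5.5) strides/s, with residual
sd 0.088 calibrated so a two-predictor OLS fit recovers adjusted R² ≈ 0.37
in expectation at n = 20.

What the simulator does **not** model: saccade/pursuit interplay, binocular
disparity, recorded blink waveforms, biomechanical ankle–knee–hip
compliance, or any nonlinearity of the reflex itself.  Passing recovery
tests therefore shows that the analysis chain is unbiased and precise for
compensatory responses of this class — not that it would be robust to, say,
heavy saccadic intrusions.

## Preprocessing

Eye traces are polyphase-FIR resampled from 220 to 200 Hz onto a grid
sharing t = 0 with the platform record (the acquisition hardware
synchronizes the two streams).  Velocity is a two-point central difference
at the trace's own rate, without pre-smoothing.  Blink detection follows
the two-threshold rule — maximal intervals with |v| > 25°/s, extended to
the nearest flanking samples with |v| < 10°/s — applied to |v|, since the
rule's signedness is not specified by its source.  Because eye velocity
passes through zero at a blink's apex, the rule naturally yields a rise and
a fall interval with the apex between them; intervals separated by less
than 50 ms are merged so the substitution spans the whole transient.
Flagged samples are replaced by linear interpolation between the interval's
boundary samples (the substitution step is under-specified in the source
material; any local interpolant works, as the coherence analysis is
insensitive to it).  Head pitch angle is the cumulative trapezoidal
integral of the pitch-velocity channel, initial angle 0, no detrending.

Before the spectral analysis, every analyzed trace — eye, inverted
platform, and the required-eye reference — passes the identical zero-phase
4th-order Butterworth high-pass at 0.15 Hz (0.75× the lower edge of the
analysis band).  Slow postural drift otherwise perturbs phase estimates at
the lowest analyzed frequencies; the cutoff balances drift rejection
against the filter's residual influence on the lowest analyzed scales.
The filter is flat and zero-phase across the band, and applying it
identically to every trace cancels its sub-1 % amplitude droop in all
ratios and cross-spectra.

## Wavelet coherence

Analytic Morlet mother wavelet (ω₀ = 6), FFT implementation, scales
log-spaced at 20 voices/octave over 0.2–2.0 Hz (two octaves around the
stimulus band).  The smoothing operator is a boxcar over time of one
scale-length and a boxcar over 0.6 octave of adjacent scales (12 bins at
this voicing) — the decorrelation width conventional for Morlet coherence;
much narrower scale smoothing leaves the coherency nearly degenerate (unit
modulus everywhere) and voids the significance test.  Coherence |c|² is
bounded in [0, 1] and self-coherency is identically 1 under any smoothing.
The cone of influence excludes points within √2·scale (the wavelet
e-folding time) of either record edge.

Significance is assessed pointwise against seeded white-noise surrogate
pairs of identical length, rate and analysis settings, pooled per scale
over in-cone times; the threshold is the 1 − α/m quantile with α = 0.01 and
Bonferroni divisor m = number of analyzed scales (the least aggressive
reading of a frequency-wise decision; configurable).  White-noise
surrogates are appropriate because the analyzed traces are deblinked and
band-limited.  The thresholds depend only on the record geometry and
settings and are cached across subjects.  Gating uses |c|²; the signed real
part is available alongside.

## Per-cycle delay and gain

The window **delay** starts from the circular-mean coherency phase over the
window's pixels at the scale nearest the nominal frequency, converted via
Δt = 1000·φ/(2πf) with positive = eye lags the inverted platform.  The
wavelet's temporal support and the smoothing blend neighbouring cycles'
phases into each window, biasing this raw statistic by several ms wherever
the delay changes between cycles.  The blending is predictable: the
smoothed cross spectrum is a linear combination of per-window kernels
(each the smoothed cross spectrum of the required waveform restricted to
one window against the full inverted platform, with smooth
partition-of-unity edges and hold segments carried as separate terms),
computable from the stimulus layout alone.  The estimator therefore
subtracts, in one explicit pass, the bias predicted by evaluating the same
circular-mean statistic on the kernel model populated with the measured
window means.  A full fixed-point or least-squares inversion of the
blending is deliberately avoided: its near-collinear directions amplify
small smooth contaminations (in-band drift, blink-substitution residue)
into large phase errors at the lowest-frequency windows, whereas the
single-pass correction inherits the window mean's noise immunity.  On
noiseless input the residual bias is ≤ ~3 ms everywhere except the
steepest part of the ascending dorsiflexion ramp in Experiment B
(0.6–0.9 Hz), where the delay changes by > 100 ms per octave and ~5–7 ms of
blending survives — a genuine time-frequency resolution limit of the
method, not removable without assuming the profile's shape.  Windows whose
significant in-cone coverage is below 50 % yield a missing estimate rather
than a biased one.

The window **gain** is the amplitude of a frequency-locked least-squares
sinusoid fit (offset as nuisance) to the band-limited eye trace over the
window, divided by the same fit to the required trace.  The locked fit is
delay-invariant and well-defined on half-cycle windows where a
peak-to-peak amplitude is not.  No linear-trend nuisance term is included:
over a half-cycle the locked cosine is itself monotone, so a trend would be
nearly collinear with it and steal amplitude; slow drift is already removed
by the band-limiting high-pass.  Head-pitch drift is never subtracted from
eye traces using the pitch channel (it is reported descriptively only).

Summaries aggregate within subject first, then across subjects
(mean ± SEM, N = subjects).

## Statistics

The designs are fully within-subjects (every subject sees every cell), so
the ANOVA engine implements a general k-factor within-subjects
decomposition on a complete balanced table: marginal-means sums of squares,
each effect tested against its own effect-by-subject interaction;
Greenhouse–Geisser ε per effect from the covariance of orthonormal contrast
scores, applied to the F degrees of freedom; generalized eta-squared with
all subject-related sums of squares in the denominator (the observed-effect
convention).  Any Bonferroni correction across a family of effects is the
caller's responsibility.  Subjects with incomplete cells (missing estimates)
are dropped before the ANOVA rather than imputed.  An up/down *direction*
relabeling helper reassigns Experiment B half-cycles by the parity rule
(odd half-cycles of a dorsiflexion start pair with even half-cycles of a
plantarflexion start) and feeds the same engine.  The stride-frequency
plane is an ordinary least-squares fit (statsmodels) reporting adjusted R².

## Problem sizes and numerical choices

Cohort analyses use 20 virtual subjects per experiment with five analyzed
repetitions per subject and start condition — the cohort size and trial
count of the original paradigm (which discarded one familiarization run
and analyzed five repetitions).  Per-cycle estimates are kept per
repetition and averaged within subject by every summary, which reduces
the group means' sampling error accordingly.  The
surrogate null uses 100 pairs; per-scale pooling over in-cone times makes
the extreme quantile stable at that count.  Smoothing, α, ω₀, voicing,
band, high-pass cutoff, surrogate count and the phase estimator variant
are all exposed in `RunConfig` and serialize to YAML; identical
configurations and seeds reproduce every output bit-exactly (seed streams
are derived statelessly, so reusing a seed object cannot advance it).

## Known limitations

* Per-window delay bias of up to ~7 ms in the steep-gradient region of the
  Experiment B ascending dorsiflexion ramp (see above); the grand means
  and all headline summary quantities are unaffected.
* At the lowest analyzed frequency a half-cycle window spans half a
  wavelength; per-trial delay scatter there is ~7–9 ms sd under default
  noise.  Averaging the five repetitions per subject brings the group
  means' SEM below ~1 ms at N = 20.
* The ANOVA engine requires complete balanced tables by design; designs
  with structurally missing cells are out of scope.
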