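# tvor

Analysis pipeline for the **vertical translational vestibulo-ocular reflex
(tVOR)** measured on a tilting platform, with a bundled video-oculography
simulator for end-to-end validation by parameter recovery.

## The problem

A person standing on a platform that tilts by ±6° about an axis ~12.5 cm
behind the ankles is translated vertically by ±1.3 cm (`r sin θ`).  To keep
fixating an LED 50 cm ahead at eye level, the eyes must counter-rotate by
±1.5° (`atan(r sin θ / d)`).  The tVOR drives these compensatory eye
movements; their **gain** (eye amplitude over the geometrically required
amplitude) and **time delay** relative to the platform quantify how well and
how quickly the reflex works — and how both depend on stimulus frequency,
repetition, and the proprioceptive state of the ankles (feet starting in
dorsiflexion vs. plantar flexion).

Two stimulus paradigms are implemented:

* **Experiment A** — five six-cycle sinusoidal sequences at 0.8, 1.6, 1.0,
  1.4 and 1.2 Hz, separated by 2-s holds, in a 40.96-s record (8192 samples
  at 200 Hz).
* **Experiment B** — 22 consecutive half-sine excursions between −6° and
  +6° whose frequency steps through a logarithmic ladder
  (0.254 … 1.589 Hz) ascending and then descending.

## The method

Per stimulus cycle (A) or half-cycle (B), for each subject:

1. **Preprocess** the 220 Hz eye trace: polyphase-resample to the platform's
   200 Hz grid; detect blinks by a two-threshold velocity rule (|v| > 25°/s,
   extended to the flanking samples with |v| < 10°/s) and substitute them by
   linear interpolation; band-limit to the analysis band.
2. **Wavelet coherence**: Morlet CWT (ω₀ = 6, 20 voices/octave,
   0.2–2.0 Hz) of the eye trace and the *inverted* platform trace, smoothed
   cross-coherency `c = S(W_e W_p*) / √(S|W_e|² S|W_p|²)`, with pointwise
   significance from seeded white-noise surrogates (p < 0.01, Bonferroni
   over scales) and cone-of-influence masking.
3. **Per-cycle reduction**: the time delay is the circular-mean coherency
   phase over the window at the stimulus scale, converted via
   `Δt = φ / (2π f)` and corrected for wavelet leakage with a forward-model
   bias subtraction; the gain is a frequency-locked sinusoid fit amplitude
   ratio.  Windows with < 50 % significant coverage yield no estimate.
4. **Statistics**: fully within-subjects repeated-measures ANOVA with
   Greenhouse–Geisser correction and generalized eta-squared (η²_G), plus an
   OLS plane with adjusted R² for the stride-frequency ~ head–neck segment
   regression.

Because no recordings of this paradigm are publicly available, a simulator
(`tvor.synthetic`) generates realistic trials with *known* injected
delay/gain structure — sensor noise, quantization, blinks and slow postural
drift included — so every stage is validated by recovering what was
injected.  Cohort runs follow the original protocol: five analyzed
repetitions per subject and start condition, averaged within subject.

## Worked example

```python
from tvor.pipeline import RunConfig, run_experiment

result = run_experiment(RunConfig(), "A", n_subjects=5, seed=1)
valid = result.estimates[result.estimates.valid]
print(round(valid.groupby("subject_id").gain.mean().mean(), 3))
print(result.summary.head(3).to_string(index=False))
```

prints

```
0.636
 frequency_hz  cycle_index  delay_ms_mean  delay_ms_sem  gain_mean  gain_sem  n_subjects
          0.8            1       3.365703      0.229167   0.639789  0.002471           5
          0.8            2       8.710208      0.209993   0.641182  0.002582           5
          0.8            3      16.035861      0.435333   0.634636  0.002822           5
```

i.e. the five simulated subjects' grand-mean gain is ≈ 0.64 (the injected
default), and the per-cycle summary recovers the rising delay ramp injected
at 0.8 Hz (2 → 37 ms across the six cycles) within a few ms.

The same flow is available from the shell:

```bash
tvor simulate-stimulus --experiment A --out trace.csv
tvor run --experiment B --subjects 20 --seed 1 --out results/expB/
```

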