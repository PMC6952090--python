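# Methods

## The decoding model

Every selectable item *i* flickers at a tag frequency *fᵢ*; the pupil
diameter of a user fixating item *g* is modelled as a noisy superposition of
entrained oscillations.  The decoder never fits this model — it only assumes
that fixation concentrates spectral power at *f_g* — but the synthetic
generator makes the assumption explicit:

    p(t) = B − Σᵢ wᵢ · G(fᵢ) · sin(2π fᵢ (t − τ)) + η_band(t) + η_white(t) − d(t)

with *wᵢ* = 1 for the fixated item and a leakage fraction otherwise, gain
G(f) = G₁ · exp(β (f − 1)), response latency τ, band-limited autonomic noise
η_band, white sensor noise η_white, and an onset constriction d(t) confined
to the first second.  The oscillation enters with a negative sign because
the pupil constricts to brighter light; the decoder is phase-blind, so only
the magnitude matters.

Decoding is: condition the trace, estimate its periodogram on a ~0.01 Hz
zero-padded grid, read the PSD at each candidate tag frequency (nearest
bin), multiply by the gain-correction weight ω(f) = 1/(a·e^{bf}), and take
the argmax.  The two-choice rule skips the correction: with candidate
frequencies only 0.06–0.25 Hz apart, the gain difference between them is
negligible and the raw comparison is already reliable.

## Pipeline and numerical choices

- **Trimming.** The first 1 s is excluded; the onset of a modulated stimulus
  drives a transient constriction unrelated to steady-state entrainment.
  A 10 s trial therefore contributes 9 s of data, an 8 s trial 7 s.
- **Smoothing.** 120 ms moving average — 40 samples at the 333 Hz nominal
  tracker rate (`window_length` rounds half up and never returns less than
  one sample).  Edges use a shrinking window so output length equals input
  length.
- **Normalization** is a z-score (mean 0, sd 1).  Within a trial this is a
  common positive rescaling of all candidate scores, so decisions are
  invariant to it; across trials it makes PSD magnitudes comparable
  regardless of recording units.
- **Periodogram.** Rectangular window; DFT zero-padded to
  N = ceil(Fs / 0.01) points (33,300 at 333 Hz), giving a grid spacing of
  exactly Fs/N ≤ 0.01 Hz.  Zero-padding interpolates the spectrum — a few
  seconds of data cannot resolve 0.01 Hz — but interpolation is exactly what
  reading the PSD at a known candidate frequency needs.  The implementation
  is checked against a brute-force O(N·K) DFT oracle at 1e−9 relative
  tolerance and against Parseval's identity on the two-sided grid.
- **Candidate read-out** is the nearest grid bin; exact midpoints resolve to
  the lower bin.  A `neighborhood` flag optionally takes the local maximum
  over a few bins on either side, for data whose oscillation frequency may
  be slightly off-nominal; it is off by default.
- **Ties** resolve to the lowest frequency (left item in the two-choice
  rule).  Any deterministic rule would do; this one is easy to test.
- **Exponential fit.** `curve_fit` (Levenberg–Marquardt) on a·e^{bx},
  initialized from an ordinary least-squares line through (f, log PSD)
  restricted to positive PSD values — the log-linear start keeps the
  iteration from diverging for any realistic calibration table.  R² is
  computed against the mean of the observed PSDs, RMSE as the root mean
  squared residual.  Degenerate inputs (fewer than three points, zero
  variance, a window longer than the trace, a trace with no valid samples)
  raise `ValueError` rather than returning nonsense.

## The gain correction

Pupil entrainment amplitude falls steeply with tag frequency, so raw PSD
comparisons across a wide frequency range systematically favour low
frequencies.  The calibration model a·e^{bx} describes the mean PSD peak as
a function of tag frequency; its reciprocal ω(x) = e^{−bx}/a flattens that
curve (correcting the model's own values yields a constant — a property the
tests exercise end to end).  The packaged default (a = 3.545, b = −2.844) is
a published group fit, so decoding works without per-user calibration;
`fit_exponential` / `ExponentialGainModel.fit` re-estimate both parameters
from any (frequency, mean PSD) table.  The sign convention matters: ω must
be the reciprocal of the decay model, i.e. ω grows with frequency; the
opposite sign would double the bias instead of removing it.

## Synthetic data: what it emulates and what it does not

Canonical parameters (the defaults of `PupilModelParams`): gain 1.0 trace
units at 1 Hz; gain decay β = −1.422 Hz⁻¹ — half the calibration decay b,
because PSD scales with amplitude squared, so the published exponential PSD
curve emerges from simulation rather than being inserted; latency 0.4 s (a
typical light-reflex latency; the method is phase-blind so this only adds
realism); leakage 0.15 — non-fixated items entrain the pupil at 15 % of the
fixated amplitude, the mechanism that makes multi-item decoding harder than
single-item; white noise sd 0.5; hippus noise of amplitude 0.5 composed of
eight random-phase sinusoids in 0.15–0.40 Hz, the autonomic band tied to
heart rate and respiration; baseline 100 units; a 5-unit onset constriction
with a 0.25 s time constant, removed by the trim step; and a steep extra
gain roll-off (8 Hz⁻¹) beyond the 3.15 Hz pupil tracking limit.

Two emergent properties tie the generator to the analysis chain, both
measured on trimmed, smoothed, **demeaned** traces: fitting the exponential
model to mean PSD peaks across the twelve probe frequencies recovers a decay
within 15 % of 2β, and applying ω to the fixated item's PSD makes it
approximately frequency-invariant (coefficient of variation < 15 % over
0.75–2.75 Hz).  Mean removal matters here: without it, spectral sidelobes of
the large DC baseline dominate every candidate bin; with full z-scoring, the
division by total variance — signal-dominated at low frequency,
noise-dominated at high — would reshape the decay.  Decoding itself is
unaffected by this distinction, since within a trial the z-score rescales
all candidates equally.

The generator does **not** model: biomechanical pupil dynamics (no delay
differential equations), covert-attention modulation of the light reflex,
blinks (the repair step exists but simulated traces are blink-free),
age-related miosis, or square-wave stimuli.  Accuracies obtained on
synthetic trials therefore show that the *algorithm* is correct and robust
to the modelled noise; they do not predict human performance.  Notably, the
simulated low-frequency conditions (0.25–0.5 Hz) do degrade — hippus noise
lands near them — but the simulation makes no attempt to reproduce the
human tracking collapse at 3 Hz quantitatively, which is why evaluation
focuses on 0.75–2.75 Hz.

## Evaluation harness

A "participant" is an independently seeded replicate block; averaging over
blocks stands in for averaging over participants.  The protocols: 12
frequencies × reps of 10 s single-stimulus trials; 8 base frequencies × 3
offsets × both sides × reps of 8 s two-choice trials; 12 keys × reps of 8 s
keypad trials.  Problem sizes used by the acceptance script — 50
reps/frequency, 100 reps/cell, 50 reps/key — give binomial standard errors
under 1.5 percentage points per condition while keeping a full run in the
tens of seconds.  Conventional significance testing on the resulting
accuracy tables (ANOVA and post-hoc comparisons) is deliberately out of
scope; the harness exports per-trial outcomes so any statistics package can
consume them.

## Known limitations

- Real-time operation is out of scope: the decoder consumes complete trial
  recordings offline.
- The display model is anchored only at its measured endpoints (0.99 and
  99.4 cd/m² at γ = 2.8); mid-gray luminances of a particular monitor may
  deviate from the offset-gamma form.
- The nearest-bin read-out assumes the stimulus frequencies are known
  exactly; hardware frame-rate quantization of the actual flicker frequency
  is not modelled.
- With amplitude 128 the waveform's raw minimum is −1, clipped to 0; the
  resulting distortion is below one part in 255 and ignored.
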