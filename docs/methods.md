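# Methods

This note documents the signal model, the numerical conventions and the
genuinely open design choices in `ftcd`, in the spirit of a model
description a statistics or neuroimaging package would ship.

## Signal model and processing assumptions

fTCD measures blood-flow velocity in the left and right middle cerebral
arteries. The recorded signal is modelled as a baseline level modulated
by multiplicative fractional components: cardiac pulsation (~1–1.5 Hz,
~10% amplitude), a task-evoked rise on the 5–10 s scale, slow drift from
probe movement and arousal/respiration, and measurement noise. The
pipeline assumes:

* uniform sampling at a declared rate (a time column, if present, is
  ignored; non-uniform timestamps only warn);
* velocity channels are positive magnitudes on an arbitrary scale — only
  relative (%) changes are meaningful, which is why each channel is
  rescaled to a mean of 100 before any comparison across channels;
* the cardiac rhythm is common to both arteries, so cycle boundaries are
  detected once (on the left channel, after ~0.1 s smoothing, via
  prominence-based systolic peak picking) and applied to both channels.
  Channel-specific boundaries would desynchronize the left−right
  difference.

Order of operations: downsample → marker detection/selection →
(optional) trim → normalization → heart-cycle integration → epoching
with baseline correction. Trimming precedes normalization so that
rest-break excursions cannot bias the channel mean. Normalization
precedes cycle integration so step levels are in % units; because
normalization is a pure rescaling and cycle integration a segment-wise
mean, the two commute exactly, so this ordering is a presentation choice,
not a numerical one. In the per-epoch normalization scope, each epoch
slice is rescaled by its own mean (the defence against slow probe drift);
cycle boundaries are still detected on the whole record.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| analysis rate | 25 | Hz | ample for a 5–10 s response; decimation by sample-dropping (stride must be integer; no anti-alias filter, matching established fTCD practice — documented, not hidden) |
| epoch / baseline / POI | −20…30 / −15…−5 / 3…13 | s vs marker | word-generation protocol conventions |
| activation window | 2 | s | standard LI window; centred on the peak; truncation is an error, never silent |
| min marker separation | 50 | s | trial length minus jitter; reverse-order scan skips closer markers |
| marker height | 2.5 | event-channel units | strictly-above comparison ("above the set height") |
| acceptance range | 50–150 | % of mean | the permissive end of common 30–50% exclusion bands; bounds inclusive |
| max separation | 20 | % | above physiological left−right differences (~5–10), below unilateral-dropout separations |
| GOR limit | 2 | % of normalized baseline | standard exclusion criterion |
| cardiac min cycle / prominence | 0.33 s / 0.25 | — | 30–180 bpm; prominence as fraction of the robust (10–90th pct) range |

## The laterality index

On the pointwise average of accepted baseline-corrected epochs, the peak
of the difference d(t) = left(t) − right(t) is located within the POI and

LI = mean of d over [peak − w/2, peak + w/2), w = 2 s.

Two deliberate choices:

* **Mean, not sum.** The classical description accumulates d over the
  window; reported LI magnitudes in the literature are nevertheless on
  the % scale of d, implying the windowed mean. The sum is
  sampling-rate-dependent (sum = mean × samples), so the mean is the
  default and `li_mode="sum"` exists for strict replication.
* **Peak by |d| ("abs"), ties to the earliest sample.** A signed-max rule
  misses the response peak of right-dominant participants, and it breaks
  the antisymmetry the statistic should have: swapping the channels
  negates d, so the signed argmax would move to the original minimum.
  With the |d| rule the analysis is *exactly* antisymmetric — LI negates
  bitwise, the peak latency is unchanged — and for the dominant direction
  it coincides with the signed max. `peak_mode="max"`/`"min"` are
  provided for replication of fixed-direction pipelines.

Per-epoch LIs repeat the computation on each epoch's own difference
(peak located per epoch). Their SD/SE give the dispersion outputs; the
95% CI is centred on the pooled-average LI with half-width
t₀.₉₇₅,ₙ₋₁ × SE — centring on the mean of per-epoch LIs instead would let
the CI drift off the reported LI, because per-epoch peak-picking is
positively biased in |LI| (a max-statistic effect; see below). Cohen's
*d* is mean/SD of the per-epoch LIs. Inferential tests: one-sample t and
Wilcoxon signed-rank of per-epoch LIs against 0; paired t / signed-rank
of per-epoch left vs right POI means. Degenerate inputs (zero SD) are
reported as such with the documented p→0 (all-equal, nonzero) or p=1
(all-zero) convention.

## Screening and quality

Rejection reasons are evaluated in the order short → range → separation
→ manual, and *all* triggered reasons are recorded; verdicts are
per-epoch independent. Short epochs (windows leaving the record) are
excluded by default; when included by configuration they are NaN-padded
at the record edges and averaging uses the epochs available per sample
(baseline and POI must be intact either way). The acceptance band is
read as a ± band about the normalized mean (both bounds configurable).
GOR is the RMS deviation of the baseline about each epoch's baseline
mean, averaged over accepted epochs per channel, computed on the
normalized, cycle-integrated signal; for a pure sinusoid of amplitude a
it equals a/√2. Dropout is the fraction of samples equal to the dropout
value (default 0), computed on the raw (pre-normalization) channels.

## Reliability

Odd/even split by accepted order, plus a seeded random split (one split
per file per run; the seed is derived stably from the run seed and file
name and recorded in the output). Cronbach's alpha uses epochs as items
and files as cases, α = k/(k−1)·(1 − Σ item variances / variance of
sums), on the complete-case submatrix over the first k epochs present in
every file (k reported) — files reject different epochs, and
complete-case truncation is the transparent, reproducible resolution.

## The simulator

`simulate_recording` builds each channel as
`level · (1 + cardiac + response ± lateral/2 + drift + noise)`:

* cardiac: zero-mean, unit-peak half-rectified harmonic sum (fast
  systolic rise, slow decay) at 1.2 Hz, 10%, independent phase per
  channel;
* response: trapezoid (2 s rise, plateau, 3 s fall, 12 s total) starting
  2 s after each marker, 8% amplitude — the scale of published
  word-generation responses;
* lateral difference: +4% sustained over the response by default, split
  ±half between the channels, with per-epoch jitter SD 0.75% emulating
  modest trial-to-trial variability in lateralization (published
  per-epoch LI SDs of ~3 include peak-picking inflation and measurement
  noise, not only true amplitude variability, so the generative SD is
  set well below them);
* drift: 1% sinusoid per channel with a 127 s period, deliberately
  incommensurate with the 60 s trial spacing so drift does not alias
  coherently into the epoch average;
* noise: 1% white Gaussian per channel; dropouts multiply segments by a
  configurable attenuation (0 = loss); markers are 0.5 s pulses of
  height 5, plus optional spurious markers.

Defaults (23 trials × 60 s at 100 Hz) mirror the standard
word-generation session; tests use 4–30 epochs, which keeps the whole
suite under a few seconds while leaving ≥ 1500 samples per epoch stage.
Ground truth records true/spurious marker times, per-epoch injected
differences, dropout-contaminated epoch indices, and analytic per-epoch
design means (trapezoid area plus the closed-form drift integral), so
generator invariants are checked against closed forms rather than the
pipeline itself.

What the simulator does *not* emulate: real spectral-envelope
statistics, heart-rate variability, respiration-locked oscillations,
hemodynamic transfer functions, or movement artifacts with realistic
time courses. Passing parameter-recovery tests therefore shows the
pipeline is correct and unbiased under the stated signal model, not that
real recordings will be as clean.

## Numerical behaviour worth knowing

* **Peak-picking bias.** Locating a per-epoch peak in noise biases
  per-epoch |LI| upward (expected max of ~12 cycle-steps of noise). With
  the |d| peak rule the bias is symmetric in sign, so a truly
  non-lateralized subject yields per-epoch LIs centred on 0 and a
  correctly calibrated t-test; a signed-max rule would instead inflate
  the mean and produce spurious significance.
* **Cardiac residual.** At 25 Hz a 1.2 Hz cycle spans 20.83 samples;
  boundary quantization leaves a residual of a few tenths of a percent
  in the integrated difference. This bounds the precision of any single
  LI at roughly ±0.2–0.3 regardless of noise level.
* **Normalization attenuation.** Scaling each channel to mean 100
  divides the evoked % change by (1 + mean task uplift); with an 8%
  response over ~20% of the record the recovered LI is ~3–5% below the
  injected value. This is inherent to mean-100 normalization, not a bug.
* Marker comparison is strictly above threshold; an equal-separation gap
  between markers is accepted (skipping requires gap < separation).
* All tab-delimited output uses "." decimals, Unix newlines and
  shortest-round-trip float formatting, so re-reading reproduces values
  exactly.

## Known limitations

Proprietary binary Doppler formats are not read (only the documented
header+TSV dialect and generic delimited tables); no anti-alias filter
before decimation (deliberate, to match the sample-dropping convention);
response-locked (multi-marker) POIs use the first accepted epoch's POI
placement for the *averaged* LI, which is ill-defined when latency varies
— per-epoch LIs handle that case correctly; no between-group inference
(export the tables to your statistics environment).
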