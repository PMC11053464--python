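# Methods

## Pipeline

One analysis run proceeds per participant: five simultaneously recorded
muscle channels share a single time base and a single annotation track of
disfluency intervals (half-open `[onset, offset)` seconds, typed as
repetition, prolongation or block, each tagged with the session phase in
which it occurred). Fluent and disfluent 1-s windows are selected once on
the shared time base and applied to every channel; each channel is filtered
once per preprocessing branch and all windows are featurized from the
filtered full-length signal, so windows near each other see consistent
filter state and no per-window edge transients.

## Filters

Three linear-phase FIR designs at the acquisition rate (2148 Hz):

| filter | design | rationale for free parameters |
|---|---|---|
| low-pass | Hamming-window FIR, order 20, cutoff 400 Hz (−6 dB) | both order and cutoff are fixed by the acquisition protocol's published processing chain |
| high-pass | Blackman-window FIR, order 400, cutoff 20 Hz | order was not specified; 400 is the smallest even Blackman order whose DC leakage is below 10⁻³ while the gain at 100 Hz stays within 10% of unity |
| mains comb | single multiband FIR, order ≈ fs/2 (1074), notches ±2 Hz around k·60 Hz for k = 1..7 | notch width and order were not specified; ±2 Hz with a 1.5 Hz transition gives ≥ 20 dB attenuation at every harmonic centre while leaving 10 Hz and 90 Hz within 0.5% of unity. Harmonics stop at the 450 Hz acquisition band edge, not at Nyquist, because the hardware records nothing above it |

All kernels are symmetric, so zero-phase application is a single convolution
centred on the kernel midpoint (reflection padding at the edges); the
realized magnitude response is then exactly the designed one and events do
not shift in time. The amplitude branch (`full`) cascades all three
filters (kernels convolved into one); the tremor-band branch (`notch_only`)
applies only the comb, because a 20 Hz high-pass would annihilate the
5–15 Hz band being analysed. Keeping both branches explicit resolves the
ambiguity in the source processing description, which lists the full
cascade but describes the per-participant comparison as running after "a
60 Hz noise filter".

## Segmentation

Fluent windows: greedy left-to-right packing of 1-s windows that overlap no
(guard-expanded) disfluency interval, with at least 0.5 s between the end
of one window and the start of the next; up to 40 per participant, fewer
with a logged warning when the recording cannot supply them. For
fixed-length windows greedy earliest-feasible packing is maximal, and the
test suite checks it against an exhaustive dynamic program on a 1 ms grid.
A window is accepted when `start + 1.0 ≤ duration`; a 10 s annotation-free
recording therefore yields seven windows (starts 0, 1.5, …, 9.0). A
seeded-random selection strategy is available as an alternative.

Disfluent windows: one per annotated event, centred on the event midpoint
and clamped to the recording; events longer than the window start at the
event onset. Sample mapping truncates the start to `floor(start·fs)` and
takes exactly `round(fs)` samples.

## Features

Amplitude features (IEMG as the rectified Riemann sum × 1/fs, mean
amplitude, RMS, and a centred moving-RMS envelope with a 50 ms default
window) are computed on the `full` branch. Spectral features use a
single-window boxcar periodogram of the 1-s segment (1 Hz resolution, no
detrending or tapering), one-sided and density-scaled so the trapezoidal
integral over [0, fs/2] reproduces the time-domain mean square to well
under 1%. Band power integrates the periodogram over [5, 15] Hz by the
trapezoidal rule with linear interpolation at the band edges (implemented
as an exact weight vector); the band fraction is that integral as a
percentage of the total. A zero-power segment yields a fraction of 0 with
an explicit flag.

## Statistics

Segment features are averaged to per-participant cell means for each
(muscle, condition) and, in stratified analyses, per context or per
disfluency type (a type stratum restricts only the disfluent side; the
fluent reference is the participant's full fluent cell). Values entering a
contrast are divided by the pooled mean of both sides ("mean activity
normalization"); this controls between-participant scale without changing
any t-statistic. Normality is screened per side with Shapiro–Wilk
(scipy.stats.shapiro) and reported as advisory p-values; failures do not
switch the test. Contrasts are two-sided Student t-tests at α = 0.05
(scipy.stats.ttest_ind with pooled variance; Welch available as an option),
paired (ttest_rel) for within-group fluent-vs-disfluent contrasts on
participants having both conditions. Cells with fewer than two values per
side are skipped with a logged reason. No multiple-testing correction is
applied by default, matching per-test reporting; a Benjamini–Hochberg flag
exists as a clearly separate extension. Percent differences follow the
"higher by N%" convention: 100·(high − low)/low, signed toward the
first-listed side of the contrast.

Pooled-variance t-tests on participant means are calibrated only when the
between-participant variance component dominates the within-participant
measurement noise in every cell; the synthetic generator is built to
reproduce that hierarchy (below), as real sEMG does.

## Synthetic studies

The generator emulates the study design: 30 control (A) and 55 stuttering
(B) participants, five muscles on one shared time base, session phases
(spontaneous personal-data speech, reading, phone call, exposition),
acquisition at 2148 Hz with a ±11 mV range, 60 Hz mains with harmonics, and
a sixth control channel spiking 5 mV for 10 ms at each disfluency onset.

Per channel the signal is

```
x(t) = A(t)·[ c(t) + g(t)·s(t) ] + mains(t),   clipped to ±11 mV
A(t) = baseline · subject_scale · env(t) · effect(t)
```

- `c(t)`: unit-RMS Gaussian carrier, band-limited to 35–450 Hz with steep
  raised-cosine edges (frequency-domain synthesis). The low edge sits above
  the tremor band plus the envelope-modulation bandwidth, so the carrier
  and its modulation sidebands contribute essentially nothing to 5–15 Hz;
  sub-35 Hz content of the emitted signal comes from the tremor component
  and envelope sidebands, as in real recordings.
- `env(t)`: tonic level 0.4 plus Poisson bursts (2 s⁻¹, 0.15–0.45 s,
  Hann-shaped) — a syllabic activity envelope shared across conditions, so
  that with no injected effect every comparison is exactly null.
- `effect(t)`: the per-(group, muscle, condition) amplitude factor, ramped
  over 0.35 s at event boundaries (muscle activation does not step
  instantaneously, and a hard gate would be a square-wave modulator).
- `s(t)`: unit-RMS 5–15 Hz narrowband noise; `g(t)` is a physiological
  tremor floor present in every channel (median gain 0.022 relative to the
  carrier, log-normal σ = 0.2 across channels) plus any injected
  condition-dependent gain. Because the tremor term is scaled by the same
  `A(t)` as the carrier, a pure amplitude effect moves band power and total
  power together and leaves the band fraction invariant — amplitude and
  tremor effects are separable by construction. An alternative `am` mode
  multiplies the carrier envelope by `(1 + g·s)` instead, which places the
  oscillation in the envelope spectrum only.
- `subject_scale`: log-normal with σ = 0.4 per (participant, muscle),
  matching the large between-participant amplitude variability of surface
  EMG; together with the tremor-floor spread it makes between-participant
  variance dominate within-participant noise, which is what keeps the
  pooled t-test calibrated.

Disfluency events arrive as a homogeneous Poisson process per context block
(defaults 1/min for group A, 8/min for group B), typed
repetition/prolongation/block with probabilities 0.5/0.25/0.25 and uniform
durations (0.2–1.5 s; blocks 0.3–2.0 s). All randomness derives from one
integer seed through independent `numpy` seed sequences per participant and
channel; identical configurations are bit-identical.

What the generator does **not** emulate: motor-unit physiology, electrode
artefacts, movement artefact below 20 Hz, audio coupling, inter-muscle
correlation, or context-dependent amplitude differences. Passing recovery
tests therefore demonstrate that the pipeline measures what this model
injects at realistic noise levels — not that the physiological effects
exist in real speakers.

## Problem sizes used in tests and the acceptance script

Calibration and power runs use the full group sizes (30 + 55) but shortened
sessions: two 20 s context blocks per participant, with disfluency rates
raised to 12/min (A) and 15/min (B) so that each participant still
contributes a realistic number of windows per analysis cell (roughly 20
fluent and 5–10 disfluent) — the quantity that matters statistically, and
what the full-length protocol (recordings of several hundred seconds, 40
fluent samples per participant) provides. Null calibration pools the full
comparison plan over 36 simulated studies; effect recovery uses 50 studies
with group B's DAO disfluent amplitude at 0.4× and a ZM tremor gain of
0.006 on both conditions, which raises B's measured ZM band fraction by a
factor of about 1.5 over the physiological floor (≈ 0.06%, matching the
published direction and relative magnitude of the tremor-band finding).
The acceptance script repeats these measurements at 12 null and 16 effect
studies to stay fast.

## Known limitations

- **Amplitude→band-fraction coupling.** A genuine amplitude drop *within*
  a 1-s analysis window makes the windowed signal nonstationary: total
  power falls while the window-edge and modulation leakage of the boxcar
  periodogram does not fall proportionally, so the measured 5–15 Hz
  fraction of that window rises slightly. With the suppression effect at
  0.4× this residual shift is a few percent of the band-fraction floor —
  negligible for between-group comparisons, but within-participant paired
  contrasts are sensitive enough to flag it at large n. This is a property
  of windowed band-fraction analysis itself (any implementation of this
  metric, including the original, shares it), not of the synthesis; a
  tapered periodogram option would reduce it at the cost of departing from
  the plain-DFT definition of the metric.
- The Student (pooled-variance) test is assumed calibrated via the
  variance hierarchy above; strongly heteroskedastic real data would favour
  the Welch option.
- One window per annotated event means long or clustered events are not
  re-weighted; overlapping windows are permitted and counted once each.
- The sample-size formula is the infinite-population form; no
  finite-population correction is provided.
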