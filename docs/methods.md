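# Methods

This note documents the models, parameter choices and numerical decisions
behind `emgpress`, in the order data flows through the package.

## Study design assumed by the pipeline

The analysis expects a fully-within crossover design: each participant
performs four overhead-press variations — barbell military press (BMP)
and machine shoulder press (MSP), each with the load path in front of or
behind the head — while surface EMG is recorded at 1000 Hz from six
muscles (anterior/medial/posterior deltoid, upper trapezius, clavicular
pectoralis major, lateral triceps brachii). A set is six repetitions with
2-s ascending, ~0.5-s isometric and 2-s descending phases; phase
boundaries come from an external event source (in practice a 30-Hz camera
sync, represented here as an event table with optional 1/30-s
quantization). Each muscle additionally has three 5-s maximal voluntary
isometric contraction (MVIC) trials.

## Signal reduction

- **Filtering.** 4th-order Butterworth band-pass, 10–500 Hz. At
  fs = 1000 Hz the upper edge sits exactly at Nyquist, which is not
  designable; the implementation clamps it to 0.99·fs/2 (495 Hz) and
  warns once. Default application is zero-phase (forward–backward), which
  squares the magnitude response (−6 dB at the edges) but leaves the
  envelope lag-free; a causal mode is available. The same filter is
  applied to MVIC and exercise trials so normalization is internally
  consistent.
- **Envelope.** 25-ms moving RMS with hop = 1 sample (a fully overlapping
  "mobile" window). Windows lie strictly inside the signal — no padding,
  which would bias the edge phases — and are stamped at window centers.
- **MVIC reference.** Per attempt, the envelope mean over the central 2 s
  (symmetric around the attempt midpoint); across attempts, the maximum
  by default ("peak attempt"), with a mean-of-attempts rule available.
- **Phase means.** A window contributes to a phase iff its center lies in
  [onset, onset + duration). Repetition aggregation drops the first and
  last repetition of each set (technique consistency), so at least three
  repetitions are required.
- **Normalization.** nRMS = 100 · phase mean / MVIC reference; values
  above 100 % are legitimate (dynamic efforts can exceed the isometric
  reference).

## Placement QC

The accepted "belly-shaped" spectrum is quantified, since a visual
criterion cannot be tested. PSDs are averaged periodograms
(Hann-tapered 0.25-s blocks, half overlap, ≈4-Hz resolution) over 1-s
segments at the start, middle and end of each trial; the integral of the
estimate matches segment variance within the estimator's accuracy
(verified to 2 % on long stationary signals). A segment passes iff:

| criterion | default | artifact it targets |
|---|---|---|
| spectral median frequency | 40–150 Hz | gross spectral displacement |
| power fraction below 20 Hz | < 0.10 | motion/baseline drift |
| line ratio (50 ± 2 Hz vs flanks) | < 5 | mains interference |
| pronounced edge mode | off | innervation-zone placement |

The edge-mode flag requires the spectral mode to lie within 5 Hz of the
expected physiological band's edges (20–150 Hz) *and* to stand at least
3× above the in-band median density. The peak-factor guard exists because
a healthy spectrum has a flat top: the argmax of a noisy flat estimate is
nearly uniform over the band and would otherwise land near an edge in
~8 % of clean segments, while a true edge-concentrated spectrum exceeds
the factor by orders of magnitude. All thresholds and the line frequency
(50/60 Hz) are configurable. A trial passes only if all three segments
pass. QC runs on raw (unfiltered) traces, since the band-pass would mask
exactly the low-frequency signatures being screened.

## Statistics

- **Design.** Per muscle, an n × 8 table (participants × load × position
  × phase). Every factor has two levels: each of the 7 effects has 1
  numerator df, its error term is the effect × subject interaction
  (n − 1 df), and sphericity corrections do not apply. The implementation
  computes per-subject ±1 contrast scores; F = n·L̄²/s²_L, which equals
  the squared paired t statistic of the contrast — the identity the test
  suite uses as an oracle, alongside a cross-check against statsmodels'
  AnovaRM and an exact sum-of-squares conservation identity.
- **Effect magnitude.** η²ₚ = F·df₁/(F·df₁ + df₂).
- **Multiple comparisons.** Bonferroni within presentation families: per
  muscle and phase, the 6 exercise pairs (m = 6); per muscle, the 4
  ascending-vs-descending contrasts (m = 4). A single global family
  (m = 28) is selectable.
- **Effect sizes.** Cohen's d with pooled SD across the two conditions
  (n − 1 denominators, no small-sample correction) and the z-based 95 %
  interval d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))). The pooled-SD d
  and normal interval are the conventional reporting pair this package
  reproduces. Two consequences are documented rather than "fixed": the
  estimator carries the textbook finite-sample factor (E[d̂] = δ/J(ν),
  Hedges' J; ≈ +5.7 % at n = 8), which calibration tests remove before
  comparing to programmed values, and the z-interval under-covers at
  n = 8 (measured ≈ 90 % instead of 95 % in the suite's coverage test).
- **Normality.** Shapiro–Wilk per cell is reported for screening only;
  the pipeline never branches on it. Constant cells are reported as
  degenerate.

## Synthetic-data generator

- **Carrier.** White Gaussian noise shaped by a 4th-order Butterworth
  band-pass, default 20–150 Hz — the simplest model with the belly-shaped
  spectrum. The carrier band is deliberately narrower than the 10–500 Hz
  acquisition filter so conditioning removes almost nothing.
- **Exact level calibration.** Within each (repetition, phase) segment
  the carrier is rescaled to unit RMS before amplitude modulation, so the
  realized segment RMS equals the programmed level exactly rather than in
  expectation. This makes ground-truth tables exact by construction and
  keeps end-to-end recovery error (filtering edge effects, 100-ms linear
  ramps between phase levels, the concavity bias of averaging 25-ms RMS
  values) under ~2–3 %, versus the ~3 % per-phase sampling scatter a
  free-running carrier would add. MVIC plateaus (0.5-s edge ramps, 4-s
  flat middle) are scaled the same way on their central 2 s.
- **Population structure.** Participant MVIC amplitudes are log-normal
  around 400 µV with CV 0.15 (no amplitude distribution is available to
  copy; these are plausible surface-EMG magnitudes). Participant-level
  activation deviations are N(0, `within_cell_sd`), default 0.05 nRMS
  fraction, independent across cells; a standardized difference δ between
  two conditions is therefore programmed as a mean difference of
  δ·`within_cell_sd`.
- **Default activation table.** Fixtures with the qualitative ordering of
  the findings (posterior deltoid back > front and barbell > machine,
  pectoralis major front > back, ascending > descending everywhere,
  upper trapezius flat) — explicitly not measured values, since the
  source figures are graphical.
- **Artifacts.** Mains: sinusoid at 50 Hz (configurable) with RMS equal
  to `amplitude` × trace RMS. Motion: < 10 Hz low-passed noise at the
  same relative RMS. Innervation zone: carrier attenuated to 40 % plus
  narrow-band 17–23 Hz noise, reproducing the amplitude loss and
  edge-shifted spectrum of an electrode over the innervation zone.
- **Seeding.** One master seed; every trial and model layer draws from a
  `SeedSequence` substream keyed by (layer, participant, muscle,
  trial/attempt), so identical (config, seed) pairs are bit-identical and
  adding trials never perturbs existing ones.

**What the generator does not emulate:** motor-unit recruitment and
firing statistics, fatigue (the protocol avoids it), nonstationarity
within a phase, cross-talk between channels, electrode impedance drift,
or any force/kinematics. Passing tests therefore demonstrate that the
pipeline recovers what it is defined to compute under the assumed signal
model — not that the model captures every property of real sEMG.

## Problem sizes in the test suite

Calibration suites run on the generator's statistical layer (activation
sampling) rather than re-synthesizing waveforms per replicate: the type-I
study uses 2000 simulated 8 × 8 tables, effect recovery 200 cohorts per
programmed δ ∈ {0.5, 1, 2}, QC discrimination 100 seeds per condition,
and waveform-level fidelity 50 full trials; the on-disk integration tests
use a reduced cohort (2 participants × 2 muscles) while in-memory
end-to-end tests use the full 8 × 6 design.

## Known limitations

- The z-based CI and uncorrected d are reproduced as conventions, with
  their small-n biases measured and documented, not corrected.
- QC thresholds quantify a visual criterion; they are surrogates chosen
  for separability on the signal model, not published cutoffs.
- EDF files can be read (via mne, if installed) but not written; CSV is
  the round-trip format.
- Phase boundaries are taken from the event table as given; no EMG-based
  onset detection is attempted.
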