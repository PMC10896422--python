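# Methods

This note documents the models, defaults and numerical choices behind
`dualtask-ef`, and what the synthetic-data validation does and does not
establish.

## Task protocol

Go-NoGo runs present `n_trials = 150` stimuli at a fixed inter-trial
interval (2.0 s at level 1, 1.3 s at level 2); run duration is defined as
`n_trials × interval` (each trial occupies its full interval), giving 300 s
and 195 s. N-Back runs present 75 letter stimuli at 1.5 s per trial
(112.5 s per run) with load N equal to the difficulty level.

Choices where the protocol is underdetermined:

- **Go/no-go ratio** — 30% no-go trials by default (configurable), the
  conventional proportion for inhibition tasks.
- **N-Back alphabet and match rate** — 8 consonant tokens, 30% match rate
  over the scorable trials (trials N … n−1), both configurable. Matches are
  placed exactly (rounded to the nearest trial), so the realised rate is
  always within 1/n of the configured one.
- **N-Back scoring window** — although 75 stimuli are presented, percent
  correct is normalised on a 44-trial window: the trials after the first N,
  truncated to 44. The window length is configurable.
- **Response windows** — a press logged for trial *i* counts for trial *i*;
  no latency modelling (reaction times are out of scope).

## EEG preprocessing

- **Bandpass** — 4th-order Butterworth, [0.5, 45] Hz, applied
  forward–backward (`sosfiltfilt`). Zero-phase filtering is the natural
  choice for offline analysis; the effective magnitude response is the
  squared design response (the effective order doubles).
- **Artifact removal** — a self-calibrated variance-threshold subspace
  cleaner. The recording is projected onto the eigenvectors of its channel
  covariance; per direction, sliding-window variances (window 0.5 s, 50%
  overlap) are summarised by median and MAD over the whole recording, and a
  window/direction pair whose variance exceeds
  `median + cutoff · 1.4826 · MAD` (cutoff 15) is zeroed before Hann
  overlap-add reconstruction. This is the discard-and-rebuild variant in
  which the threshold comes from the recording's own variance distribution;
  classical ASR instead calibrates on clean reference data, and a
  `calibration` argument exposes that behaviour, but self-calibration is
  the default. When nothing exceeds threshold the output equals the input
  exactly (fast path), which makes the infinite-cutoff identity and
  clean-limit idempotence testable.
- **Epoching** — one epoch per stimulus onset, with the epoch length equal
  to the trial duration (2.0 / 1.3 s Go-NoGo, 1.5 s N-Back). Fractional
  sample counts are floored so all epochs are equal length; onsets whose
  window overruns the recording are dropped and reported. Non-finite
  samples are a hard error, never interpolated.

## Band-power features

PSD is estimated per epoch by Welch's method (Hann, 50% overlap, segment
length `min(1 s, epoch)`). Band edges are half-open `[low, high)` at shared
boundaries, with gamma closed at 45 Hz, so delta, theta, alpha, beta and
gamma tile [1, 45] Hz without double-counting any frequency bin, and
low beta + high beta = beta holds to machine precision. Relative power uses
the broadband [1, 45] Hz integral as denominator, so the five canonical
bands sum to exactly 100%; the [0.5, 1) Hz residue of the filter band is
excluded. Per-epoch features are averaged arithmetically. The table has
exactly 8 × 7 × 2 = 112 feature columns.

## Gait metrics

- The **progression axis** is the principal horizontal direction of the
  heel marker's path (oriented along net displacement), which keeps stride
  length and step width well-defined on curved walkways.
- Stride time is the mean inter-heel-strike interval; cadence =
  120/stride time; stride length is the mean heel displacement along the
  progression axis between ipsilateral heel strikes; gait speed = stride
  length / stride time. Stance is (toe-off − heel strike)/cycle; double
  support is the sum of both double-support intervals per cycle (for
  alternating bilateral gait this is identically `2·stance − 1` of the
  cycle). Boundary cycles whose contralateral events fall outside the
  record are skipped in the double-support average.
- Joint angles are consumed as curves (inverse kinematics is the motion-lab
  vendor's job); curves are linearly resampled to 101 points over each gait
  cycle. GVS is the RMS deviation from a reference curve; GPS defaults to
  the RMS of the nine GVS values — the standard aggregation, under which
  nine equal scores g give GPS = g — with a plain-sum option for
  compatibility with summing conventions.
- The packaged healthy reference (`reference_curves`) is **synthetic**:
  smooth parametric shapes with plausible adult ranges, suitable as a fixed
  comparison point for testing and for relative comparisons between
  conditions. For clinical use a real normative dataset should be supplied.

## Statistics

- Screening ρ is the Spearman correlation of the three across-subject mean
  feature values against levels (1, 2, 3); with 3 points it is ±1 exactly
  when the means are strictly monotone. Per-subject ρ values are also
  reported (the single-subject confirmation tables). Note that the
  across-subject-mean screen is not invariant under nonlinear monotone
  transforms of the data (means do not commute with such transforms); the
  per-subject ranks, Friedman statistic and W are invariant.
- The Friedman test uses average-rank tie handling and the chi-square
  approximation with k − 1 degrees of freedom (scipy). A matrix whose every
  row is fully tied carries no rank information and is reported as
  χ² = 0, p = 1. Kendall's W = χ²/(n(k−1)), clipped to [0, 1]; classes:
  high ≥ 0.8, slightly high on the open interval (0.5, 0.8).
- Wilcoxon signed-rank (side symmetry) uses the exact distribution for
  ≤ 25 untied non-zero differences, the normal approximation otherwise;
  all-zero differences are degenerate and raise. The six condition
  comparisons use the unpaired Wilcoxon–Mann–Whitney test across subjects —
  deliberately unpaired, matching the original procedure even though the
  conditions are repeated measures; a paired alternative is available via
  `wilcoxon_signed_rank`.
- No multiple-testing correction is applied across the 112 features by
  default (fidelity to the original procedure); `benjamini_hochberg` is
  provided for sensitivity analyses.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not the biophysics:

- **EEG** = 1/f^1 background (10 µV RMS) + six band-limited Gaussian
  components (delta 6, theta 5, alpha 8, low beta 3, high beta 2.5, gamma
  1.5 µV RMS), each made by bandpass-filtering white noise with the
  package's own 4th-order Butterworth and normalised to its target RMS, so
  component variance equals the configured power exactly. Difficulty
  effects are per-(channel, band) amplitude factors over the three levels;
  the defaults mirror the two headline effects (delta up at Fz: 1.0, 1.3,
  1.6; high beta down at Fz: 1.0, 0.85, 0.7). Subject heterogeneity is a
  log-normal amplitude jitter (sd 0.2) per subject and band, constant
  across levels — it moves a subject's overall power without disturbing
  level trends. Walking adds 10 dB of broadband background gain,
  emulating the SNR degradation of ambulatory recording. Artifacts are
  Poisson bursts (2/min by default, 0.2–0.5 s, 20× channel RMS, 1–3
  channels).
- **Gait**: heel markers rest during stance (62% of the 1.1 s cycle) and
  advance one stride (1.25 m) during swing; the right side lags by half a
  cycle, so total double support is 24% by construction (the
  `double_support_fraction` field is validated against `2·stance − 1`,
  which alternating bilateral gait forces). Condition effects are additive
  stride-length deltas (−0.08 / −0.10 m under Go-NoGo) and
  foot-progression offsets (−4 / −5° under Go-NoGo, −3° under N-Back 2,
  negative = external rotation). Noise: 0.03 m cycle-to-cycle and 0.05 m
  between-subject stride variation, 1° curve noise.
- The device sampling rate defaults to 512 Hz (configurable); tests and the
  stochastic validations run at 128 Hz, which still resolves the 45 Hz band
  edge.

What passing the synthetic validations shows: the pipeline is internally
consistent (noise-free gait metrics close to 1e-6; component powers obey
Parseval), recovers injected monotone effects with the study's sample size,
and controls its false-positive rate under the null. What it does not show:
robustness to real-EEG phenomena the generator omits (eye blinks with
frontal topography, line noise, electrode drift, non-stationary rhythms,
volume-conduction correlations between channels) or to real gait
variability (asymmetry, turning strides on short walkways, marker
occlusion).

## Problem sizes

The stochastic validations use 13 subjects (the study's sample size), the
sitting setting, 26-trial Go-NoGo and 20-trial N-Back runs with a 40 s
baseline at 128 Hz, over 20 master seeds for the effect study and 20 for
the null study. These sizes keep per-subject feature estimates based on
≥ 20 epochs per condition, which is where the per-condition mean stabilises
in the generator; the full protocol sizes (150/75 trials, 512 Hz) remain
the defaults of `simulate_study`.
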