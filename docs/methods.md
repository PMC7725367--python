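# Methods

This note documents the models and procedures implemented in `usvkit`, the
defaults and why they were chosen, the numerical details that matter for
reproducibility, and the known limits of validating the chain on synthetic
data.

## Spectrograms

Audio is read from PCM RIFF WAV (16-bit integers scaled by 32768 so the
most negative code is exactly −1.0). The short-time Fourier transform uses
a 256-point FFT — the standard setting for 300 kHz mouse-ultrasound
recordings, giving 1.171875 kHz bins up to the 150 kHz Nyquist — with a
Hann window and 50% overlap (hop 128 samples ≈ 0.427 ms). The recording
literature rarely states window or overlap; Hann/50% is the common default
and makes the bin arithmetic exactly testable. Frames start at sample 0
without padding (`floor((n − fft)/hop) + 1` frames, center-timestamped),
and all intervals in the toolkit are half-open `[start, end)` seconds.

Magnitudes are in dB re digital full scale: scaling by 2/Σw makes a
full-scale sine read ~0 dB in its peak bin, so synthetic calls can be
planted at an exact dB level. Values are clipped at −120 dB. No microphone
calibration is attempted — like the field's detection tools, amplitudes are
relative, and only differences (SNR, +6.02 dB per amplitude doubling)
are meaningful.

## Detection

The detector is an explicit, testable pipeline with the user-facing
controls of automatic mouse-ultrasound detectors (adjustable minimum
duration; 0–9 quality score). It does not reproduce any proprietary
implementation bit-exactly.

1. **Noise floor**: per-frequency-bin median magnitude across all frames.
   The median is robust because vocalizations occupy a small fraction of a
   10-minute trial.
2. **Frequency track**: per frame, spectral *power* is first averaged over
   `smooth_frames = 9` adjacent frames (~3.8 ms). This is essential: the
   per-frame maximum over the ~100 in-band bins of raw Hann-windowed noise
   exceeds the median floor by ~8 dB routinely (extreme-value statistics
   of ~exponential bin powers), so without averaging the default threshold
   would fire on pure noise in most frames. Averaging shrinks the noise
   variance so an 8 dB exceedance becomes rare, while tonal calls persist
   across frames and keep their level. The in-band (20–140 kHz default)
   argmax bin is recorded iff it exceeds its own bin's floor by
   `snr_threshold_db = 8`. Because averaging smears a call's power about
   half a window past its true edges, the present-mask is then eroded by
   `smooth_frames // 2` frames per side, which restores the boundary of
   strong calls.
3. **Segmentation**: maximal runs of present frames, with internal gaps of
   at most `max_gap_ms = 5` bridged, then runs shorter than
   `min_duration_ms` (default 10 ms, lowerable to 5 ms to recover short
   calls at a higher false-positive risk) are discarded. The gap limit is
   deliberately below the 10 ms duration threshold so bridging cannot
   assemble threshold-passing elements from sub-threshold fragments alone.
4. **Quality score**: `round(9 · min(1, median_snr/30) · continuity)`,
   half-away-from-zero, clamped to 0–9, where continuity is the fraction
   of frames inside the element carrying a track point. The two factors
   target the two failure modes of a dubious element — faint and
   fragmentary; 30 dB is the saturation SNR (a clean, strong call).
   Scores ≥ 5 are treated as good quality.

Measured element length carries a small systematic bias: onset/offset
ramps put the outermost frames below threshold, so lengths read ~1 ms
short at 25 dB SNR (about ±2 frames). Tests budget for this.

## Features

Per element: length (ms) from the interval; unweighted mean of track
frequencies (kHz); mean of per-frame peak magnitudes (dB); and slope
(kHz/ms) as the OLS coefficient of frequency (kHz) on time (ms) over all
present track points. Elements with fewer than `min_track_points = 3`
points get missing track-derived features — the "too short or faint" case.
The slope is a one-number contour summary: a symmetric chevron regresses
to ~0 and must be interpreted with that in mind. Mean frequency is
unweighted (not amplitude-weighted) — the literal reading of "mean", and
the simplest. Latency to first vocalization is the earliest element start,
or the full trial duration (600 s default) when the animal was silent.

## Classification

Published repertoires use a human rater and a 15-type ultrasonic
vocabulary plus two sonic categories. `usvkit` substitutes a deterministic
decision list over measurable descriptors, applied in a fixed order so
every element gets exactly one label:

1. sonic split at exactly 20 kHz (mean track frequency): `squeak` with a
   harmonic, else `lfv`;
2. `uh` (ultra-high) at mean ≥ 90 kHz;
3. `us` under 5 ms; `s` under 12 ms with a simple contour;
4. jump classes by >10 kHz instantaneous steps (one up / one down /
   multiple);
5. `h` for harmonic stacks (secondary peak near 2× the fundamental at
   ≥ floor + 6 dB in ≥ 50% of frames);
6. `complex` at ≥ 2 direction changes (2 kHz hysteresis), `ch` (chevron)
   at exactly one;
7. `f`/`u`/`d` by frequency range (< 5 kHz = flat) and slope sign;
8. `uc` (unclassified) for anything unmeasurable or unmatched.

All thresholds are configurable (`ClassificationRules`). Ten of the 15
labels are freely renamable; `w` (wave) and `cm` (composite) exist in the
default vocabulary for compatibility with hand-labelled data but are not
produced by the default rules (waves fall under `complex`). This is a
surrogate, not a replication of any specific rater: on well-separated
synthetic types it is ≥ 90% accurate (tested), but agreement with human
labels on real recordings is unknown and the thresholds exist precisely so
users can align them.

## Detector evaluation

Event detection has no natural "negative event", so rates are computed at
the frame level: a frame is positive iff its center lies inside an
element. The ROC sweeps the quality-score cutoff from 9 down to 0 and is
anchored at (0,0) and (1,1); AUC is the trapezoidal area over FPR.
Element-level error counts use greedy one-to-one matching by temporal
intersection-over-union ≥ 0.5, largest overlap first. On the synthetic
benchmark (20 seeded recordings, 8 calls each of ≥ 15 ms at 20–30 dB SNR)
the default detector reaches recall 1.0, precision ≥ 0.95 and AUC ≥ 0.95;
this validates the pipeline's internal consistency, not its performance on
real, reverberant, artifact-laden recordings.

## Repertoire statistics

All composition statistics are implemented from first principles on the
Bray–Curtis dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) between per-type count
profiles (undefined for two silent animals; silent subjects are excluded
from composition analyses, matching standard practice).

- **ANOSIM**: R = (mean between-group rank − mean within-group rank) /
  (M/2), M = n(n−1)/2, mid-ranks for ties. R ≈ 0 under the null, → 1 for
  separated groups.
- **PERMANOVA**: pseudo-F from the partition SS_total = Σd²/n,
  SS_within = Σ_groups (Σ d² within)/n_g; F = (SS_between/(g−1)) /
  (SS_within/(n−g)). For 1-D Euclidean distances this equals the classical
  one-way ANOVA F (tested to 1e−9), and the statistic matches scikit-bio's
  implementation exactly (used as an independent cross-check only).
- **Permutation p-values** permute group labels with the add-one
  convention p = (1 + #{perm ≥ observed}) / (1 + n_perm); 999 permutations
  by default, seed mandatory. Permutations are vectorised (label matrix ×
  condensed rank/d² vectors), so hundreds of tests run in seconds.
- **nMDS**: Kruskal stress-1 minimised by SMACOF iterations (Guttman
  transform, unit weights) with isotonic-regression disparities, from 21
  random starts by default ("iterations" in the field's reporting usually
  means starts; both counts are exposed). Both the best-start stress
  (standard) and the mean over starts are returned. Convergence tolerance
  1e−7 on stress, max 300 iterations, distances clipped at 1e−12.
- **SIMPER**: contribution of type t to pair (x, y) is |xₜ−yₜ|/Σⱼ(xⱼ+yⱼ),
  averaged over all cross-group pairs; contributions sum exactly to the
  mean between-group Bray–Curtis. Types are ranked with a cumulative
  cutoff marked at 70%.

## Count models and model comparison

Counts per trial are fitted by log-link GLMs via statsmodels' IRLS, with
treatment contrasts (reference/control level on the intercept), so with a
single factor each coefficient is the log ratio of its group's mean to the
control mean — e.g. group means 50 and 142 give a treatment coefficient
ln(142/50) ≈ 1.04 regardless of dispersion. The negative-binomial size
parameter θ is estimated by profile maximum likelihood: a bounded 1-D
optimisation over log θ (range e⁻⁵–e¹², tolerance 1e−8), refitting the
GLM at each candidate. AICc = −2logL + 2k + 2k(k+1)/(n−k−1) counts θ as a
parameter (and both variance components for mixed models), so comparisons
are internally consistent; relative likelihood is exp(−½ΔAICc) with the
best model at 1. Wald z/t tests provide two-sided p-values; no post-hoc
corrections are applied.

Latency uses gaussian OLS. Repeated per-call measurements use a gaussian
random-intercept model (animal identity as the grouping factor) fitted by
maximum likelihood through statsmodels' MixedLM. Skewed responses such as
per-call length are intended to be log-transformed before the gaussian
fit; inverse-gaussian mixed models are deliberately not implemented — the
scientific use (direction and ranking of group contrasts) is preserved
while keeping the likelihood tractable and testable. Variability
differences are modelled Levene-style: |value − median| becomes the
response for the same machinery. Dispersion is Pearson χ²/df.

## Synthetic data

`make_recording` renders windowed FM sinusoids (flat, chirp, chevron,
jump, harmonic-stack; Tukey ramps against spectral splatter) into white
gaussian noise at a specified per-sample RMS (dBFS). The per-bin median
spectrogram floor of that noise has a closed form (Rayleigh median
σ·√(ln2·Σw²), scaled 2/Σw), so calls can be planted at an exact SNR above
the floor. Calls never overlap (single-caller setting, as in divided-cage
recording designs). Everything is seed-deterministic.

`simulate_study` draws the five-group priming design: groups 0d (unprimed
control) and 1/10/20/30 days post-priming, 10 males each. Per-mouse USV
counts are negative-binomial with control mean 50 and primed mean 142 —
the magnitude of priming effects reported for wild-derived mice — and
θ = 1.5, chosen so simulated NB fits show no overdispersion (Pearson
dispersion ≈ 1), consistent with published model diagnostics. Zero-count
mice can occur, as in the real study. Per-USV features: lengths lognormal
(log-sd 0.5) with means 14.93 ms (control) vs 32.5 ms (day 1; other
primed groups at control level, as only day 1 showed the length effect);
slopes gaussian (sd 0.6) at −0.16 (control) vs +0.16 kHz/ms (primed);
frequencies gaussian around 70 kHz with a 3 kHz per-animal random offset
and group sds of 12 kHz (control) vs 8 kHz (primed), the
narrower-after-priming pattern. Type composition shifts plant the
qualitative published pattern: controls emit more `uc` and fewer
`complex`; day-1 males more `uh`/`complex` and fewer `s`/`us`. Where the
literature gives no value (log-sd, slope sd, per-animal offset, exact
composition vectors) the defaults are one-time choices at realistic
magnitudes, stated here and not tuned thereafter.

What the generator does *not* emulate: reverberation and echoes, cage
noise and broadband artifacts, overlapping callers, amplitude modulation
within calls, the full diversity of natural syllable shapes, and
between-animal heterogeneity in everything except frequency. Passing the
synthetic benchmarks therefore demonstrates the correctness and internal
consistency of the chain, not field performance on real recordings.

## Problem sizes and determinism

The validation suite uses deliberately modest problem sizes — recordings
of a few seconds at 300 kHz, 20-recording detector benchmarks, 50-seed
recovery loops, 200-seed null calibrations with 199–999 permutations —
chosen so the whole suite completes in well under a minute of compute per
pillar while keeping Monte-Carlo error far from the asserted margins.
Every stochastic routine takes an explicit seed; permutation tests,
generators and the acceptance script are bit-reproducible for a fixed
seed.

## Known limitations

- Real-data results (a published detector AUC of 0.989 on its original
  annotated recordings; published ANOSIM/PERMANOVA values) cannot be
  reproduced here because the underlying audio and per-mouse tables are
  not available; the synthetic benchmark plays the role of a property
  check, and its AUC happens to land in the same range.
- No sub-bin frequency interpolation: track frequencies are quantised to
  1.17 kHz bins, which bounds mean-frequency accuracy to ~half a bin.
- The classifier is a rule-based surrogate for a human rater (see above).
- Frame-level FPR depends on the amount of silence in a recording;
  element-level precision/recall are reported alongside for that reason.
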