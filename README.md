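# usvkit

Detection, classification and statistical analysis of mouse ultrasonic
vocalizations (USVs).

Male house mice emit complex ultrasonic calls (> 20 kHz) during courtship,
and experiments on vocal behaviour — for example, testing whether a prior
encounter with a female raises a male's later calling rate — need a chain
of tools: find call elements in very-high-sample-rate recordings, measure
their spectro-temporal features, sort them into a syllable vocabulary,
score the detector itself, and compare per-animal counts and repertoires
across treatment groups. `usvkit` implements that whole chain as a tested
Python library with a thin command-line front end, plus a synthetic-data
generator so every stage can be exercised and validated without any real
audio.

## What it computes

- **Detection** (`usvkit.detect`): a spectrogram-based detector in the
  style of automatic mouse-ultrasound detection tools. Per-bin median
  noise floor, per-frame dominant-frequency track thresholded on SNR,
  run-merging into elements with an adjustable minimum duration (10 ms
  default, 5 ms to recover short calls), and an integer *quality score*
  0–9 per element (scores ≥ 5 = good quality), combining median SNR and
  track continuity.
- **Features** (`usvkit.features`): length (ms), mean frequency (kHz),
  mean amplitude (dB), and slope (kHz/ms) — the OLS regression coefficient
  of frequency on time over all points of the detected frequency track —
  plus latency-to-first-vocalization summaries.
- **Classification** (`usvkit.classify`): a deterministic, configurable
  rule table assigning each element one of 15 ultrasonic syllable types
  (complex, ultra-high `uh`, short `s`, ultra-short `us`, unclassified
  `uc`, plus shape/jump/harmonic types) or a sonic category (`lfv`,
  `squeak`) below the fixed 20 kHz cut.
- **Detector evaluation** (`usvkit.evaluate`): frame-level TPR/FPR,
  ROC over the quality-score sweep, trapezoidal AUC, and element-level
  error counts by greedy IoU matching.
- **Repertoire statistics** (`usvkit.repertoire`): diversity (number of
  types used, 0–15), Bray–Curtis dissimilarity
  d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), ANOSIM R, PERMANOVA pseudo-F (both with
  999-permutation p-values, add-one convention), non-metric MDS with
  Kruskal stress-1 over 21 random starts, and SIMPER contribution
  decomposition with the 70% cumulative cutoff.
- **Count models** (`usvkit.stats`): log-link Poisson and
  negative-binomial GLMs with treatment contrasts (control on the
  intercept, so coefficients are log group-mean ratios), gaussian OLS and
  random-intercept mixed models, AICc = −2logL + 2k + 2k(k+1)/(n−k−1),
  relative likelihoods exp(−½ΔAICc), Levene-style |x − median| variability
  responses, Spearman ρ, and Pearson χ²/df dispersion.
- **Synthesis** (`usvkit.synth`): FM call rendering into calibrated noise
  with ground-truth labels, and a five-group priming-study simulator
  (10 mice per group; negative-binomial counts with control mean 50 and
  primed mean 142; group-specific length/slope/frequency-spread and
  composition shifts).

## Worked example

```python
import numpy as np
from usvkit.synth import random_recording
from usvkit.detect import detect_file
from usvkit.evaluate import match_elements
from usvkit.features import feature_table

w, truth = random_recording(n_calls=8, snr_db=25, seed=3)
elements = detect_file(w)
print(len(elements), match_elements(elements, truth))
print(feature_table(elements)[["length_ms", "mean_freq_khz", "slope_khz_ms", "quality"]].round(2).head(3))
```

prints

```
8 (8, 0, 0)
   length_ms  mean_freq_khz  slope_khz_ms  quality
0      17.92          71.48          0.00        7
1      18.35          57.42          0.00        7
2      21.33          50.25          0.01        7
```

— all 8 planted calls detected with no false alarms or misses, each with
its measured features and a good-quality score (≥ 5).

Fitting the study-level count models to one simulated experiment:

```python
from usvkit.stats import DesignSpec, fit_count_glm
from usvkit.synth import StudyConfig, simulate_study

counts, usvs, truth = simulate_study(StudyConfig(seed=1))
y = counts["n_usv"].to_numpy(float)
treat = np.where(counts["group"] == "0d", "control", "primed")
fit = fit_count_glm(DesignSpec(y, treat, reference="control"), "negbin")
print(fit.coefficients.round(2).to_dict())
```

prints `{'(Intercept)': 3.58, 'primed': 1.34}` — the treatment coefficient
is the log ratio of primed to control mean counts (the generating value is
ln(142/50) ≈ 1.04; any one simulated study scatters around it).

The same flows are available from the shell:

```sh
usvkit synth --n-calls 10 --snr-db 25 --seed 7 --out rec.wav --truth rec.labels
usvkit detect rec.wav --min-dur-ms 5 --out det.labels
usvkit evaluate det.labels rec.labels --duration-s 2.5
usvkit pipeline rec.wav --out-dir out/
```

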