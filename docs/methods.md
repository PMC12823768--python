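# Methods

`bruxhmm` classifies 5-second, pre-segmented repetitions of simulated
orofacial movements into three classes — bruxism movement with tooth
contact (BMwTC: clenching, tapping, grinding), bruxism movement without
tooth contact (BMwoTC: bracing), and non-bruxism movement (non-BM:
swallowing, yawning, speaking, scratching, head/body motion, snoring) —
from six surface-EMG channels (bilateral masseter, bilateral
infrahyoid, chin, suprahyoid; 1000 Hz, 10–500 Hz acquisition band) and
one skin-conducted sound channel (44.1 kHz). This note documents the
models, the synthetic data that stands in for human recordings, and the
design choices that were genuinely open.

## Feature extraction

Each channel of a segment is reduced to mel-frequency cepstral
coefficients on 100 ms Hamming windows shifted by 50 ms: power
spectrum (FFT size = next power of two ≥ the window length: 128 for
EMG, 8192 for sound), triangular mel filterbank, natural log with a
floor of 1e-10, orthonormal DCT-II, keeping 13 coefficients including
the 0th (overall log-energy). Delta features — the 2-frame regression
slope, edge frames replicated — are appended by default, giving 26
dimensions per frame. A 5-s segment yields exactly 99 frames at both
sampling rates, so EMG and sound streams stay frame-synchronous, the
precondition for multi-stream fusion.

Parameter notes:

- **Mel filters**: 20 for the 0–500 Hz EMG band, 24 for sound — chosen
  so every triangle spans at least two FFT bins at the default FFT
  sizes. The filter count only needs to exceed the 13 kept
  coefficients.
- **Hum removal**: zero-phase second-order IIR notches at the mains
  frequency (default 60 Hz) and its harmonics up to the 8th, Q = 30 at
  the fundamental with the same 2 Hz absolute width at every harmonic.
  Constant absolute width matters: constant-Q notches widen with
  frequency and would remove tens of hertz of signal band.
- **No pre-emphasis, no liftering, no cepstral mean normalization** —
  these are speech-recognition conventions with no counterpart in this
  recording chain; pre-emphasis exists as an off-by-default option.
- The 13-static + 13-delta reading of the feature set is the default;
  `append_delta=False` gives the 13-dimensional static variant, and
  both are exercised in the tests.

## Classification model

Each class is modelled by a 3-state left-to-right hidden Markov model:
entry in state 1, each state may repeat or advance, an optional
non-emitting exit is reachable from the last state but is not enforced
at decode time by default (`require_exit=False`; segments may end in
any state, and both variants are available). Emissions are 10-component
diagonal-covariance Gaussian mixtures per state and per stream.
Diagonal covariances are a deliberate choice: full 26×26 covariances
for 30 components on minutes of data would be near-singular.

A multi-stream model keeps one mixture set per stream per state and
fuses streams state-synchronously: the frame log-likelihood is the
weighted sum of per-stream mixture log-densities, with unit weights by
default and no weight training. With weights (1, 0) on duplicated
streams this reduces exactly to the single-stream score, which the
tests assert to 1e-12.

All probability arithmetic is in the natural-log domain with
log-sum-exp. Training is Baum-Welch EM with the left-to-right zero
pattern preserved, a mixture-weight floor of 1e-5 and a variance floor
of 1e-3 × the pooled per-dimension variance enforced after every
M-step; the E-step is vectorized across sequences of equal length.
Initialization splits every sequence into three contiguous blocks and
runs k-means (k-means++, fixed seed, frames sorted canonically so the
result is independent of training-set order) on the pooled block
frames; transitions start at self 0.6 / advance 0.4. Stopping: 20
iterations or relative improvement < 1e-4, whichever comes first (the
synthetic corpus typically converges in 6–8 iterations).

Classification assigns a segment to the class with the highest Viterbi
log score (best-path likelihood); the forward (sum-over-paths) score is
available behind a flag. Ties break deterministically in the order
BMwTC, BMwoTC, non-BM. Scores are not length-normalized — every
segment is 99 frames at the defaults, so normalization would be a
no-op; a per-frame option exists for variable-length inputs.

## Evaluation

Leave-one-subject-out: each subject serves once as the test set while
the three models train on all other subjects' segments, each class
model pooling every segment of its class (with 12 subjects: 165 BMwTC,
55 BMwoTC, 330 non-BM training segments per fold). Per fold, the 3×3
confusion matrix yields one-vs-rest sensitivity, specificity, PPV, NPV
and the F-value (harmonic mean of PPV and sensitivity) per class.
Undefined 0/0 ratios are reported as 0 with an explicit flag and still
enter the averages — conservative and visible rather than silently
dropped. Study summaries are means ± sample SD (ddof = 1) over folds,
weighting every subject equally rather than pooling counts.

F-values are compared across stream sets with a one-way fixed-effects
ANOVA on the 12 per-subject values per set, followed by Tukey's HSD
(studentized-range distribution, pooled within-group variance,
Tukey–Kramer SE for unequal sizes), α = 0.05 — run separately for the
seven single-channel sets and the five multi-stream sets. Both
statistics are implemented in the package (scipy supplies only the F
and studentized-range distributions) and are validated against
`scipy.stats.f_oneway` and `scipy.stats.tukey_hsd` in the tests.

## Synthetic data generator

No public recordings exist for this protocol, so the generator is a
first-class, tested component that emulates the acquisition: 12
subjects, 10 tasks × 5 repetitions of 5 s (5 s between repetitions,
30 s between tasks), EMG at 1000 Hz band-limited to 10–500 Hz by a
4th-order zero-phase Butterworth stage, then contaminated with mains
hum (fundamental + odd harmonics, 1/k roll-off, per-subject amplitude
0.01–0.05 a.u.); sound synthesized directly at 44.1 kHz over a uniform
noise floor (RMS 0.003 a.u.). Output is one CSV per EMG channel, one
mono PCM16 WAV, and a JSON manifest of half-open sample windows;
identical configurations produce byte-identical datasets (every random
draw is keyed by master seed, subject, task, repetition and channel).

EMG is Gaussian noise shaped by a per-task band-pass filter and an
amplitude envelope (sustained ramps, 2 Hz burst trains, single bursts,
or low-pass-modulated irregular activity) — no motor-unit simulation,
because the MFCC/HMM pipeline only sees spectral-temporal envelopes.
Inter-subject variability: lognormal gain (σ = 0.3), uniform ±10%
spectral shift, uniform hum level. Within-subject variability: a shared
per-repetition effort jitter (lognormal σ = 0.25) plus independent
per-channel jitter (σ = 0.10).

The paper-level structure the generator encodes, since no amplitude or
SNR values are published for any task:

- **Bracing shadows clenching.** Identical masseter band, level 0.70
  vs 1.00 (a gap comparable to the effort jitter), identical
  infrahyoid levels; the systematic cues are stronger suprahyoid
  co-activation (0.70 vs 0.55) and the faint tooth-contact creaks that
  clenching — but not bracing — leaves on the sound channel. This makes
  BMwoTC the hardest class in every stream set — the study's central
  qualitative finding. A practical lesson baked into these choices:
  band-shape differences are nearly deterministic cues for cepstral
  features, so confusable tasks must share bands exactly and differ
  only in level.
- **Masseter is the informative channel** for tooth-contact bruxism:
  clenching/tapping/grinding all run at 0.7–1.0 a.u. there against a
  0.02 resting floor, with tapping's 2 Hz burst train and grinding's
  higher band (165 ± 95 Hz) as reliable signatures.
- **Infrahyoid is a low-SNR site** (levels ≤ 0.2 for every task),
  reproducing its poor standing in the reference results.
- **Sound carries tooth contact**: loud click trains for tapping,
  friction noise for grinding, faint low-rate creaks for clenching,
  gulp/speech/snore events for the corresponding non-BM tasks, and
  silence for bracing.
- The `separability` knob (default 1.0) pulls all task levels
  log-linearly toward a common anchor, shrinking between-class
  contrast monotonically for sensitivity analyses.

What the generator does **not** emulate — and hence what passing tests
do and do not show: real motor-unit statistics, electrode artefacts
beyond mains hum, sleep-stage structure, unsegmented continuous
recordings (onsets are known from the manifest, matching the per-event
analysis), and the acoustic richness of real snoring or speech. Results
on this corpus validate the pipeline's mechanics and qualitative
orderings, not clinical performance on human data.

## Problem sizes and reproducibility

The default study — 12 subjects, all 12 stream sets, full LOSO —
trains 432 GMM-HMMs and takes roughly 15 minutes on one CPU;
the examples use 2–4 subjects for minute-scale runs. Every entry point
(generator, initialization, study) takes an explicit seed, and
identical seeds reproduce identical reports. `scripts/acceptance.py`
re-runs the default study from scratch for any seed and writes the
headline quantities as JSON.

## Known limitations

- The BMwoTC class trains on a single task (bracing, 55 segments per
  fold), so its model is much tighter than the pooled BMwTC/non-BM
  models; on channels where bracing and clenching coincide this
  asymmetry attracts clenching segments to the BMwoTC model — visible
  in the confusion matrices, and consistent with the class's low
  F-values.
- Stream weights are fixed at 1; no discriminative or weight training.
- No continuous decoding: the unit of classification is a pre-cut 5-s
  segment.
- EDF input is not supported; CSV/WAV are the interchange formats.
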