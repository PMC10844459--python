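# Methods

`hdspeech` re-implements a digital speech-assessment pipeline for
Huntington disease (HD): acoustic, timing and intelligibility features are
extracted from three timed speech tasks (reading the first paragraph of the
Rainbow Passage, counting forward 1–20, counting backward 50→30 in steps of
3), compared across HD / prodromal HD (pHD) / control groups, correlated
with clinical scales, and fed to leave-one-subject-out (LOSO) random-forest
models. This note records the model, the defaults and why, what the
synthetic data emulate, and the numerical choices made where the design was
open.

## Input contract

The pipeline consumes *timed transcripts* — ordered word tokens with
start/end times in seconds — produced by any external ASR or forced
aligner, plus optionally the raw mono PCM WAV. Re-implementing a speech
recognizer is out of scope: the word timestamps are the source of truth for
all timing features, and any aligner emitting `{text, start, end}` JSON is
acceptable. Token normalization lower-cases, strips characters outside a–z,
removes apostrophes and splits hyphenated words; it is idempotent.

## Timing features

Voiced intervals are the (merged) word spans; the signal is the interval
from the first word onset to the last word offset, so recording time
outside it never influences any feature. Total pause time is total signal
minus total voiced time, which makes the conservation identity
`voiced + pause = signal` exact by construction. The speech-to-pause ratio
is voiced/pause (reported missing, not infinite, when there is no pause),
and the articulatory rate is words per second of *voiced* time.

Only gaps of at least `min_pause_s` count toward the number of pauses and
the mean pause length; shorter gaps are treated as within-speech
articulation but still contribute to total pause time. The default
`min_pause_s = 0.10 s` was chosen because the published control-group
summaries are *nearly but not exactly* consistent with
`mean pause ≈ total pause / number of pauses` (6.01 / 22.5 ≈ 0.27 vs a
printed 0.26), implying some small threshold whose exact value the source
does not state; it is a config knob. A 40 s task-limit truncation option
exists and is off by default.

## Acoustics

**Pitch.** Frame-wise F0 by normalized autocorrelation (NCCF): frames of
40 ms with 10 ms hop, lag search over 60–400 Hz, voicing decided by a 0.45
threshold on the normalized peak plus an absolute energy floor (RMS 1e-4 of
full scale). The frame length gives ≥ 2.4 periods at the 60 Hz search
floor. For periodic signals the NCCF is near-equal at the period and its
multiples, so the tracker picks the smallest-lag local maximum within 90%
of the global peak (avoiding octave-down errors) and refines the lag by
parabolic interpolation. Pitch mean and sample SD (n−1) are taken over
voiced frames whose centers fall inside voiced intervals; fewer than two
qualifying frames yields missing values. Synthetic harmonic tones at
80–300 Hz are recovered well within 2% (measured ≤ 0.02%).

**Loudness.** Per frame, the Hann-windowed amplitude spectrum is grouped
into the 24 critical bands of the Bark scale (Traunmüller's formula,
`z = 26.81 f / (1960 + f) − 0.53`); the RMS magnitude per band is summed
across bands and the sum mapped to a sone-like scale by the fixed monotone
power law `(p / 2e-5) ** 0.6`. Two points are deliberate design decisions
rather than inferences: (a) whether the band sum happens before or after
the loudness transform is ambiguous in the source description, so the
band-RMS sum is transformed once per frame, and (b) absolute calibration is
arbitrary — a bare waveform carries no SPL reference — so only relative
comparisons between recordings made under one setup are supported. The
summary is the mean over frames inside voiced intervals; silence maps to 0
and the measure is strictly monotone in overall gain (verified over
40 dB).

## Intelligibility and reading accuracy

Normalized text is encoded letter-wise (a=1 … z=26, inter-word space=0; the
table is swappable) and compared by classic dynamic time warping: local
cost |Δcode|, steps (1,0)/(0,1)/(1,1), full-path sum. The similarity score
is `1 / (1 + DTW distance)`, so identical encodings score exactly 1. The
step pattern and cost are validated against brute-force enumeration of all
monotone warping paths rather than against any published constant. The
intelligibility score applies the same similarity to transcripts of one
recording from a higher-capacity ("medium") and a lower-capacity ("small")
recognizer; under the synthetic corruption channel its expectation is
strictly decreasing in the channel's error rate.

Word-level accuracy uses a minimum-edit alignment with indel cost 1 and
substitution cost 2, making matches exactly the longest common
subsequence; a substitution therefore decomposes into one extra plus one
missing word, matching the two reported features. Both the extra-word and
missing-word ratios are normalized by the reference length (the reference
is the bounded, comparable denominator; the missing ratio then lies in
[0,1]).

## Counting tasks

Number words (including compound tens+ones forms and digit strings; an
internal English lexicon covering 0–99) are parsed from the transcript;
non-number chatter is dropped. Scoring uses a *chain rule*: the first value
is correct iff it equals the task start (1 or 50) and each later value iff
it equals the previously spoken value plus the step (+1 / −3).
Participants were instructed to keep counting after mistakes, so the chain
rule forgives an isolated slip instead of cascading it; position-wise
scoring against the canonical sequence is available via `canonical=True`.
Values beyond the nominal stop (below 30 backward) are still chain-scored,
not penalized. Counts per second divides by total signal time; the
articulatory rate inside the counting timing block divides by voiced time,
as in the passage task. Timing features are computed on the number tokens
only.

## Cohort statistics

Pairwise group contrasts use the two-sided independent two-sample t-test
with pooled variance and Cohen's d on the pooled (n−1 weighted) SD —
pooled rather than Welch because the published effect sizes are reproduced
exactly by the pooled form. No multiplicity correction is applied by
default, mirroring the exploratory design; Benjamini–Hochberg is available
behind a flag. Correlations are Pearson for MoCA and the UHDRS functional
and motor scales, Spearman for the ordinal 0–4 dysarthria score. When
subjects contribute several visits the default analysis unit is the visit.

For simulation-recovery studies the package provides a bias-corrected
sample d (`sample_cohens_d(..., debias=True)`): the raw sample d
overestimates |d| in small groups, and the Hedges factor is evaluated at
the Satterthwaite effective degrees of freedom because group variances here
differ by an order of magnitude, where the pooled-df factor under-corrects.

## Prediction models

LOSO cross-validation holds out every visit of one subject per fold; a
hard invariant (asserted in tests) is zero subject overlap between train
and test. The classifier is a random forest with balanced class weights,
500 trees by default (stability at n = 36; tree count is configurable and
smaller forests are used in some simulation studies for runtime), fixed
seed. Out-of-fold predictions are pooled before computing metrics:
weighted (overall) accuracy, balanced accuracy (mean per-class recall),
per-class recall, confusion matrix, and macro-averaged one-vs-rest AUC
from pooled class probabilities (the averaging convention is not stated in
the source; macro OvR was chosen and both accuracy variants are reported).
Missing features are imputed with the training fold's median. Regressors
target the four clinical scores and report MSE, MAE and explained variance
`1 − var(residual)/var(target)` on pooled out-of-fold predictions.
Impurity-based feature importances are averaged across folds. The default
feature selection feeding the models is "any nominally significant
contrast (p < 0.05) in the analyzed cohort".

## Synthetic data

The generator defines the study conditions: group sizes 18 HD / 7 pHD /
11 control, one visit per subject by default, and per-group feature means
and SDs fixed at the published passage-reading summaries (counting-task
summaries are published for HD and control only; prodromal defaults sit
midway, consistent with the observed intermediate phenotype).

Bounded features are drawn from *moment-matched* truncated normals: the
underlying (μ, σ) are solved numerically so that the post-truncation mean
and SD equal the targets. This matters for near-zero features (control
extra-word ratio 0.01 ± 0.02), where naive truncation visibly shifts the
moments. A lower-truncated normal cannot have SD exceeding its mean
distance from the bound, so such infeasible targets are matched in mean
with the SD capped at 95% of the attainable limit. Upper bounds (e.g.
similarity ≤ 1) are deliberately not enforced: the published control
similarity summary (0.92 ± 0.14) is incompatible with any [0,1]-supported
truncated normal, so enforcing the bound would falsify the moments the
generator exists to reproduce; synthetic similarity values can slightly
exceed 1.

A per-subject latent severity factor z links features to clinical scores
through a Gaussian copula: features load on z with weight ρ = 0.5 (signed
by each feature's direction of worsening, inferred from the HD-vs-control
means) and clinical scores with weight α = 0.8 around the published
per-group clinical means/SDs. HD dysarthria scores are assigned by severity
quantile with cut fractions 1/18 and 13/18, reproducing the published
0/1/2 strata (1, 12 and 5 of 18 HD participants; mean 1.22); pHD and
controls are 0. Features are conditionally independent given z — no
empirical cross-feature covariance is available — so synthetic
classification and regression metrics are *calibration bounds* for the
pipeline, not reproductions of the clinical results: passing them shows
the machinery recovers planted structure at the published effect sizes,
not that real cohort performance would match.

Synthetic recordings render a harmonic pulse train (1/k harmonic rolloff,
10 ms Hann ramps) at a known F0 inside known word spans with optional
noise floor, so the extractors can be checked against planted ground
truth. The ASR-error channel corrupts each word independently with the
given probability: letter substitution (1/2), deletion (1/4), or
duplication into two perturbed copies (1/4); at rate 1 no word survives
unchanged.

## Problem sizes and determinism

Simulation studies use 200 cohort replicates for effect-size recovery,
10 seeded cohorts for classification summaries, 20 label permutations for
the null calibration (100-tree forests there), 1,000 random segmentations
for the timing invariants, and 20 frequencies × 3 gains for pitch
recovery. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give identical cohorts,
fold assignments and model reports.

## Known limitations

- Absolute loudness values are not comparable across recording setups, and
  the sone calibration is arbitrary by construction.
- The letter-code table and DTW step pattern are reproducible choices, not
  published constants; different choices would rescale similarity values.
- The pause-count threshold cannot be pinned down from the published
  summaries; it defaults to 0.10 s.
- Real-cohort results (correlation coefficients, regression errors, the
  73% balanced accuracy / 0.92 AUC) require the study's unreleased
  recordings; the synthetic analyses bound and calibrate, but do not
  reproduce, them.
- Number parsing is English-only and covers 0–99.
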