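# Methods

## Feature model

An epoch is a channels × samples matrix at sampling rate `fs` (µV). Per
channel, the power spectral density is estimated by Welch's method: Hamming
taper of 128 samples, 50% overlap, per-segment mean removal, one-sided
density normalisation (so integrated PSD × bin width recovers the variance
of a zero-mean stationary signal to within a fraction of a percent — the
Parseval check in the test suite allows 5%). Band power is the **mean** of
the PSD bins inside each half-open interval `[low, high)`:

| band | Hz |
|---|---|
| θ | 4–8 |
| slow α | 8–10 |
| α | 8–12 |
| β | 12–30 |
| γ | 30–`gamma_upper` |

The slow-α/α overlap on 8–10 Hz is kept deliberately: both are standard
reporting bands. γ is open-ended in the literature (">30 Hz"); the default
upper edge of 45 Hz stays below 50/60 Hz mains interference and below the
Nyquist frequency of a 128 Hz consumer headset. It is configurable, as is
an optional log10 transform of band powers (default off: the pipeline is
defined on the linear scale).

Asymmetry features are right-minus-left band-power differences over the
montage's symmetric electrode pairs. Built-in montages: the 32-channel
Biosemi cap (14 lateral pairs, midline Fz/Cz/Pz/Oz excluded) giving
32×5 + 14×5 = 230 features, and the 14-channel Emotiv EPOC headset
(7 pairs) giving 105. Pairings are the standard left/right mirror images
of the 10–20 names and can be overridden via a YAML montage file. One
feature row per whole trial; no sub-windowing.

## Transforms and their contracts

* **Median binarization** (the subject-based normalisation under study):
  bit k is 1 iff the feature strictly exceeds the subject's per-feature
  median; ties map to 0. The median uses the midpoint convention for even
  row counts. Profiles are fitted from feature rows only — never labels —
  so a test subject's profile can be computed from unlabeled data as soon
  as recordings exist, and refined progressively.
* **z-score**: mean and sd (sample convention, ddof = 1; the population
  convention differs negligibly at realistic n) fitted on training rows
  only. Zero-sd features map to 0 rather than raising: degenerate but
  reachable on binary inputs, and a hard error would make pipelines
  non-composable.
* **max-min**: per-subject linear map of each feature to [0, 1]; values
  outside the fitted range are clipped, constant features map to 0.

The key analytic property, verified bitwise by property tests: binarization
is invariant to any strictly increasing per-feature, per-subject map of the
raw features, while both affine transforms are only affine-equivariant.

## Evaluation protocols

Balancing first draws exactly `k` trials per class per subject (uniform,
without replacement, seeded); subjects whose minority class has fewer than
`k` trials are discarded. `suggest_k` picks the largest `k` that discards
at most a configurable fraction of subjects (default 25%) — the trade-off
between populated training sets and retained subjects has no canonical
rule, so the budget is explicit.

* **LOSO**: every subject is held out in turn; per repetition (default 20)
  a fresh uniform draw of 90% of the *other* subjects' rows (unstratified —
  nothing more specific is warranted) forms the training set. Transforms
  are fitted per their contracts on that split; the classifier is scored on
  all held-out rows. All compared methods see the identical split, so the
  resulting records are paired: n_subjects × reps comparisons per
  classifier (24 × 20 = 480, 16 × 20 = 320).
* **Intra-subject**: per repetition (default 100), one positive and one
  negative trial of the subject form the test set, the subject's remaining
  trials the training set — 2 × m × reps judgments; chance is exactly 0.5.
* **Scalability**: for each test subject and each p, a random set of p
  other subjects (one draw, shared across methods) supplies all its rows
  for training; reported accuracy is the mean over test subjects.

Classifiers are delegated to scikit-learn behind a fixed contract
(`svm_cubic` = degree-3 polynomial SVC, `svm_rbf` = Gaussian SVC,
`naive_bayes` = GaussianNB), hyperparameters at library defaults, recorded
in the run manifest. A training matrix whose every feature is constant
carries no information; naive Bayes then returns the majority training
class instead of dividing by a zero variance floor.

## Friedman rank comparison

Within each paired comparison, methods are ranked by accuracy descending
(rank 1 = best; ties averaged). The tie-corrected χ² statistic

    χ² = (k−1) · (Σ_j R_j² − N²k(k+1)²/4) / (Σ_ij r_ij² − Nk(k+1)²/4)

is referred to χ²(k−1); all-tied data yield statistic 0, p = 1. The
Iman–Davenport F correction is available as an option (default off). The
module implements the statistic directly because the central comparison
has k = 2 methods, which general-purpose routines refuse; the test suite
cross-checks against scipy at k = 3 and against an exact binomial sign
test at k = 2. For the sign-test comparison the mid-p tail is the exact
counterpart of the uncorrected χ² (the plain exact tail differs by the
continuity half-step, ≈10% relative at N of a few hundred).

## Synthetic study conditions

`generate_feature_space` draws each row as

    distort_s( b_s + y·δ·e + ε )

with per-subject baseline `b_s ~ N(0, σ_subj² I)`, class `y ∈ {0,1}`
(balanced by construction), a fixed sparse ±1 pattern `e` on a fraction of
emotion-responsive features, noise `ε ~ N(0, σ_noise² I)`, and a strictly
increasing per-subject per-feature distortion (identity, sign-preserving
power `sign(x)|x|^a`, or logistic; power is the default — logistic
saturates numerically under large baselines). Defaults: 24 subjects,
16 trials per class, 50 features, σ_subj/σ_noise = 10, δ/σ_noise = 1,
responsive fraction 0.5 — the subject-dominant regime observed in the
public affect databases (24 retained subjects × 32 balanced trials is the
balanced valence protocol of the largest of them). The effect is injected
*before* the distortion: that is exactly the mechanism a
monotone-invariant transform can undo and an affine one cannot, which is
the hypothesis under test.

What the generator does **not** emulate: 1/f spectra, volume conduction,
artifacts, label noise, or any genuinely shared emotion–EEG patterns
beyond one linear effect direction. Passing benchmarks therefore
demonstrate that the pipeline recovers a subject-masked effect under
monotone per-subject distortions — not that any particular accuracy is
attainable on real recordings.

`generate_signals` sums one sinusoid per band (6, 9, 10.5, 21, 37 Hz —
single representative frequencies keep band powers closed-form checkable)
with per-subject amplitudes, random phases and white noise.

## Benchmark scale and pilot

A pilot simulation at the default conditions (naive Bayes, 2 repetitions
per held-out subject, 10 generator seeds) gave LOSO accuracy 0.514 ± 0.007
for z-score and 0.974 ± 0.004 for binarization; the ≥ 0.1 margin asserted
by the benchmark test is fixed by that pilot, with the z-score chance band
set at ±0.05 (conservative relative to the binomial error of ~240
effective subject draws). The acceptance script uses the same scale
(10 runs × 2 reps averaged; one full 20-rep run for the 480-comparison
Friedman cell); the suite and the script each complete in well under a
minute on one CPU. The scalability trend is asserted as a positive
Spearman correlation over p ∈ {1, 3, 5, 9, 15, 23}.

## Numerical choices and limitations

* Band bins are selected half-open; a band with zero bins in the frequency
  grid is an error naming the band and the grid resolution.
* Binarization ties (equality with the median) map to 0 — over a subject's
  own fitted rows each bit's mean lies in [(n−1)/(2n), 1/2].
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical tables,
  records and curves.
* Labels enter the pipeline only at classifier training and scoring;
  transform fits receive feature matrices only, enforced by interface.
* t-SNE scatter plots (`plot-embedding`) delegate to scikit-learn and are
  a visual aid outside the tested core.
* Binary valence/arousal only; multi-class labels, artifact handling,
  re-referencing, filtering and loaders for proprietary database formats
  are out of scope.
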