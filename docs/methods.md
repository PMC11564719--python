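# Methods

This note documents the models and procedures implemented in `bwhpat`, the
conventions fixed where the method leaves choices open, and what the synthetic
benchmark does and does not demonstrate.

## The black-white hole pattern (BWHPat)

BWHPat is a windowed 1-D textural descriptor. Every overlapping 69-sample
window `bl` of a signal is laid out as five regions inspired by a black-hole /
white-hole sketch:

| region | samples (1-based) | shape | center |
|---|---|---|---|
| black hole `b` | 1–25 | 5×5 | `Cb = b(3,3)` |
| its event horizon `eb` | 26–34 | 3×3 | `cb = eb(2,2)` |
| singularity `C` | 35 | 1×1 | — |
| white-hole horizon `ew` | 36–44 | 3×3 | `cw = ew(2,2)` |
| white hole `w` | 45–69 | 5×5 | `Cw = w(3,3)` |

Fourteen candidate binary patterns compare eight cells of one region against a
reference: patterns 1–4 compare each matrix against its own center, 5–8
against the singularity, 9 pairs `b` with `w`, 10 pairs the two horizons, and
11–14 pair holes with horizons. The comparison kernel is the signum step
`x >= c -> 1`.

For each window the descriptor *selects* one of the 14 patterns: each pattern
has an associated statistic group (its participating region(s), with the
singularity appended for 5–8 and both regions concatenated for 9–14), and the
pattern whose group `(mean, sample std)` lies closest — Euclidean distance in
that plane — to the whole-signal `(mean, sample std)` wins. The eight selected
bits are packed MSB-first into a byte (`sum BF(z) * 2^(8-z)`, range 0–255);
the byte stream over all `lng − 68` windows is the *map signal*, and its
256-bin count histogram is the feature vector.

Conventions fixed here:

- **Matrix fill** is row-major (`b(a,c) = vb((a−1)·5+c)`), the conventional
  raster order.
- **The eight compared cells of a 5×5 matrix** are the outer-ring corners and
  edge midpoints in row-major order — (1,1),(1,3),(1,5),(3,1),(3,5),(5,1),
  (5,3),(5,5) — symmetric about the center and consistent with the 3×3 case,
  whose eight cells are the non-center cells in row-major order. The choice is
  isolated in one table (`_PATTERN_OPERANDS`) so it can be swapped.
- **Whole-signal statistics are computed once per input series** (they are
  normalizing constants of the selection), group statistics per window;
  selection is per window. Standard deviations use the n−1 denominator.
- **Ties** in the distance argmin resolve to the lowest pattern index,
  deterministically.
- **Histograms are raw counts** (segments within a case share their length,
  so counts are comparable); a `normalize=True` flag divides by the window
  count.
- **Inputs shorter than 69 samples** yield an all-zero histogram plus a
  warning rather than an error, so short wavelet subbands cannot crash the
  pipeline.

The numpy reference path and a fused numba kernel implement identical float64
arithmetic; a test asserts bit-identical map signals between the two.

## Tunable Q-factor wavelet transform

The multilevel front end is a frequency-domain two-channel filter bank
iterated J times on the lowpass branch, parameterized by quality factor Q,
redundancy r and levels J (defaults 1, 3, 9 → 10 subbands). With
β = 2/(Q+1) and α = 1 − β/r, level j outputs a lowpass of
2·round(αʲN/2) samples and a highpass of 2·round(βαʲ⁻¹N/2) samples; the
transition bands use the Daubechies-type function
θ(ω) = ½(1+cos ω)√(2−cos ω), which satisfies θ(ω)² + θ(π−ω)² = 1, so
analysis followed by synthesis is exact to floating-point rounding (measured
max error ~1e−15; the acceptance bound is 1e−8). Odd-length inputs are
zero-padded by one sample and the pad dropped on reconstruction. Signals too
short for the requested depth raise an error naming the failing level.

## Feature extraction

Each input series (the raw segment plus its 10 subbands) contributes a
270-vector: the 256 BWHPat bins followed by 14 statistical moments, in the
order Tsallis entropy, Shannon entropy, Renyi entropy, Sure entropy,
log-energy entropy, energy, Higuchi fractal dimension, standard deviation,
variance, range, mean, median, minimum, maximum. The 11 vectors are
concatenated raw-first into a 2970-feature row per segment.

The entropy conventions (open upstream) are fixed in `MomentConfig`:
probabilities are energy-normalized (p_i = x_i²/Σx²) with 0·log 0 := 0;
Renyi order 2; Tsallis order 2 ((1−Σp²)/(q−1)); Sure entropy
Σ min(x_i², τ²) with τ = 2; log-energy entropy Σ log(x_i² + ε) with
ε = 1e−12; Higuchi uses k_max = 10 and the least-squares slope of
log L(k) against log(1/k). A classic 1-D LBP (9-sample window, eight
neighbors signum-compared to the center, MSB-first code, 256-bin histogram)
is provided as the ablation baseline.

## Feature selection (INCA)

NCA learns one nonnegative relevance weight per feature by maximizing the
expected leave-one-out accuracy of a soft nearest-neighbor rule under the
weighted city-block metric d_w(i,j) = Σ_r w_r²|x_ir − x_jr|, with L2 penalty
λ = 1/n. Numerical choices: features are z-scored first; soft-neighbor
probabilities use a stable softmax; distances are divided by their mean at
initialization (a fixed length scale) so the exponentials stay responsive at
any dimensionality; weights start at 1. The optimizer is a deterministic
full-batch gradient ascent run for ⌈n/2⌉ iterations (the iteration budget
scales with the number of segments). A stochastic per-sample optimizer would
add a randomness source and, at 2970 features, orders of magnitude of cost
without changing how the weights are used (ranking only). Features are ranked
by descending w².

INCA then scores every nested subset of the top-x ranked features for
x = 50..500 (a 451-point loss curve) by stratified 10-fold CV
misclassification of the 1-NN/L1 classifier, standardizing inside each fold
with training statistics. One fold assignment (derived from the run seed) is
shared across all 451 sizes so the curve is comparable point to point; nested
subsets are evaluated incrementally (cumulative per-feature distance sums),
which makes the curve cheap. The minimum-loss subset wins; ties resolve
toward fewer features. Re-evaluating the winning subset with the
classification module under the same fold seed reproduces the stored minimum
loss exactly (tested).

Note the selection protocol mirrors the study design: the NCA ranking sees
*all* segments, and the winning size is the minimum over 451 evaluations on
one fold assignment. Both are optimistic-selection steps outside any outer
CV; consequences are discussed under Limitations.

## Classification and metrics

1-nearest-neighbor with city-block distance, no weighting, features z-scored
per fold from training statistics, stratified 10-fold CV (`knn_cv`) or
leave-one-subject-out folds (`loso_cv`). Nearest-neighbor ties resolve to the
lowest training index; k > 1 majority votes with ties to the smallest label.
Accuracy is the fraction of correct held-out predictions (trace of the
confusion table over its total). F1 is one-vs-rest 2tp/(2tp+fp+fn) per class,
macro-averaged — the three-class report needs one number per channel and the
binary formula does not disambiguate averaging; macro is chosen and labeled.

## Cortex map

Per case, the 24 channel accuracies are summarized by their median (even
count → mean of the middle pair); channels *strictly* above the median are
that case's meaningful channels (so at most 12 of 24; equality is skipped,
and all-equal accuracies give an empty set). The intersection of the three
per-case sets is the ultimate meaningful channel set, reported with channel
names in the montage order Fp1, Fp2, AFz, …, O2, A1, A2. An empty
intersection is returned as such, alongside the per-case sets.

## Synthetic data generator

Each record emulates one subject's 24-channel, 250 Hz recording. Channels
carry unit-variance 1/f-shaped Gaussian noise (spectrally shaped white
noise), the standard first-order stand-in for EEG background. A configurable
subset of channels (default AFz, C4, CPz, P7, A2) additionally carries a
10 Hz sinusoid with per-record random phase and amplitude

    a = base_alpha_amp · class · (effect_size − 1),    base_alpha_amp = 0.25

so the planted component vanishes at effect_size = 1 (all channels then have
identical expected alpha power) and grows with the class label (1 = low,
2 = moderate, 3 = high pain) — the minimal model whose band power is
analytically checkable and which the pipeline can separate. Labels are
assigned to subjects by a largest-remainder quota on `class_probs` (default
uniform) and shuffled by the seed: marginals track the requested
probabilities exactly even at small n, which keeps stratified 10-fold CV
feasible at benchmark scale. Records are segmented without overlap into the
three case durations 60/30/15 s (segment counts double as durations halve);
all segments inherit the record's label. Identical seeds give bit-identical
datasets.

What the generator does **not** emulate: physiological rhythms beyond one
alpha line, artifacts (blinks, EMG), inter-channel correlation,
non-stationarity, or subject heterogeneity. Passing the recovery benchmark
therefore shows that the implementation wires the four phases correctly and
can detect planted narrow-band class structure — not that the pipeline
performs comparably on real EEG.

## Benchmark problem sizes

The seeded recovery study (`bwhpat.experiments.recovery_experiment`) uses 30
subjects × 60-s records: 30/60/120 segments for cases 1/2/3, 24 channels,
effect size 3 on the 5 default planted channels, INCA 50..500, tenfold CV —
about one minute per seed on one CPU, ten seeds per study. The unit-test
pipeline smoke runs use 9 subjects × 6 channels × 8-s records with 3-fold CV
and case durations 8/4/2 s.

## Known limitations

- **Selection-induced accuracy saturation at small n.** Because the NCA
  ranking sees all segments and the reported accuracy is the minimum CV loss
  over 451 candidate sizes, channels with *no* class information reach
  perfect CV accuracy once the segment count is small relative to the 2970
  candidate features (observed for cases with ≤ 60 segments; re-validating
  with fresh folds does not remove it, since the ranking itself is fit to all
  data). When every channel saturates, the strict-median rule returns empty
  meaningful sets and the cortex-map intersection is empty, so
  planted-channel recovery fails at benchmark scale even though planted
  channels classify perfectly. De-saturating all three cases needs roughly
  ≥ 120 segments per case, which multiplies NCA cost (O(n²p) per iteration,
  iterations = n/2) beyond a desk-scale budget. This is a property of the
  selection-outside-CV protocol, faithfully implemented; a nested
  (double) CV would remove the bias at further cost and is out of scope.
- The per-channel results share one fold seed across channels for
  comparability; different seeds give slightly different tables.
- EDF export requires an EDF writer backend (`mne` + `edfio`); without it the
  exporter raises a clear error. CSV is the native, exactly round-tripping
  format.
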