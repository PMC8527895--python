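# Methods

`speechtrf` models the coupling between continuous speech and
low-frequency EEG with multivariate temporal response functions (TRFs),
derives phoneme distance maps from the phonetic-feature TRFs, and decodes
second-language (L2) proficiency from TRF-derived features.  Because the
package is exercised end-to-end on synthetic cohorts, this note describes
both the analysis models and the generative model that the tests run
against, and states explicitly what passing tests do and do not show.

## Stimulus descriptors

All regressors live on a common 50 Hz grid.  The master descriptor has 43
dimensions in eight named groups:

| group | dims | content |
|-------|------|---------|
| `S`   | 16   | auditory spectrogram (cochlear-style band envelopes) |
| `E`   | 1    | broadband envelope = mean of the `S` bands |
| `Ed`  | 1    | half-wave-rectified first difference of `E` |
| `Pon` | 1    | phoneme-onset impulses (one sample per phoneme) |
| `Pvc` | 2    | vowel / consonant onset impulses; columns sum to `Pon` |
| `Phn` | 19   | binary step functions of articulatory features |
| `Pt`  | 2    | phonotactic prefix probability at onsets (`Pt1`) and its change (`Pt2`) |
| `Sem` | 1    | semantic dissimilarity at content-word onsets |

Two canonical sets are fitted: `ALL = [E, Ed, Pvc, Pon, Pt, Sem]`
(8 columns) and `EXT = [S, Ed, Phn, Pon, Pt, Sem]` (40 columns).

The auditory spectrogram approximates a peripheral auditory model in
three stages: 128 band-pass filters log-spaced from 100 Hz to 0.4 of the
audio rate, a hair-cell stage (half-wave rectification, 30 Hz low-pass,
cube-root compression), and a lateral inhibitory network (half-rectified
first difference across frequency), after which band envelopes are
resampled and averaged 8:1 into 16 output bands.  This is a documented
approximation built from standard DSP primitives, not a port of any
particular toolbox.

Phonotactic probabilities come from a MaxEnt grammar: the harmony score
of a string is `h(x) = sum_i w_i C_i(x)` over weighted constraint
violations, `P*(x) = exp(-h(x))`, and `P(x) = P*(x) / sum_{y in Omega}
P*(y)`.  Omega is the set of all inventory strings of the same length;
for unigram/bigram constraints the normaliser is computed exactly by a
transfer-matrix recursion, so no enumeration is needed (an explicit Omega
is supported for toy oracles).  `Pt1` uses the normalised probability
`P`; `P*` is exposed for comparison.

Semantic dissimilarity of a content word is one minus the Pearson
correlation between its embedding and the mean embedding of the
preceding content words of the sentence; a sentence-initial word uses
the previous sentence's words.  The very first content word of a passage
has no context; it receives the mean of all other dissimilarity values
(the choice avoids an arbitrary 0 or 1 and leaves the regressor's scale
untouched).  Content words are the complement of a configurable stopword
set; in the synthetic languages the lexicon carries the flag directly.

Onset-to-sample mapping is nearest-sample with exact ties resolved toward
the earlier sample.

## TRF estimation

The forward model is `y(c, t) = b_c + sum_f sum_tau w(c, tau, f)
x_f(t - tau) + noise` over the half-open lag window (0, 600] ms — 30 lags
at 50 Hz; the closed window would give 31.  Estimation is ridge
regression per channel on the lagged design with an unpenalised
intercept.  Design columns are z-scored per lagged column over the
recording; z-scoring after lag expansion keeps the zero padding at trial
onsets inside the column span (it encodes pre-trial silence), which makes
noiseless recovery exact.  Reported weights are transformed back to raw
feature units.

The ridge parameter is tuned over a 13-point grid log-spaced from 1e-2 to
1e10.  Cross-validation leaves one trial out; within each training fold
the grid is evaluated either on a single reserved training trial
(`inner="holdout"`, the default used by the cohort pipeline) or by full
inner leave-one-out (`inner="loo"`).  One lambda is shared across
channels, selected by the mean correlation across channels; the final
model is refit on all trials at the modal fold-wise lambda.  Prediction
correlations are computed per trial and averaged (not pooled), which
keeps folds exchangeable.  With only two trials no inner fold exists and
the grid median is used.

Because all subjects of a cohort hear the same stimulus, the stimulus
side of the normal equations — per-trial Gram matrices and fold-wise
eigendecompositions of the centred training Gram — is computed once per
descriptor set and shared across subjects; per-subject data enter only
through cross-products.  Scoring uses sufficient statistics in the fold
eigenbasis, so no per-lambda predictions are materialised.

Two identifiability facts shape the oracle tests.  First, `Pon` equals
the sum of the two `Pvc` columns by construction, so the `ALL` design has
a 30-dimensional null space and only the total vowel-onset and
consonant-onset responses (`Pon + Pvc_V`, `Pon + Pvc_C`) are
identifiable; recovery is asserted on those totals together with `E`,
`Ed`, `Pt1`, `Pt2` and `Sem`.  Second, the `Phn` block has rank equal to
the phoneme-inventory size (9 in the default toy languages, below the 19
feature dimensions); only the projected per-phoneme responses
(`indicator-table @ weights`) are identifiable, and the generator plants
its phoneme kernels as the minimum-norm solution consistent with the
planted responses.

Generic (group-average) models are element-wise means of per-subject
weights and biases; a left-out subject's EEG is scored against the four
group models for three predictor sets (envelope, phoneme-level gain
`PhnEnv'Sgr - Env'Sgr`, semantic dissimilarity), giving 12 group-similarity
features.

## Phoneme distance maps

Phonetic-feature TRF weights are projected to the phoneme domain by the
phoneme-by-feature indicator table, embedded by classical (Torgerson)
MDS with time latencies as dimensions, and aligned by Procrustes
analysis (translation, orthogonal rotation/reflection and isotropic
scaling, matching the common MATLAB convention).  The projection routine
takes a single electrode (Cz) or a concatenation across electrodes; the
cohort pipeline concatenates the five midline electrodes (Fpz, Fz, Cz,
Pz, Oz), which at desk-scale SNR averages down map noise without
changing the geometry of the planted (spatially smooth) responses.  Four
MDS dimensions are retained by the pipeline (positive-eigenvalue axes
capped at 10 in the general routine).

The native reference space is built by mutually aligning the per-native
subject maps (seed map = first native subject, two refinement passes) and
averaging.  Per-subject L1-L2 distances use the fully aligned maps.
Contrast ratios (a pair's distance divided by the native map's distance
for the same pair) are computed on unaligned maps: pair distances are
invariant to rotation and translation, and the Procrustes scale factor
would otherwise shrink a strongly mismatched (assimilated) configuration
wholesale.

For cross-group weight comparisons the pipeline fits a companion set of
EXT models at a common lambda — the minimum of the per-subject tuned
values.  Tuned lambdas differ systematically between groups (their
responses differ in total signal), and regularisation both scales weight
amplitudes and leaks structure between correlated regressor groups; a
common, minimal lambda keeps map geometry a property of the responses
rather than of the shrinkage.  Prediction-based features keep the
per-subject tuned fits.

## Proficiency decoding

Each subject is summarised by 26 features: 9 weight-derived (5 rank-1
multilinear-PCA scores for the envelope, onset, phonetic-feature,
phonotactic and semantic TRFs; 1 MPCA score of the spectrogram weights
collapsed across lags; 2 phonotactic window means, 80–140 and 300–700 ms;
1 semantic window mean, 300–700 ms — windows intersected with the 0–600 ms
lag range, electrodes Fz/Cz/Oz), 5 prediction-correlation features
(per-electrode correlation vectors for the single-feature models and the
phoneme-level gain, each compressed by MPCA), and 12 generic-model
features.  The MPCA is an alternating-least-squares rank-1 multilinear
fit with unit-norm non-subject modes; the sign is fixed so scores
correlate positively with the mean-subject projection.

Support vector regression (RBF kernel, C = 1, epsilon = 0.1, gamma =
1/(d·var)) decodes the CEFR level (A1..C2 encoded 1..6) with
leave-one-subject-out cross-validation; features are standardised on the
training fold only.  Predictions are continuous; thresholding at 3.5
(ties to the A side) yields the A-vs-C classification.  Backward
elimination greedily removes the feature whose exclusion most lowers the
out-of-fold MSE and stops when the best removal improves it by less than
5% (relative).

The permuted-label control retrains under label permutations and
correlates the out-of-fold predictions with the **true** labels, averaged
over 20 permutations.  Correlating with the permuted labels themselves is
biased negative under leave-one-out (the training mean anti-correlates
with the held-out label, about −0.3 at n = 24), which would be
misread as anti-decoding; against the true labels the null expectation is
exactly 0 by exchangeability.

Binary classifications (e.g. native vs non-native) use an SVM with the
same kernel and a shuffled-label baseline (95th percentile of 100
permutations).

## Group statistics

Point-wise one-way fixed-effects ANOVA over (lag, electrode) points with
Benjamini-Hochberg FDR at q < 0.05; N1-P2 peak-to-peak amplitude on the
electrode-averaged envelope TRF (default search windows 50–150 and
150–300 ms, configurable — the windows are a package default, not a
reported value); trough latency as the argmin of the TRF in 300–600 ms
(ties to the earliest lag, flagged when no negative value exists); cosine
distance between a subject's TRF and the group-mean TRF flattened over
electrodes and latencies; Spearman rank correlation with mid-ranked ties.
The three-way proficiency × latency × electrode ANOVA is a fixed-effects
type-II decomposition; a Greenhouse-Geisser epsilon computed from the
subject × latency covariance rescales the degrees of freedom of effects
involving latency.  None of these metrics is invariant to adding a
constant across channels; tests assert exact values on fixtures instead.

## Synthetic cohorts

The generator emulates a listening study with groups A, B, C (eight
subjects per group by default, CEFR sub-levels within each) and a native
group, all hearing the same stimulus: per-trial transcripts sampled from
a toy language (default 6 shared + 3 target-unique phonemes, random
bigram MaxEnt grammars, 120-word lexicon, 16-dimension embeddings;
the 62-channel montage and 400-dimension embeddings of larger studies
are configuration options, 32 channels and 16 dimensions are the
desk-scale defaults).  EEG is the convolution of planted kernels with the
stimulus regressors plus noise with a 1/f + white spectrum mixed 50/50 in
power — a standard resting-EEG approximation.  The default conditions
used by the acceptance analyses are 6 trials × 60 s at 50 Hz, 0 dB SNR,
and inter-subject kernel variability of 10% in amplitude and 12 ms in
latency.

Planted effects:

* the semantic trough deepens (amplitude 0.35 + 0.11·level) and moves
  earlier (latency 540 − 30·level ms) with proficiency; the native kernel
  peaks at 360 ms with amplitude 1.1;
* the phonotactic kernel has a late (~370 ms) component that deepens with
  proficiency and an early (~120 ms) component present only for L2
  listeners, largest at low proficiency and exactly zero for natives;
* responses to target-unique phonemes interpolate between the nearest
  shared phoneme's response (Hamming-nearest on the feature rows, ties
  lexicographic; full assimilation at the lowest proficiency) and a
  distinct native pattern.

Noise amplitude is fixed per cohort from a mid-proficiency reference
forward model rather than per subject, so that planted amplitude effects
do not leak into the noise level.  Effect sizes are free parameters of
the generator, chosen once at magnitudes comparable to the acoustic
components; they are not calibrated to any reported group values.

What passing tests show: the estimators invert the generative model they
are given — linear kernels, stationary noise, perfectly aligned
transcripts, a stimulus shared across subjects.  They do not show
robustness to artifacts, imperfect forced alignment, nonlinear or
nonstationary neural responses, or inter-subject latency variability
beyond the planted jitter, and desk-scale cohorts say nothing about
effect sizes in real populations.

## Numerical choices

Degenerate inputs: constant predicted or observed channels score r = 0
with a warning; a singular system at lambda = 0 raises with advice to use
lambda > 0; an all-zero tensor is rejected by MPCA; zero-norm TRFs are
rejected by the cosine metric; phoneme pairs with zero native-map
distance are excluded from contrast ratios with a warning.  Bad-channel
detection flags variance above 3× the mean of the 6 nearest neighbours
and aborts if more than half the channels are flagged; spherical-spline
interpolation uses order m = 4, 20 Legendre terms and ridge 1e-5.
Band-pass filtering is a zero-phase (order 2+2) Butterworth, resampling
is polyphase with a Kaiser window.  MDS eigenvalues below 1e-12 of the
maximum count as zero.  All randomness flows through explicit
`numpy.random.Generator` seeds; identical seeds give bit-identical
cohorts.
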