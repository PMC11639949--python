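# Methods

`femvoice` implements the computational core of a dysarthric
voice-conversion framework in which a fuzzy clustering model over joint
acoustic/phonemic features decides *when conversion is done*: an
utterance is converted repeatedly until its membership in the
normal-speech cluster strictly dominates its membership in every
dysarthric cluster. This note describes the models, the defaults and
why, the synthetic data they are tested on, and the limits of what
those tests show.

## Feature representation

Waveforms are mono, resampled to 16 kHz. Two frame-synchronous
representations are computed with one shared framing convention
(centered analysis, reflection padding, Hann window):

* **Mel-spectrogram** — magnitude STFT mapped through an 80-band
  triangular Mel filterbank (HTK Mel scale, 0–8 kHz). Window 46.4 ms
  and hop 11.6 ms; at 16 kHz these round to 742 and 186 samples
  (nearest integer; the millisecond values are taken as authoritative
  even though they are not integer sample counts). FFT length is the
  next power of two (1024). Output is linear in waveform amplitude —
  no log compression by default — so silence maps to exactly zero and
  scaling the input scales every entry proportionally. For the
  conversion-model input convention, frame counts can be zero-padded to
  a multiple of 4.
* **MFCC + dynamics** — log of the same 80-band Mel magnitudes (floor
  1e-10), orthonormal DCT-II, first `n_cepstra = 13` coefficients, plus
  delta and delta-delta blocks from the standard ±2-frame regression
  filter with edge replication, giving 39 columns. The joint per-frame
  vector is the concatenation `[X_mfcc(t), X_phoneme(t)]`, where the
  phoneme block is a one-hot (or posterior) row from an upstream
  phoneme predictor; predicting phonemes is out of scope here, labels
  arrive through a contract.

The delta filter width (±2) and the reuse of the Mel filterbank for
MFCCs are package choices; conventions in the field differ and nothing
downstream depends on them beyond the 3 × n_cepstra width contract.

## Fuzzy expectation-maximization clustering

Given frames `x_i` and K clusters (K−1 dysarthric types plus one
normal-speech cluster), the model alternates:

* **E-step** `mu_ij = 1 / sum_k (d_ij / d_ik)^(2/(m−1))`, with `d_ij`
  the Euclidean distance to center `C_j`; a point coinciding with a
  center receives full membership there (first such center on ties).
* **M-step** `C_j = sum_i mu_ij^m x_i / sum_i mu_ij^m` — the unique
  minimizer of `J = sum_ij mu_ij^m d_ij^2` for fixed U, so J is
  provably non-increasing; the suite checks this with 1e-9 slack. A
  cluster whose total weight vanishes is reinitialized from a random
  data point and the event logged.

**Initialization** anchors the last center (`normal_index = K−1`) at
the arithmetic mean of the normal-speech frames; the other K−1 centers
are distinct data points drawn uniformly at random (seeded).
**Convergence** is declared when either the maximum per-center
displacement or the Frobenius norm of the membership change falls below
its tolerance (both default 1e-6); which criterion fired is recorded.

Defaults: `m = 2.0` (the common fuzzy-clustering choice; the formula
degenerates at m = 1, so m > 1 is enforced), `max_iter = 300`, K equal
to the number of speech types (15 in the reference setting) — K is a
parameter, never estimated. Features are z-scored per dimension before
clustering by default (`standardize=True`), because MFCC magnitudes and
one-hot phoneme indicators live on very different scales; centers are
always reported back in input units so the conversion gate operates in
the original feature space.

The estimator (`FuzzyEMClustering`) follows scikit-learn conventions
(get_params/clone, `fit(X, normal_mask=...)`, fitted attributes with a
trailing underscore, `predict_proba` = soft memberships), so it
composes with sklearn model selection; the module-level functions
(`e_step`, `m_step`, `fit_fem`, ...) expose the same arithmetic
functionally.

## Conversion gate

Whole-utterance membership is the arithmetic mean of frame membership
rows (pluggable; a renormalized median is provided). The gate declares
an utterance normal iff its normal-cluster membership **strictly**
exceeds every other membership — ties are conservatively not-normal.
The loop applies a shape-preserving conversion operator, re-scores
membership, and stops at the first normal-dominant state or at
`max_iter = 50`; exceeding `max_iter` is a flagged outcome
(`terminated_by="max_iter"`), not an error, so batch runs complete.
The full membership trace (pre-loop state included, hence length
`n_iter + 1`) is returned.

The trained diffusion converter is out of scope. Two reference
operators stand in: the **oracle centroid converter** moves every frame
a fraction α toward the normal centroid (distance contracts by exactly
(1−α) per step — an affine test double with a known fixed point), and
the **identity converter** exercises the safeguard path. The forward
(corrupting) half of the diffusion process is provided as a utility:
Gaussian noise with a nondecreasing per-step sigma schedule, used for
calibration tests. Whether a real converter restarts diffusion each
gate iteration or continues from its previous output is left to the
operator implementation; the gate only requires a shape-preserving map.

## Evaluation metrics

WER uses a minimal-cost word-level alignment (unit costs; on equal cost
the backtrace prefers substitution, then deletion, then insertion) and
the formula `WER = (S+D+I)/N × 100%`. Corpus WER pools S, D, I, N over
utterances before the formula (a macro average over per-utterance
percentages is available — published figures do not say which
convention they use, so both exist). Severity-level mild/severe WERs
combine into a "total" as their unweighted mean, the convention under
which every published Total cell in the comparison table this package
ships (`PUBLISHED_WER_COMPARISON`) is reproduced exactly to the printed
precision; a weighted mean is available for unequal group sizes.
Tokenization is lowercase + punctuation stripping + whitespace split
(ASR output is assumed pre-normalized). MOS is the arithmetic mean of
integer 1–5 listener ratings; the listening study itself is not
reproducible computationally, only its aggregation arithmetic lives
here.

## Synthetic corpus

The generator emulates the *shape* of a clinical voice-disorder corpus,
not its content: `n_types = 15` speech types (14 dysarthric archetypes
+ 1 normal), per-type isotropic Gaussian frame features
(`spread = 1.0`) around centroids drawn with all pairwise distances
≥ `min_separation × spread` (default 6; redrawn up to a bounded number
of attempts, then a `SeparationError` reports the attempt count),
10 utterances per type of 40–120 frames, per-type categorical phoneme
distributions (Dirichlet-drawn), and an 80/10/10 utterance-level
train/test/validation split with largest-remainder rounding so sizes
are exact. Utterance lengths and per-type counts are not documented
for the original corpus; these defaults are the package's own and are
configurable. A separate waveform path renders a 6-partial harmonic
source with cycle-level jitter (frequency perturbation), shimmer
(amplitude perturbation) and additive breath noise, peak-normalized to
≤ 1 — enough structure for the feature path to chew on, with no claim
of clinical realism.

What passing tests on this corpus do **not** show: real dysarthric
speech is not a separable isotropic Gaussian mixture in joint feature
space, phoneme streams are not i.i.d. categorical, and a learned
converter does not contract affinely toward the normal centroid.
The tests certify the algorithmic machinery (convergence, gating
semantics, metric arithmetic, determinism), not clinical performance.

## Numerical and design notes

* Distances are Euclidean; the objective uses squared distances. The
  E-step is computed via `d^(−2/(m−1))` row-normalization, with exact
  zero-distance handling before the power.
* Seeds: every stochastic routine takes an explicit seed;
  `run_pipeline` fans one global seed into per-stage seeds via
  `SeedSequence([seed, stage_index])`, so stages are individually
  reproducible, and the run manifest records a SHA-256 hash of every
  written file. Repeated runs are byte-identical (timing fields aside).
* Cluster recovery at the default study conditions (15 types,
  separation 6, 20 seeds) yields a mean adjusted Rand index of about
  0.9: the random-data-point initialization sometimes leaves one type
  without a nearby center and the fuzzy updates then merge two types
  into one cluster, which caps per-seed ARI near 0.92–0.94 with
  occasional lower outliers. This is inherent to the anchored
  random-point initialization, which is kept as specified rather than
  replaced by a seeding heuristic.
* Problem sizes in the test suite and acceptance script (20-seed
  recovery runs at the default corpus size, ~12 000 frames each;
  smaller 5-type corpora for pipeline determinism) were chosen so the
  full suite runs in well under a minute of compute per concern while
  keeping the statistics stable.
* The published "256-dimensional features" figure discussion is not
  reconcilable with 3·n_cepstra + d_phoneme; dimensionality is a
  configuration knob (default 39 + 10).
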