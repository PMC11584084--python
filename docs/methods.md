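# Methods

This note describes the models and procedures implemented in `eegrsa`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Entity vectors from text

An entity's descriptive text arrives as sentence-segmented tokens, each
flagged `is_content` (open-class: nouns, verbs, adjectives, adverbs).
The package trusts this flag and does no tagging of its own; the
synthetic generator emits it, and real-text users must supply it.

Sentences are concatenated greedily into **passages**: a passage closes
as soon as its cumulative word count reaches `min_words` (default 20;
tokens without an alphanumeric character, i.e. punctuation, do not
count).  A trailing under-length passage is kept as its own passage —
descriptive text is scarce and discarding it would bias the
representation; `keep_short_tail=False` merges it backward instead.

Each passage is embedded and reduced to one vector: content-word vectors
only (for a static provider, out-of-vocabulary words are skipped rather
than zero-imputed, since zero vectors drag the mean toward the origin;
for a contextual provider, the top `min(4, L)` layers are averaged per
token), then averaged within the passage.  The entity vector is the
unweighted mean of passage vectors — a **two-stage mean** that weights
passages, not tokens.  Repeated tokens count each time they occur.

The provider contract is deliberately minimal (`lookup` for static
tables, `encode` returning per-token per-layer vectors for contextual
models) so that real language models can be plugged in; the shipped toy
providers are deterministic lookup tables, and a contextual toy that
replays the static table at every layer is used to verify that the
pooling pipeline is provider-agnostic.

## Non-semantic baselines

Two scalar controls represent each entity by one number: **name length**
(characters, internal spaces included — multi-word names are read as a
whole; a no-spaces option exists) and **orthography** (mean Levenshtein
distance to all other stimulus names, case-folded, unit costs, via the
edlib C library).  To let a scalar model drive the RSA encoder, values
are z-scored over entities and similarity(i,j) = −|z_i − z_j|: the
simplest monotone similarity that preserves the encoder's
weight-by-resemblance semantics.  This conversion rule is our choice —
there is no canonical way to put a one-dimensional model into a
Pearson-similarity encoder — and baseline results should be read with
that in mind.

## RSA encoding and leave-two-out evaluation

First-order similarities are Pearson correlations between entity
vectors.  The predicted response for held-out entity *d* is the raw
weighted sum `Σ_i r(v_d, v_i) · x_i` over training entities — negative
weights included, no normalization.  Predictions are scored with
Spearman's ρ (average ranks for ties).  Evaluation enumerates all
unordered entity pairs as test sets; the training set is always every
other entity, also under category-restricted evaluation (restriction
narrows the *test pool* only; a switch restricts training too).  The
final score is the mean over all recorded correlations, two per pair.

Degenerate predictions are skipped, not scored: a pair is dropped (and
`n_pairs` decremented, with a warning) when a predicted or observed
vector is constant, **or when the weighted sum cancels to numerical
zero** (relative tolerance 1e-8 against the weight norm times the
response scale).  The second clause matters: when similarity weights are
an affine function of a regressed-out confound — which happens for
scalar models whenever the test item sits at the extreme of the value
range — the prediction collapses to machine epsilon, and correlating
that rounding dust would bias the mean score.  Real predictions sit many
orders of magnitude above the threshold.

## Confound regression

Per train/test split, ordinary least squares maps the confound (name
length) to every feature (channel × time sample); only training entities
enter the fit, and the fitted model residualizes training and test rows
alike (linear extrapolation, no clipping).  The confound is standardized
with training statistics — residuals are identical to unstandardized
OLS, but slopes become scale-free.  Residualization happens once per
split on the full channels × times feature vector, before any per-unit
slicing.  It is applied to all entities uniformly (a switch restricts it
to personally familiar entities, whose names cannot be length-matched in
advance).  Training residuals are exactly orthogonal to the confound;
the validation suite asserts |r| < 1e-10 per feature.

## Time-resolved and searchlight analyses

Time-resolved encoding uses, per time point, all electrodes as the
feature vector.  The searchlight tiles 0–800 ms into consecutive 100 ms
windows (2 × the 50 ms temporal radius; reported effects in 100 ms bins
motivate tiling over sliding, though a sliding step is available) and
pairs each window with every electrode disk: all channels within 30 mm
straight-line 3-D distance of a center, every channel acting as a
center.  Cluster features are member channels × in-window samples,
flattened.  Geodesic scalp distance is not used — positions are points
and no head surface is modelled.

## Group statistics

Per analysis unit, scores are tested across subjects against chance
level 0 with a one-sample t (n−1 denominator; zero-variance units warn
and get t = 0).  **TFCE** integrates `extent^E · h^H · dh` over
thresholds (E = 0.5, H = 2, dh = 0.1 — the method's canonical defaults),
one-tailed so non-positive t enhances to 0; the implementation processes
thresholds descending with an incremental union-find and is tested
against an explicit threshold-loop/connected-components oracle.
Adjacency is a chain over time points, and for searchlight units:
same-window clusters with centers ≤ 40 mm apart (a free parameter) plus
same-center clusters in consecutive windows.

The null is built by flipping each subject's sign jointly across units
(exchangeable under a symmetric null — the standard one-sample
convention), recomputing t and TFCE, and recording the maximum enhanced
value per permutation; `p(u) = (1 + #{max ≥ enh(u)}) / (1 + n_perm)`,
which keeps p strictly positive and controls the family-wise error rate
by design.  Sign assignments are enumerated exhaustively when
`2^n_subjects ≤ 4096`, otherwise 1024 random draws (default).  Model
comparisons apply the same test to per-subject score differences.

## The synthetic generator

The generator emulates the study conditions the pipeline targets: 33
subjects by default, 32 entities in a person/place × famous/familiar
design, a 128-channel-like montage (Fibonacci sampling of the upper
hemisphere at 95 mm; fully deterministic), epochs 0–800 ms at 5 ms, and
a name-length confound.  Evoked responses follow

    x[e,c,t] = (M_s · v_e)_c · w(t)  +  β · len(name_e) · g_c  +  ε

with `v_e` the planted entity vector (shared category and familiarity
topic components, weights 1.0 / 0.6 / 0.8 idiosyncratic), `M_s` a
subject-specific mixing whose rows are scaled by a fixed sparse loading
(a random half of channels carries no semantic signal; the loaded half
has exponential gains — this is what the searchlight is expected to
localize), `w(t)` a boxcar over the signal window (unambiguous for
recovery tests; real components have smooth shapes), `g` a fixed
Gaussian confound topography, and ε i.i.d. Gaussian scaled so the
within-window signal/noise standard-deviation ratio equals `snr`
(`snr = 0` disables the signal and fixes unit noise).

Texts are 5–15 sentences of 5–40 tokens; content words are noisy copies
of the entity vector (per-dimension sd 0.25/√dim) drawn from a
40-word per-entity pool, function words come from a shared closed-class
list.  Name lengths are **balanced across design cells** (one multiset
of lengths, 4–16 characters, reused in every cell), mirroring
stimulus-level length matching: without it, at small entity counts the
name-length similarity structure chance-correlates with the planted
semantic structure and the baselines inherit real signal.

All randomness derives from one master seed through
`SeedSequence([seed, stream, index])` with fixed stream codes;
per-subject streams are keyed by subject index, so enlarging a dataset
never reshuffles existing subjects.

What the generator does **not** emulate: realistic ERP morphology
(N400/LPC waveshapes), volume conduction, spatially or temporally
autocorrelated noise, inter-subject topography alignment, or text with
realistic redundancy — its texts are so internally consistent that a
single sentence already determines the entity vector (the
model-comparison analysis script shows this as an honest null).  Passing
the validation suite therefore demonstrates the correctness and
calibration of the *procedures*, not effect sizes or spatial patterns
expected in real EEG.

## Validation problem sizes

The statistical self-checks (test suite and `scripts/acceptance.py`)
run at sizes chosen once for single-CPU turnaround: predictor oracle on
1000 random ≤6-entity instances; encoder null calibration with 16
entities × 20 subjects over 200 seeds; family-wise calibration with 100
null experiments (160 time points, 20 subjects, 8 entities, 16 channels,
512 permutations); signal recovery with 30 subjects, snr 1, 16 entities,
64 channels, 20 ms sampling over 20 seeds (searchlight contrast between
clusters containing top-quartile-loaded channels and clusters with no
loading); baseline nulls at the full 32-entity design, 32 channels,
time-resolved only.  Note the per-seed baseline check runs two highly
correlated permutation tests at α = 0.05, so its false-positive rate has
a nominal floor near 5% — isolated single-point flags at arbitrary
latencies are expected type-I events, not residual confounding.

## Known limitations

- The scalar-to-similarity conversion for baselines is a documented
  guess; different monotone rules could rank baseline models differently.
- With a boxcar temporal profile, singleton searchlight clusters carry
  no within-cluster pattern; montages sparser than ~25–30 mm spacing
  make the searchlight blind by construction.
- i.i.d. noise makes Spearman across channels far more sensitive than
  real, spatially correlated EEG noise would allow; synthetic effect
  sizes are not predictions for real data.
- The permutation test assumes a null symmetric about zero; encoding
  scores satisfy this under exchangeability, but heavy asymmetric
  artifacts in real data would violate it.
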