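# Methods

`sentperturb` implements, end to end, the measurement logic of
perturbation-based encoding-model studies of the human language network:
which aspects of a sentence — its word order, its function words, its
content words, its topical identity — must be present in a stimulus
representation for that representation to linearly predict fMRI voxel
responses to the intact sentence.  Because the real measurements (fMRI
matrices, pretrained-transformer activations) are not shippable, every
stage runs against a synthetic study whose generative assumptions are
explicit and whose planted structure makes the expected outcomes provable.
This note records the model, its parameters, and the design decisions.

## The encoding benchmark

Stimuli are sentences organized as experiment → topic → passage → sentence.
Text is normalized to lowercase, whitespace-delimited words; all
sentence-internal punctuation except hyphens and apostrophes is removed,
and the terminal period is carried as metadata and re-appended on
rendering, so word-level perturbations never touch it.

For one perturbation condition, one design cell, and one embedding layer,
the benchmark is:

1. split each experiment's sentences into k = 5 cross-validation folds
   (random by sentence, or by whole passage);
2. per voxel, fit ordinary least squares with intercept from the training
   sentences' summary vectors to that voxel's responses (minimum-norm
   pseudoinverse when the feature count exceeds the training count);
3. predict the held-out sentences and score each voxel with Pearson r
   (zero-variance predictions or targets score 0 and are flagged, never
   dropped);
4. average r over folds per voxel, take the median over a participant's
   voxels, process experiments separately, and average a participant's
   scores across the experiments they completed.

The design crosses two factors. *Train source*: the mapping is trained on
intact (Original) representations and tested on perturbed ones — the main
design — or trained and tested on perturbed ones.  *Contextualization*:
representations are computed with the perturbed preceding in-passage
sentences fed as a prefix, or from the sentence alone.  Under the
train-on-intact design the three sentence-replacement conditions are
realized inside each test fold by deranging the *original* representations
within passage/topic groups (or the whole fold), because training and test
stimuli must stay disjoint; groups of size one cannot be deranged and are
logged as the unshuffled fraction.  On the full stimulus structure
(96 four-sentence passages plus 72 three-or-four-sentence passages) with
five folds this leaves ≈54% of test sentences unmoved for the
within-passage variant and ≈7% for the within-topic variant under
singleton-only accounting; `scripts/acceptance.py` recomputes the former.
Layer scores are reported for the best-performing layer per condition
(across-participant median, ties to the deeper layer), or with the
Original condition's best layer applied everywhere.

## Perturbation conditions

Twenty conditions in five categories.  Word-order: local adjacent swaps at
exact adjacent-transposition distance k ∈ {1, 3, 5, 7} (whole swap
sequences are resampled, up to 10,000 attempts, until the verified
Kendall-tau distance — duplicates resolved by stable position assignment —
equals k; shorter sentences for which this is impossible are skipped with
a warning), full reversal, and two low-PMI orderings.  The deterministic
one interleaves class lists as [odd content | odd function | even function
| even content] (1-based within class), placing every function word between
the two content lists.  The randomized one draws 10 distinct whole-sentence
permutations — excluding the realized k-swap outputs for that sentence —
and keeps the one with the lowest PMI score.  Information-loss: stable-order
deletion keeping {content words}, {N,V,Adj}, {N,V}, {N}, or only function
words; pronouns and proper names count as nouns.  Semantic-distance:
replacement by another sentence from the same passage, topic, or experiment
(constrained derangements; within-experiment scope by default), or by a
supplied paraphrase.  Controls: per-sentence draws without replacement from
the dataset word pool (length-matched) or noun pool (length-matched to the
kept-nouns output), and a single-filler length control.

A string's PMI score is the mean positive pointwise mutual information of
all word pairs within a four-word sliding window (bigrams, 1- and
2-skip-grams), with Laplace smoothing α = 0.1 over a pluggable counts
provider: P(w) = (c(w)+α)/(N₁+αV), P(w₁,w₂) = (c(w₁,w₂)+α)/(N₂+αV²),
natural log.  The normalizer is 1/(3n−2) as conventionally printed, even
though a sentence of n ≥ 4 words contributes 3n−6 window pairs; a
`normalizer="pairs"` switch divides by the actual pair count instead (the
choice rescales all scores equally and cannot affect an argmin).  Because
the window is symmetric and pair counts unordered, the score is exactly
invariant under full reversal — reversal destroys global order while
preserving the local co-occurrence profile.

All generators are bit-reproducible: every random draw is seeded by a hash
of (master seed, condition, sentence id), so adding a condition never
perturbs another's output.

## Representations

An embedding provider maps a token sequence to per-layer token vectors
(n_layers × n_tokens × dim).  Sentence summaries are either the last
token's vector (the terminal period, by which a unidirectional encoder has
aggregated the sentence) or the mean over the sentence's tokens.

The synthetic provider stands in for a pretrained network.  Each word has
a fixed pseudo-random unit base vector (hashed from the word and the
provider seed).  A token's raw vector is its base vector, plus
`positional_weight` (default 0.1) times a pseudo-random vector indexed by
position *from the sequence end* (so a sentence's representation does not
depend on how much context precedes it when context weighting is off),
plus `context_weight` λ (default 0.3) times a recency-discounted running
average of the preceding tokens' base vectors (decay 0.8 per step, strictly
causal) — the discount makes the summary weakly order-sensitive.  Each
layer applies its own random mixing matrix followed by tanh at gain 2.5;
the saturation makes layers non-linearly related, so a linear readout
planted at one layer is identifiable by the benchmark rather than equally
readable from every layer.

Optionally, the provider degrades tokens in improbable contexts: a token's
vector receives deterministic hash-noise scaled by
`weight · (max(0, s − μ)/μ)²` (capped), where s is the token's bigram
surprisal under the synthetic corpus language model and μ the corpus-mean
surprisal.  This emulates the way a trained network's representations
deteriorate on inputs unlike its training distribution, and is the planted
link between a string's predictability and its predictivity.  Default
weight 2.0; weight 0 disables it.

## The synthetic study

The generator's defaults replicate the target benchmark's printed
structure: Experiment 2 with 24 topics × 4 passages × 4 sentences of 7–18
words (384 sentences) and Experiment 3 with 24 disjoint topics × 3
passages totalling 72 passages — 45 of three and 27 of four sentences, the
unique split matching the printed totals — of 5–20 words (243 sentences);
627 sentences in all.  Sentences come from a part-of-speech template
grammar (patterns such as FUNCTION NOUN VERB · FUNCTION ADJ NOUN) over a
pseudoword vocabulary, so POS tags are known by construction and no tagger
download is needed; each topic owns a noun pool (topic nouns drawn with
probability 0.7) so topically related sentences share vocabulary.  Count
tables and the Laplace-smoothed bigram language model are harvested from
3,000 sentences of the same grammar, which gives collocated pairs genuinely
elevated PMI and makes scrambled sentences genuinely more surprising.
Synthetic paraphrases keep each word with probability 0.5 and replace the
rest with same-POS alternatives, emulating human paraphrases only in their
lexical-overlap statistics.

Voxel responses are planted linear readouts.  The reference representation
— what the synthetic language network encodes — is, by default, the mean
of each sentence's *content-word* token vectors computed with the context
average restricted to content words while recency is still measured in
full-sentence time: the network is blind to function words as lexical
items, yet deleting a function word shifts the timing of the content words
around it and therefore changes the code.  This is the generative
counterpart of a meaning-driven language system.  Per participant, the
response is

    Y_p = shared·readout(X) + a_p·readout_p(X) + w·L[passage] + σ·ε_p

with a participant-shared readout, a participant-specific readout
(a_p = 0.2), a per-passage latent shared across participants (w = 0.2) that
creates exactly the train/test leakage that by-passage splitting removes,
and independent Gaussian noise (σ = 0.5).  Five participants and 50 voxels
by default; all weights and latents are retained as ground truth.

Under these defaults the qualitative structure of the real findings holds
by construction: predictivity falls monotonically as content classes are
deleted; function-word-only and random-word strings score near zero;
replacement predictivity falls with semantic distance (within-passage ≫
within-topic ≫ anywhere, the first two floored by their unshuffled
fractions); word-order degradation produces graded, comparatively small
drops via the surprisal-degradation channel; and the
surprisal-increase-versus-predictivity-drop correlation across conditions
is positive.  What passing these tests does *not* show: real fMRI noise
structure (autocorrelation, session effects), sub-word tokenization,
linguistic realism beyond POS patterns and topical vocabulary, or the
real-data effect magnitudes — the synthetic world demonstrates the
pipeline's correctness on a model system, not the neuroscience result.

The study defaults use mean-token summaries: the synthetic provider's
terminal-period vector is a weaker lexical carrier than a trained
transformer's last token, so the mean summary is the appropriate synthetic
analogue; last-token summaries are fully supported and exercised in tests.

## Noise ceiling

Measurement noise bounds attainable predictivity.  Each participant's
voxels are predicted from m other participants' responses through the same
CV/OLS/Pearson pipeline; v(m) is extrapolated to m → ∞ and voxel ceilings
aggregated by the median.  Two decisions differ from the most obvious
construction, both switchable:

* **Pooling** (`pooling="mean"`, alternative `"concat"`): predictor
  matrices are averaged, not concatenated.  Concatenation grows the OLS
  feature count linearly in m, so at desk scale held-out v(m) *decreases*
  for large pools through overfitting, corrupting the extrapolation;
  averaging keeps the feature count fixed and v(m) rises monotonically as
  predictor noise averages out.
* **Extrapolation form** (`form="ratio"`, alternative
  `"saturating_exp"`): under additive noise the true curve is
  v∞/√(1+b/m), which the ratio form v∞·m/(m+τ) tracks closely over small
  pools; the saturating exponential plateaus too early and underestimates
  the asymptote by ~0.02 at realistic SNR.  Fits use bounded non-linear
  least squares per voxel; non-convergence falls back to the largest
  observed value and is flagged in the diagnostics.

## Statistics

Condition contrasts are two-sided dependent-samples t tests over
participant scores, Bonferroni-corrected within the declared comparison
family; one-sample tests against zero are supported.  Error bars are the
median absolute deviation over participants after subtracting each
participant's across-condition mean within a manipulation category,
scaled by 1.4826 for normal consistency — they show within-participant
variation across conditions, not uncertainty around the median.
Representational similarity between a condition and the original sentences
is the per-sentence Spearman correlation of summary-vector components
(average ranks for ties), averaged over sentences, per layer; its Pearson
correlation with predictivity is taken over all (condition × layer) cells.
Mean string surprisal uses the final-layer next-token distribution —
here, the synthetic bigram model — in nats; the surprisal analysis pairs
each condition's surprisal increase with its predictivity drop and
excludes the sentence-replacement category, whose strings bear no relation
to the original string.

## Numerical and degenerate-input conventions

Layer indices are 0-based internally, 1-based in all reports.  Undefined
Pearson correlations (zero variance) are recorded as 0 with a warning.
Information-loss conditions may empty a sentence (recorded, not fatal;
the terminal period still anchors its representation).  Local-swap
conditions skip sentences shorter than k+1 words.  Derangements use
rejection sampling with a bounded attempt budget.  All pipeline stages
derive their randomness hierarchically from one master seed.

## Problem sizes

Defaults and tests run at desk scale by design: 627 synthetic sentences,
5 participants × 50 voxels, 6 embedding layers of dimension 32, 3,000-
sentence count corpora.  The directional end-to-end check runs ten seeded
replicates of the full default study; the ceiling-versus-oracle check uses
240 sentences × 16 voxels × 8 participants at σ = 0.45.  These sizes were
chosen so each property is measured with margin well above its seed-to-seed
spread.

## Known limitations

Real-data magnitudes (e.g., absolute predictivity levels or ceiling
values) are out of reach without the fMRI matrices and pretrained weights,
and nothing here estimates them.  The printed unshuffled fraction for the
within-topic shuffle (single digits) depends on an accounting convention
the source does not state; singleton-only accounting, used here, lands
about two percentage points below it, and the tests treat that value as an
order-of-magnitude check only.  The embedding contract supports a real
transformer adapter, but none is shipped; any provider implementing
`encode()` with deterministic output can be dropped in.
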