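# sentperturb

**Controlled sentence perturbations and voxelwise encoding models for
language-fMRI benchmarks.**

Encoding models predict brain responses to sentences from the sentence's
representation in an artificial neural network: for each voxel v, fit an
ordinary-least-squares map from training-sentence embeddings x to responses
y_v, predict held-out sentences, and score with Pearson r — averaged over
five cross-validation folds, median over a participant's voxels, aggregated
across participants.  The predictivity of the intact sentences says little
about *which aspects* of the stimulus carry the match.  `sentperturb`
answers that by systematically perturbing the stimuli whose representations
are tested: scrambling word order (at controlled adjacent-transposition
distance, by reversal, or by minimizing windowed pointwise mutual
information), deleting words by part of speech (content words, nouns+verbs,
nouns, function words), replacing sentences by semantically nearer or
farther ones (same passage / same topic / anywhere, via constrained
derangements, or paraphrases), and length-matched random-word controls —
20 conditions in all, crossed with whether the mapping model trains on
intact or perturbed representations and whether representations are
contextualized by the preceding passage.

The package is aimed at computational cognitive neuroscientists who want
to run or audit this measurement logic without the original fMRI data:
every stage — stimuli, count tables, a bigram language model, per-layer
embeddings, and multi-participant voxel responses with planted structure —
can be generated synthetically, so all claims are testable end to end on a
model system.  Alongside the benchmark it implements the windowed
positive-PMI score

    PMI(w_1..w_n) = 1/(3n-2) · Σ_{i<j≤i+3} max(0, log P(w_i,w_j)/(P(w_i)P(w_j))),

a noise ceiling (brain-to-brain predictivity extrapolated to an infinite
participant pool), representational-similarity and surprisal correlates of
predictivity, and the dependent-t / Bonferroni / MAD statistics used to
compare conditions.

## Worked example: perturbing a sentence

```python
from sentperturb import Token, Sentence, StimulusSet, apply_condition

words = ("it is in every beekeeper's interest to conserve local plants "
         "that produce pollen").split()
tags = ["NOUN", "VERB", "FUNCTION", "FUNCTION", "NOUN", "NOUN", "FUNCTION",
        "VERB", "ADJ", "NOUN", "FUNCTION", "VERB", "NOUN"]
sentence = Sentence("bee1", tuple(Token(w, t) for w, t in zip(words, tags)),
                    passage_id="p1", topic_id="beekeeping", experiment_id="E2",
                    position_in_passage=0)
stimuli = StimulusSet([sentence])
for condition in ["ReverseOrder", "LowPMI", "KeepContentW", "KeepN", "KeepFunctionW"]:
    out = apply_condition(condition, sentence, stimuli, rng_seed=0)
    print(f"{condition:>14}: {' '.join(out.surfaces)}.")
```

prints

```
  ReverseOrder: pollen produce that plants local conserve to interest beekeeper's every in is it.
        LowPMI: it beekeeper's conserve plants pollen in to every that is interest local produce.
  KeepContentW: it is beekeeper's interest conserve local plants produce pollen.
         KeepN: it beekeeper's interest plants pollen.
 KeepFunctionW: in every to that.
```

`ReverseOrder` destroys global order while exactly preserving the PMI
profile (the window is symmetric); `LowPMI` interleaves content and
function words to minimize local combinability; the `Keep*` conditions
delete everything outside a part-of-speech set while preserving order.

## Worked example: a synthetic encoding benchmark

```python
from sentperturb import (SynthConfig, gen_stimulus_set, gen_counts, gen_bigram_lm,
                         gen_brain, perturb_stimulus_set, SyntheticEmbeddingProvider,
                         encode_condition, EncodingModel, NoiseCeilingModel, seed_for)
from sentperturb.represent import encode_content_tokens
from sentperturb.synthdata import surprisal_noise

cfg = SynthConfig(seed=1)                      # the full 627-sentence structure
stimuli = gen_stimulus_set(cfg)
lm = gen_bigram_lm(gen_counts(cfg, n_sentences=2000))
kw = dict(seed=seed_for(1, "prov"), n_layers=6, dim=32)
provider = SyntheticEmbeddingProvider(token_noise=surprisal_noise(lm), **kw)
brain = gen_brain(stimuli, encode_content_tokens(stimuli, SyntheticEmbeddingProvider(**kw)), cfg)

stores = {"Original": encode_condition(stimuli, None, provider,
                                       "contextualized", "mean_token", condition="Original")}
pert = perturb_stimulus_set(stimuli, "KeepN", seed_for(1, "pert"))
stores["KeepN"] = encode_condition(stimuli, pert, provider,
                                   "contextualized", "mean_token", condition="KeepN")
results = EncodingModel(stimuli, brain, stores, "KeepN").fit()
print(results.summary())
ceiling = NoiseCeilingModel(brain, n_iter=2).fit(seed=1)
print(f"noise ceiling: {ceiling.asymptote:.3f}")
```

prints

```
Encoding benchmark results
==========================
condition:      KeepN
design:         TrainIntact-TestPerturbed_Contextualized
cv:             5-fold by sentence
participants:   5
layers:         6
best layer:     4 (median participant score 0.3800)

median score per layer:
  layer   1: +0.3323
  layer   2: +0.3416
  layer   3: +0.3398
  layer   4: +0.3800
  layer   5: +0.3480
  layer   6: +0.3432

noise ceiling: 0.883
```

The synthetic brain is a noisy linear readout of content-word
representations at layer 4 (1-based), so the benchmark recovers layer 4 as
the best-performing layer, and keeping only the nouns retains part — but
only part — of the planted signal (the Original condition scores ≈0.62 on
this world).  The ceiling of 0.883 is the extrapolated brain-to-brain
predictivity given the generator's noise level.

## Command line

The same pipeline is scriptable:

```bash
sentperturb run --seed 0 --out runs/demo          # simulate → perturb → embed → encode → analyze
sentperturb simulate --seed 0 --out runs/raw      # stimuli + count tables only
sentperturb perturb --stimuli runs/raw/stimuli.jsonl --condition ReverseOrder \
    --seed 0 --out runs/rev.jsonl
sentperturb report --scores runs/demo/scores.csv
```

Artifacts are plain files: JSON-lines stimuli, TSV counts, HDF5
representation stores and brain responses, tidy CSV score/similarity/
surprisal/statistics tables, a JSON ceiling estimate, and PNG figures.
Reruns with the same config and seed are bit-identical.

## Documentation

`docs/methods.md` describes the model and procedure in full: the encoding
benchmark and its design factors, every perturbation's defining constraint,
the PMI score and its conventions, the synthetic provider and what the
generator does and does not emulate, the noise-ceiling estimator, and the
statistics.
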