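"""Shared fixtures: the worked-example sentence, small synthetic worlds."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sentperturb.corpus import Sentence, StimulusSet, Token
from sentperturb.perturb import TableCounts
from sentperturb.represent import SyntheticEmbeddingProvider, encode_condition
from sentperturb.synthdata import (
    BrainSpec,
    ExperimentSpec,
    SynthConfig,
    gen_bigram_lm,
    gen_counts,
    gen_paraphrases,
    gen_stimulus_set,
)

# The running worked example: a beekeeping sentence with its coarse tagging
# (pronouns count as nouns; 'is' as verb).
EXAMPLE_WORDS = (
    "it is in every beekeeper's interest to conserve local plants that produce pollen"
).split()
EXAMPLE_TAGS = [
    "NOUN", "VERB", "FUNCTION", "FUNCTION", "NOUN", "NOUN", "FUNCTION",
    "VERB", "ADJ", "NOUN", "FUNCTION", "VERB", "NOUN",
]


@pytest.fixture(scope="session")
def example_sentence() -> Sentence:
    return Sentence(
        id="ex1",
        words=tuple(Token(w, t) for w, t in zip(EXAMPLE_WORDS, EXAMPLE_TAGS)),
        passage_id="p1",
        topic_id="t1",
        experiment_id="E",
        position_in_passage=0,
    )


@pytest.fixture(scope="session")
def example_context(example_sentence) -> StimulusSet:
    return StimulusSet([example_sentence])


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A scaled-down two-experiment study (209 sentences)."""
    return SynthConfig(
        experiments=(
            ExperimentSpec("E2", 8, 4, {4: 32}, (7, 18)),
            ExperimentSpec("E3", 8, 3, {3: 15, 4: 9}, (5, 20)),
        ),
        brain=BrainSpec(n_participants=4, n_voxels=30, reference_layer=3, noise_sigma=0.4),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_stimuli(small_cfg) -> StimulusSet:
    return gen_stimulus_set(small_cfg)


@pytest.fixture(scope="session")
def small_counts(small_cfg) -> TableCounts:
    return gen_counts(small_cfg, n_sentences=1200)


@pytest.fixture(scope="session")
def small_lm(small_counts):
    return gen_bigram_lm(small_counts)


@pytest.fixture(scope="session")
def small_paraphrases(small_stimuli, small_cfg):
    return gen_paraphrases(small_stimuli, small_cfg)


@pytest.fixture(scope="session")
def provider() -> SyntheticEmbeddingProvider:
    return SyntheticEmbeddingProvider(seed=42, n_layers=5, dim=24)


@pytest.fixture(scope="session")
def original_store(small_stimuli, provider):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return encode_condition(
            small_stimuli, None, provider, "contextualized", "mean_token",
            condition="Original",
        )


@pytest.fixture(scope="session")
def default_stimuli() -> StimulusSet:
    """The full printed stimulus structure (627 sentences)."""
    return gen_stimulus_set(SynthConfig())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
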