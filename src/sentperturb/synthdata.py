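"""Synthetic stimulus sets, count tables, a toy bigram LM, and voxel data.

Everything the pipeline consumes can be generated here as a pure function
of a configuration and a seed, so every stage is testable without any
download.  The default structure replicates the two-experiment reading
benchmark the pipeline targets: Experiment 2 with 96 four-sentence passages
in 24 topics (384 sentences, 7-18 words each) and Experiment 3 with 72
passages of three or four sentences (45 and 27 passages respectively, 243
sentences, 5-20 words each) in 24 further topics — 627 sentences in all.

Sentences come from a POS-template grammar over a pseudoword vocabulary, so
part-of-speech tags are known by construction; each topic owns a noun pool,
so same-topic sentences share vocabulary the way topically related passages
do.  Count tables and the bigram language model are harvested from a large
sample of the same grammar, which gives grammar-collocated word pairs
genuinely elevated PMI and makes scrambled sentences genuinely more
surprising than intact ones.

Voxel responses are noisy linear readouts of a reference layer's sentence
representations: a participant-shared readout plus a participant-specific
readout, a passage-level shared latent (which creates exactly the
train/test leakage that by-passage splitting removes), and independent
Gaussian noise.  The generative parameters are retained as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import Sentence, StimulusSet, Token
from .encode import BrainDataset
from .perturb import TableCounts, seed_for
from .represent import RepresentationStore

__all__ = [
    "ExperimentSpec",
    "VocabSpec",
    "BrainSpec",
    "SynthConfig",
    "gen_stimulus_set",
    "gen_counts",
    "gen_bigram_lm",
    "gen_paraphrases",
    "gen_brain",
    "BigramLM",
]

_FUNCTION_WORDS = (
    "the", "a", "of", "in", "to", "that", "and", "with", "for",
    "on", "by", "every", "some", "this", "as", "at",
)

_START = "<s>"


@dataclass(frozen=True)
class ExperimentSpec:
    """Structure of one experiment's materials."""

    name: str
    n_topics: int
    passages_per_topic: int
    passage_length_counts: Mapping[int, int]  # sentences-per-passage -> n passages
    sentence_length_range: tuple[int, int]

    def __post_init__(self) -> None:
        n_passages = sum(self.passage_length_counts.values())
        if n_passages != self.n_topics * self.passages_per_topic:
            raise ValueError(
                f"{self.name}: passage counts {n_passages} != "
                f"{self.n_topics} topics x {self.passages_per_topic} passages"
            )

    @property
    def n_sentences(self) -> int:
        return sum(k * v for k, v in self.passage_length_counts.items())


@dataclass(frozen=True)
class VocabSpec:
    """Vocabulary sizes per POS class."""

    nouns_per_topic: int = 8
    n_shared_nouns: int = 80
    n_verbs: int = 80
    n_adjs: int = 50
    n_advs: int = 30
    function_words: tuple[str, ...] = _FUNCTION_WORDS
    topic_noun_prob: float = 0.7  # P(draw a noun from the topic pool)


@dataclass(frozen=True)
class BrainSpec:
    """Generative model of the synthetic voxel responses."""

    n_participants: int = 5
    n_voxels: int = 50
    reference_layer: int = 3  # 0-based layer carrying the planted signal
    shared_scale: float = 1.0
    participant_scale: float = 0.2
    passage_signal_weight: float = 0.2
    noise_sigma: float = 0.5


def _default_experiments() -> tuple[ExperimentSpec, ExperimentSpec]:
    return (
        ExperimentSpec("E2", 24, 4, {4: 96}, (7, 18)),
        ExperimentSpec("E3", 24, 3, {3: 45, 4: 27}, (5, 20)),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Full synthetic-study configuration (structure, vocabulary, brain)."""

    experiments: tuple[ExperimentSpec, ...] = field(default_factory=_default_experiments)
    vocab: VocabSpec = VocabSpec()
    brain: BrainSpec = BrainSpec()
    seed: int = 0


# ---------------------------------------------------------------------------
# Vocabulary and grammar
# ---------------------------------------------------------------------------

_ONSETS = "b bl br c cl cr d dr f fl fr g gl gr h j k l m n p pl pr r s sk sl sm sp st t tr v w z".split()
_VOWELS = "a e i o u ai ea ee oa oo".split()
_CODAS = "b ck d g k l m n nd ng nt p r rd rn s st t x".split()


def _pseudoword(rng: np.random.Generator, n_syllables: int = 2) -> str:
    parts = []
    for i in range(n_syllables):
        parts.append(str(rng.choice(_ONSETS)))
        parts.append(str(rng.choice(_VOWELS)))
    parts.append(str(rng.choice(_CODAS)))
    return "".join(parts)


def _word_pool(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        w = _pseudoword(rng, int(rng.integers(1, 3)))
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


@dataclass
class _Vocabulary:
    topic_nouns: dict[str, list[str]]  # topic id -> noun pool
    shared_nouns: list[str]
    verbs: list[str]
    adjs: list[str]
    advs: list[str]
    function_words: tuple[str, ...]

    def pos_of(self) -> dict[str, str]:
        tags: dict[str, str] = {}
        for pool in self.topic_nouns.values():
            tags.update({w: "NOUN" for w in pool})
        tags.update({w: "NOUN" for w in self.shared_nouns})
        tags.update({w: "VERB" for w in self.verbs})
        tags.update({w: "ADJ" for w in self.adjs})
        tags.update({w: "ADV" for w in self.advs})
        tags.update({w: "FUNCTION" for w in self.function_words})
        return tags


def _topic_ids(cfg: SynthConfig) -> list[str]:
    return [
        f"{exp.name}.topic{t:02d}"
        for exp in cfg.experiments
        for t in range(exp.n_topics)
    ]


def _build_vocab(cfg: SynthConfig) -> _Vocabulary:
    rng = np.random.default_rng(seed_for(cfg.seed, "vocab"))
    taken = set(cfg.vocab.function_words)
    topics = _topic_ids(cfg)
    topic_nouns = {t: _word_pool(rng, cfg.vocab.nouns_per_topic, taken) for t in topics}
    return _Vocabulary(
        topic_nouns=topic_nouns,
        shared_nouns=_word_pool(rng, cfg.vocab.n_shared_nouns, taken),
        verbs=_word_pool(rng, cfg.vocab.n_verbs, taken),
        adjs=_word_pool(rng, cfg.vocab.n_adjs, taken),
        advs=_word_pool(rng, cfg.vocab.n_advs, taken),
        function_words=tuple(cfg.vocab.function_words),
    )


_CHUNKS = (
    ("FUNCTION", "NOUN", "VERB"),
    ("FUNCTION", "ADJ", "NOUN"),
    ("VERB", "FUNCTION", "NOUN"),
    ("FUNCTION", "NOUN", "ADV", "VERB"),
)


def _pos_template(length: int, rng: np.random.Generator) -> list[str]:
    """A POS sequence of exactly ``length`` starting FUNCTION NOUN VERB."""
    pattern = ["FUNCTION", "NOUN", "VERB"]
    while len(pattern) < length:
        pattern.extend(_CHUNKS[int(rng.integers(0, len(_CHUNKS)))])
    return pattern[:length]


def _fill_template(
    pattern: Sequence[str],
    topic: str,
    vocab: _Vocabulary,
    rng: np.random.Generator,
    topic_noun_prob: float,
) -> list[Token]:
    out = []
    for pos in pattern:
        if pos == "NOUN":
            if rng.random() < topic_noun_prob:
                pool = vocab.topic_nouns[topic]
            else:
                pool = vocab.shared_nouns
        elif pos == "VERB":
            pool = vocab.verbs
        elif pos == "ADJ":
            pool = vocab.adjs
        elif pos == "ADV":
            pool = vocab.advs
        else:
            pool = list(vocab.function_words)
        out.append(Token(str(pool[int(rng.integers(0, len(pool)))]), pos))
    return out


def _passage_lengths(exp: ExperimentSpec) -> list[list[int]]:
    """Sentences-per-passage for each topic (deterministic 45/27-style split)."""
    lengths: list[int] = []
    for n_sent, n_pass in sorted(exp.passage_length_counts.items(), reverse=True):
        lengths.extend([n_sent] * n_pass)
    # round-robin over topics keeps the mix even and deterministic
    return [lengths[t :: exp.n_topics] for t in range(exp.n_topics)]


def gen_stimulus_set(cfg: SynthConfig | None = None) -> StimulusSet:
    """Generate the hierarchical stimulus set described by ``cfg``."""
    cfg = cfg or SynthConfig()
    vocab = _build_vocab(cfg)
    sentences: list[Sentence] = []
    for exp in cfg.experiments:
        per_topic = _passage_lengths(exp)
        lo, hi = exp.sentence_length_range
        passage_no = 0
        for t in range(exp.n_topics):
            topic = f"{exp.name}.topic{t:02d}"
            for n_sent in per_topic[t]:
                passage = f"{exp.name}.pass{passage_no:03d}"
                passage_no += 1
                for pos_in_passage in range(n_sent):
                    sid = f"{passage}.s{pos_in_passage}"
                    rng = np.random.default_rng(seed_for(cfg.seed, "sentence", sid))
                    length = int(rng.integers(lo, hi + 1))
                    pattern = _pos_template(length, rng)
                    words = _fill_template(
                        pattern, topic, vocab, rng, cfg.vocab.topic_noun_prob
                    )
                    sentences.append(
                        Sentence(
                            id=sid,
                            words=tuple(words),
                            passage_id=passage,
                            topic_id=topic,
                            experiment_id=exp.name,
                            position_in_passage=pos_in_passage,
                        )
                    )
    return StimulusSet(sentences)


# ---------------------------------------------------------------------------
# Counts and bigram LM
# ---------------------------------------------------------------------------


def gen_counts(
    cfg: SynthConfig | None = None,
    n_sentences: int = 3000,
    window: int = 4,
) -> TableCounts:
    """Harvest count tables from a large sample of grammar-generated text.

    Counts include unigrams, unordered pairs within a sliding ``window``,
    and ordered adjacent bigrams (with a start symbol) for the bigram LM.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SynthConfig()
    vocab = _build_vocab(cfg)
    topics = _topic_ids(cfg)
    rng = np.random.default_rng(seed_for(cfg.seed, "counts"))
    uni: dict[str, int] = {}
    pairs: dict[tuple[str, str], int] = {}
    bigrams: dict[tuple[str, str], int] = {}
    lo = min(e.sentence_length_range[0] for e in cfg.experiments)
    hi = max(e.sentence_length_range[1] for e in cfg.experiments)
    span = window - 1
    for _ in range(n_sentences):
        topic = topics[int(rng.integers(0, len(topics)))]
        length = int(rng.integers(lo, hi + 1))
        pattern = _pos_template(length, rng)
        words = [t.surface for t in _fill_template(pattern, topic, vocab, rng, cfg.vocab.topic_noun_prob)]
        prev = _START
        for i, w in enumerate(words):
            uni[w] = uni.get(w, 0) + 1
            bigrams[(prev, w)] = bigrams.get((prev, w), 0) + 1
            prev = w
            for j in range(i + 1, min(i + span, len(words) - 1) + 1):
                a, b = sorted((w, words[j]))
                pairs[(a, b)] = pairs.get((a, b), 0) + 1
    return TableCounts(uni, pairs, bigrams)


@dataclass
class BigramLM:
    """Laplace-smoothed bigram next-word model; surprisal in nats."""

    counts: TableCounts
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if not self.counts.bigrams:
            raise ValueError("counts table carries no bigram section")
        self._row_totals: dict[str, int] = {}
        for (a, _), c in self.counts.bigrams.items():
            self._row_totals[a] = self._row_totals.get(a, 0) + c
        self._vocab = sorted(self.counts.unigrams)

    @property
    def vocab(self) -> list[str]:
        return self._vocab

    def prob(self, word: str, prev: str | None) -> float:
        prev = _START if prev is None else prev
        V = len(self._vocab)
        c = self.counts.bigrams.get((prev, word), 0)
        total = self._row_totals.get(prev, 0)
        return (c + self.alpha) / (total + self.alpha * V)

    def surprisal(self, word: str, prev: str | None) -> float:
        return -float(np.log(self.prob(word, prev)))

    def mean_corpus_surprisal(self) -> float:
        """Count-weighted mean bigram surprisal of the harvested corpus."""
        total_c = 0
        total_s = 0.0
        for (a, b), c in self.counts.bigrams.items():
            total_s += c * self.surprisal(b, None if a == _START else a)
            total_c += c
        return total_s / total_c


def gen_bigram_lm(counts: TableCounts, alpha: float = 0.1) -> BigramLM:
    """Build the bigram language-model provider from harvested counts."""
    return BigramLM(counts, alpha=alpha)


def surprisal_noise(lm: BigramLM, weight: float = 2.0, power: float = 2.0, cap: float = 4.0):
    """Per-token degradation scales for the embedding provider.

    A token's scale grows with its bigram surprisal in excess of the
    corpus-typical surprisal (zero for tokens at or below it, raised to
    ``power`` so that strongly improbable junctions are penalized
    disproportionately), emulating a trained network whose representations
    degrade on inputs unlike its training distribution — the generative
    link between predictability and predictivity.  Tokens outside the
    model's vocabulary (e.g., the terminal period) get scale 0.
    """
    mu = lm.mean_corpus_surprisal()
    vocab = set(lm.vocab)

    def scales(tokens):
        out = np.zeros(len(tokens))
        prev = None
        for i, w in enumerate(tokens):
            if w in vocab:
                s = lm.surprisal(w, prev if (prev in vocab or prev is None) else None)
                out[i] = min(cap, weight * (max(0.0, s - mu) / mu) ** power)
            prev = w
        return out

    return scales


# ---------------------------------------------------------------------------
# Paraphrases
# ---------------------------------------------------------------------------


def gen_paraphrases(
    stimuli: StimulusSet,
    cfg: SynthConfig | None = None,
    keep_prob: float = 0.5,
) -> dict[str, list[str]]:
    """Synthetic paraphrases: keep roughly half the words, replace the rest
    with same-POS alternatives (topic nouns stay topical).

    Emulates human-written paraphrases only in their lexical-overlap
    statistics, not in meaning.
    """
    cfg = cfg or SynthConfig()
    vocab = _build_vocab(cfg)
    out: dict[str, list[str]] = {}
    for s in stimuli:
        rng = np.random.default_rng(seed_for(cfg.seed, "paraphrase", s.id))
        words = []
        for tok in s.words:
            if rng.random() < keep_prob:
                words.append(tok.surface)
                continue
            replacement = _fill_template(
                [tok.pos if tok.pos != "UNKNOWN" else "NOUN"],
                s.topic_id, vocab, rng, cfg.vocab.topic_noun_prob,
            )[0]
            words.append(replacement.surface)
        out[s.id] = words
    return out


# ---------------------------------------------------------------------------
# Brain data
# ---------------------------------------------------------------------------


def _unit_variance(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return (M - M.mean(axis=0)) / sd


def gen_brain(
    stimuli: StimulusSet,
    reference: RepresentationStore,
    cfg: SynthConfig | None = None,
) -> BrainDataset:
    """Generate multi-participant voxel responses with planted structure.

    Per participant p, voxel responses are

        Y_p = shared_scale * readout(X) + participant_scale * readout_p(X)
              + passage_signal_weight * L[passage] + sigma * noise_p

    where X is the reference store's signal-layer sentence matrix
    (column-standardized), the readouts are random linear maps whose outputs
    are standardized per voxel, L is a per-passage latent shared across
    participants, and noise is independent standard Gaussian.  All weights
    and latents are returned as ground truth.
    """
    cfg = cfg or SynthConfig()
    spec = cfg.brain
    if not 0 <= spec.reference_layer < reference.n_layers:
        raise ValueError("reference_layer outside the store's layer range")
    ids = list(stimuli.sentence_ids)
    if reference.sentence_ids != ids:
        reference = reference.reindex(ids)
    X = _unit_variance(reference.layer(spec.reference_layer))
    n, dim = X.shape
    V = spec.n_voxels
    rng = np.random.default_rng(seed_for(cfg.seed, "brain"))
    W_shared = rng.standard_normal((dim, V)) / np.sqrt(dim)
    signal = _unit_variance(X @ W_shared)
    passages = [s.passage_id for s in stimuli]
    unique_passages = list(dict.fromkeys(passages))
    latents = {p: rng.standard_normal(V) for p in unique_passages}
    L = np.stack([latents[p] for p in passages])
    responses: dict[str, np.ndarray] = {}
    W_parts: dict[str, np.ndarray] = {}
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        prng = np.random.default_rng(seed_for(cfg.seed, "brain", pid))
        W_p = prng.standard_normal((dim, V)) / np.sqrt(dim)
        W_parts[pid] = W_p
        part = _unit_variance(X @ W_p)
        noise = prng.standard_normal((n, V))
        responses[pid] = (
            spec.shared_scale * signal
            + spec.participant_scale * part
            + spec.passage_signal_weight * L
            + spec.noise_sigma * noise
        )
    return BrainDataset(
        sentence_ids=ids,
        experiment_of={s.id: s.experiment_id for s in stimuli},
        responses=responses,
        ground_truth={
            "reference_layer": spec.reference_layer,
            "W_shared": W_shared,
            "W_participants": W_parts,
            "passage_latents": latents,
            "shared_scale": spec.shared_scale,
            "participant_scale": spec.participant_scale,
            "passage_signal_weight": spec.passage_signal_weight,
            "noise_sigma": spec.noise_sigma,
            "seed": cfg.seed,
        },
    )
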