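"""Controlled sentence perturbations and the windowed positive-PMI score.

Twenty conditions are supported, grouped into five categories:

* original       -- the unchanged sentence.
* word-order     -- permutations of the sentence's words: local adjacent
                    swaps at a controlled adjacent-transposition distance
                    (1/3/5/7), full reversal, and two orderings that minimize
                    local pointwise mutual information (PMI).
* information-loss -- stable-order deletion of words by part of speech
                    (keep content words / N+V+Adj / N+V / N only / function
                    words only).
* semantic-distance -- replacement of the sentence by another sentence from
                    the same passage, the same topic, anywhere in the
                    experiment (each via constrained derangements), or by a
                    supplied paraphrase.
* control        -- length-matched random word lists, random noun lists
                    matched to the KeepN length, and a single-filler
                    length control.

A string's PMI score averages the positive PMI of all word pairs inside a
four-word sliding window (bigrams, 1-skip-grams and 2-skip-grams), with
Laplace-smoothed probabilities from a pluggable counts provider:

    score(w_1..w_n) = 1/(3n-2) * sum_{i<j<=i+3} max(0, log P(wi,wj)/(P(wi)P(wj)))

The 1/(3n-2) normalizer is the printed form; ``PmiConfig(normalizer="pairs")``
divides by the actual number of window pairs (3n-6 for n >= 4) instead.
Because the window is symmetric and pair counts are unordered, the score is
exactly invariant under word-order reversal.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np

from .corpus import CONTENT_POS, Sentence, StimulusSet, Token

__all__ = [
    "CONDITION_CATEGORY",
    "CONDITIONS",
    "CATEGORIES",
    "PerturbedStimulus",
    "CountsProvider",
    "TableCounts",
    "PmiConfig",
    "UngenerableCondition",
    "seed_for",
    "pmi_score",
    "adjacent_transposition_distance",
    "local_word_swaps",
    "reverse_order",
    "low_pmi_deterministic",
    "low_pmi_random",
    "keep_pos_subset",
    "make_control",
    "derange",
    "group_constrained_shuffle",
    "paraphrase_overlap",
    "apply_condition",
    "perturb_stimulus_set",
]

#: Condition name -> category, fixed mapping.
CONDITION_CATEGORY: dict[str, str] = {
    "Original": "original",
    "1LocalWordSwap": "word-order",
    "3LocalWordSwaps": "word-order",
    "5LocalWordSwaps": "word-order",
    "7LocalWordSwaps": "word-order",
    "ReverseOrder": "word-order",
    "LowPMI": "word-order",
    "LowPMIRandom": "word-order",
    "KeepContentW": "information-loss",
    "KeepNVAdj": "information-loss",
    "KeepNV": "information-loss",
    "KeepN": "information-loss",
    "KeepFunctionW": "information-loss",
    "Paraphrase": "semantic-distance",
    "RandSentFromPassage": "semantic-distance",
    "RandSentFromTopic": "semantic-distance",
    "RandSent": "semantic-distance",
    "RandWordList": "control",
    "RandN": "control",
    "LengthControl": "control",
}

CONDITIONS = tuple(CONDITION_CATEGORY)
CATEGORIES = ("original", "word-order", "information-loss", "semantic-distance", "control")

_SWAP_K = {"1LocalWordSwap": 1, "3LocalWordSwaps": 3, "5LocalWordSwaps": 5, "7LocalWordSwaps": 7}
_KEEP_SETS = {
    "KeepContentW": frozenset({"NOUN", "VERB", "ADJ", "ADV"}),
    "KeepNVAdj": frozenset({"NOUN", "VERB", "ADJ"}),
    "KeepNV": frozenset({"NOUN", "VERB"}),
    "KeepN": frozenset({"NOUN"}),
}


class UngenerableCondition(RuntimeError):
    """A condition could not be realized for a sentence (e.g., too short)."""


@dataclass(frozen=True)
class PerturbedStimulus:
    """One sentence under one condition, with generation provenance."""

    condition: str
    sentence_id: str
    words: tuple[Token, ...]
    seed: int
    achieved_swap_distance: int | None = None
    pmi_score: float | None = None
    source_sentence_id: str | None = None

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.words)


class CountsProvider(Protocol):
    """Contract for unigram and unordered-pair count tables."""

    n_unigrams: int  # total unigram tokens counted
    n_pairs: int  # total pairs counted
    vocab_size: int

    def unigram_count(self, w: str) -> int: ...

    def pair_count(self, w1: str, w2: str) -> int: ...


@dataclass
class TableCounts:
    """Dict-backed counts provider; pair counts are unordered (symmetric).

    Optionally carries ordered adjacent-bigram counts for building a bigram
    language model on the same corpus sample.
    """

    unigrams: dict[str, int] = field(default_factory=dict)
    pairs: dict[tuple[str, str], int] = field(default_factory=dict)
    bigrams: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = {}
        for (a, b), c in self.pairs.items():
            key = (a, b) if a <= b else (b, a)
            canon[key] = canon.get(key, 0) + c
        self.pairs = canon

    @property
    def n_unigrams(self) -> int:
        return sum(self.unigrams.values())

    @property
    def n_pairs(self) -> int:
        return sum(self.pairs.values())

    @property
    def vocab_size(self) -> int:
        return len(self.unigrams)

    def unigram_count(self, w: str) -> int:
        return self.unigrams.get(w, 0)

    def pair_count(self, w1: str, w2: str) -> int:
        key = (w1, w2) if w1 <= w2 else (w2, w1)
        return self.pairs.get(key, 0)

    # -- TSV round-trip (sections: UNIGRAMS / PAIRS / BIGRAMS) ----------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#UNIGRAMS\n")
            for w, c in sorted(self.unigrams.items()):
                fh.write(f"{w}\t{c}\n")
            fh.write("#PAIRS\n")
            for (a, b), c in sorted(self.pairs.items()):
                fh.write(f"{a}\t{b}\t{c}\n")
            if self.bigrams:
                fh.write("#BIGRAMS\n")
                for (a, b), c in sorted(self.bigrams.items()):
                    fh.write(f"{a}\t{b}\t{c}\n")

    @classmethod
    def from_tsv(cls, path) -> "TableCounts":
        uni: dict[str, int] = {}
        pairs: dict[tuple[str, str], int] = {}
        bigrams: dict[tuple[str, str], int] = {}
        section = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    section = line[1:].strip().upper()
                    continue
                parts = line.split("\t")
                if section == "UNIGRAMS":
                    uni[parts[0]] = int(parts[1])
                elif section == "PAIRS":
                    pairs[(parts[0], parts[1])] = int(parts[2])
                elif section == "BIGRAMS":
                    bigrams[(parts[0], parts[1])] = int(parts[2])
        return cls(uni, pairs, bigrams)


@dataclass(frozen=True)
class PmiConfig:
    """Settings for the windowed positive-PMI score.

    alpha: Laplace smoothing constant added to every count.
    window: sliding window width in words (pairs span at most window-1).
    normalizer: "printed" uses 1/(3n-2); "pairs" divides by the number of
        window pairs actually scored.
    """

    alpha: float = 0.1
    window: int = 4
    normalizer: str = "printed"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.normalizer not in ("printed", "pairs"):
            raise ValueError("normalizer must be 'printed' or 'pairs'")


def seed_for(master_seed: int, *keys) -> int:
    """Derive a stable 31-bit child seed from a master seed and string keys."""
    h = hashlib.sha256(("|".join([str(master_seed), *map(str, keys)])).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# PMI
# ---------------------------------------------------------------------------


def pmi_score(
    words: Sequence[str], counts: CountsProvider, cfg: PmiConfig | None = None
) -> float:
    """Mean positive PMI over all word pairs within a sliding window.

    Probabilities are Laplace smoothed: P(w) = (c(w)+a)/(N_uni+aV) and
    P(w1,w2) = (c(w1,w2)+a)/(N_pair+aV^2). Natural logarithm. Returns 0 for
    a single-word input (no pairs).
    """
    cfg = cfg or PmiConfig()
    n = len(words)
    if n == 0:
        raise ValueError("empty word list")
    a = cfg.alpha
    V = counts.vocab_size
    denom_uni = counts.n_unigrams + a * V
    denom_pair = counts.n_pairs + a * V * V
    span = cfg.window - 1
    total = 0.0
    n_pairs = 0
    for i in range(n - 1):
        for j in range(i + 1, min(i + span, n - 1) + 1):
            p1 = (counts.unigram_count(words[i]) + a) / denom_uni
            p2 = (counts.unigram_count(words[j]) + a) / denom_uni
            p12 = (counts.pair_count(words[i], words[j]) + a) / denom_pair
            total += max(0.0, math.log(p12 / (p1 * p2)))
            n_pairs += 1
    if cfg.normalizer == "printed":
        denom = 3 * n - 2
    else:
        denom = max(n_pairs, 1)
    return total / denom


# ---------------------------------------------------------------------------
# Word-order manipulations
# ---------------------------------------------------------------------------


def _stable_permutation(orig: Sequence[str], perturbed: Sequence[str]) -> list[int]:
    """Map perturbed positions to original positions, resolving duplicate
    words by original order (stable assignment)."""
    if sorted(orig) != sorted(perturbed):
        raise ValueError("perturbed words are not a permutation of the original")
    queues: dict[str, list[int]] = {}
    for idx, w in enumerate(orig):
        queues.setdefault(w, []).append(idx)
    pointers = {w: 0 for w in queues}
    perm = []
    for w in perturbed:
        perm.append(queues[w][pointers[w]])
        pointers[w] += 1
    return perm


def adjacent_transposition_distance(
    orig_words: Sequence[str], perturbed_words: Sequence[str]
) -> int:
    """Minimum number of adjacent transpositions converting orig into
    perturbed (Kendall tau distance, i.e. inversion count of the induced
    permutation; duplicates resolved by stable assignment)."""
    perm = _stable_permutation(orig_words, perturbed_words)
    n = len(perm)
    inversions = 0
    for i in range(n):
        for j in range(i + 1, n):
            if perm[i] > perm[j]:
                inversions += 1
    return inversions


def local_word_swaps(
    words: Sequence[str],
    k: int,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> list[str]:
    """Swap k randomly chosen words with an immediate neighbor so that the
    achieved adjacent-transposition distance is exactly k.

    Whole swap sequences are resampled until the verified distance equals k
    (individual swaps can undo each other, and swaps of identical words are
    invisible). Raises :class:`UngenerableCondition` when the attempt budget
    is exhausted, which can happen for very short sentences.
    """
    n = len(words)
    if k == 0:
        return list(words)
    if n < k + 1:
        raise UngenerableCondition(f"need at least {k + 1} words for {k} swaps, got {n}")
    for _ in range(max_attempts):
        out = list(words)
        for _ in range(k):
            i = int(rng.integers(0, n))
            if i == 0:
                j = 1
            elif i == n - 1:
                j = n - 2
            else:
                j = i + int(rng.choice([-1, 1]))
            out[i], out[j] = out[j], out[i]
        if adjacent_transposition_distance(words, out) == k:
            return out
    raise UngenerableCondition(
        f"could not realize exactly {k} adjacent transpositions in {max_attempts} attempts"
    )


def reverse_order(words: Sequence[str]) -> list[str]:
    """Reverse the order of the words."""
    return list(words)[::-1]


def low_pmi_deterministic(words: Sequence[str], tags: Sequence[str]) -> list[str]:
    """Deterministic low-PMI reordering by content/function interleaving.

    Words are split into content and function classes; within each class the
    odd-positioned (1st, 3rd, ... in original order) and even-positioned
    words form separate lists, which are concatenated as
    [odd content | odd function | even function | even content].  This places
    all function words between the two content lists, maximizing the linear
    distance between originally adjacent content words.  Degenerates
    gracefully to two lists for all-content or all-function sentences.
    """
    if len(tags) != len(words):
        raise ValueError("tags length mismatch")
    content = [w for w, t in zip(words, tags) if t in CONTENT_POS]
    function = [w for w, t in zip(words, tags) if t not in CONTENT_POS]
    odd_c, even_c = content[0::2], content[1::2]
    odd_f, even_f = function[0::2], function[1::2]
    return odd_c + odd_f + even_f + even_c


def low_pmi_random(
    words: Sequence[str],
    rng: np.random.Generator,
    scorer: Callable[[Sequence[str]], float],
    n_candidates: int = 10,
    excluded: Iterable[Sequence[str]] = (),
    max_attempts: int = 10_000,
) -> tuple[list[str], float]:
    """Lowest-PMI pick among random whole-sentence permutations.

    Draws ``n_candidates`` distinct random permutations that are neither the
    original order nor in ``excluded`` (the realized local-swap outputs for
    the same sentence), scores each, and returns the argmin candidate with
    its score.
    """
    banned = {tuple(words)} | {tuple(e) for e in excluded}
    candidates: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(candidates) < n_candidates:
        attempts += 1
        if attempts > max_attempts:
            raise UngenerableCondition(
                f"could not draw {n_candidates} admissible permutations"
            )
        cand = tuple(rng.permutation(list(words)).tolist())
        if cand in banned or cand in seen:
            continue
        seen.add(cand)
        candidates.append(cand)
    scores = [scorer(c) for c in candidates]
    best = int(np.argmin(scores))
    return list(candidates[best]), float(scores[best])


# ---------------------------------------------------------------------------
# Information loss and controls
# ---------------------------------------------------------------------------


def keep_pos_subset(
    words: Sequence[str], tags: Sequence[str], keep: frozenset[str] | set[str]
) -> list[str]:
    """Retain only words whose POS is in ``keep``, preserving order.

    An empty result is permitted (some sentences have no words of the kept
    classes); callers decide how to record it.
    """
    if len(tags) != len(words):
        raise ValueError("tags length mismatch")
    return [w for w, t in zip(words, tags) if t in keep]


def make_control(
    condition: str,
    sentence_words: Sequence[str],
    rng: np.random.Generator,
    pool: Sequence[str] | None = None,
    target_length: int | None = None,
    filler: str = "the",
) -> list[str]:
    """Control conditions: RandWordList / RandN / LengthControl.

    RandWordList draws length(sentence) words without replacement from the
    pooled dataset word list; RandN draws ``target_length`` nouns from the
    dataset noun pool; LengthControl repeats a single filler word.
    """
    n = len(sentence_words)
    if condition == "LengthControl":
        return [filler] * n
    if condition == "RandWordList":
        want = n
    elif condition == "RandN":
        if target_length is None:
            raise ValueError("RandN needs target_length (the KeepN output length)")
        want = target_length
    else:
        raise ValueError(f"not a control condition: {condition}")
    if pool is None:
        raise ValueError(f"{condition} needs a word pool")
    if len(pool) < want:
        raise UngenerableCondition(f"pool of {len(pool)} exhausted (need {want})")
    idx = rng.choice(len(pool), size=want, replace=False)
    return [pool[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# Derangements and constrained shuffles
# ---------------------------------------------------------------------------


def derange(ids: Sequence, rng: np.random.Generator, max_attempts: int = 10_000) -> dict:
    """Random fixed-point-free permutation of ``ids`` (rejection sampling)."""
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("no derangement exists for fewer than 2 elements")
    idx = np.arange(len(ids))
    for _ in range(max_attempts):
        perm = rng.permutation(len(ids))
        if not np.any(perm == idx):
            return {ids[i]: ids[int(perm[i])] for i in range(len(ids))}
    raise RuntimeError("derangement attempt budget exhausted")  # pragma: no cover


def group_constrained_shuffle(
    ids: Sequence,
    group_of: Mapping,
    rng: np.random.Generator,
) -> tuple[dict, float]:
    """Derange ids within each group; singletons stay put.

    Returns the permutation map and the fraction of ids left unmoved
    (singleton groups are the only source of fixed points).
    """
    ids = list(ids)
    groups: dict = {}
    for i in ids:
        groups.setdefault(group_of[i], []).append(i)
    mapping: dict = {}
    unmoved = 0
    for members in groups.values():
        if len(members) < 2:
            mapping[members[0]] = members[0]
            unmoved += 1
        else:
            mapping.update(derange(members, rng))
    fraction = unmoved / len(ids) if ids else 0.0
    return mapping, fraction


def paraphrase_overlap(
    original_words: Sequence[str], paraphrase_words: Sequence[str]
) -> tuple[float, int]:
    """Word-multiset overlap fraction (relative to the original length) and
    the paraphrase-minus-original length difference."""
    if not original_words or not paraphrase_words:
        raise ValueError("both word lists must be non-empty")
    from collections import Counter

    inter = Counter(original_words) & Counter(paraphrase_words)
    overlap = sum(inter.values()) / len(original_words)
    return overlap, len(paraphrase_words) - len(original_words)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def _tags_of(sentence: Sentence) -> tuple[str, ...]:
    return sentence.pos_tags


def _retag(words: Sequence[str], sentence: Sentence) -> tuple[Token, ...]:
    """Carry POS tags over to a permuted/subset word sequence (stable by
    original occurrence order for duplicates)."""
    queues: dict[str, list[str]] = {}
    for t in sentence.words:
        queues.setdefault(t.surface, []).append(t.pos)
    pointers = {w: 0 for w in queues}
    out = []
    for w in words:
        if w in queues and pointers[w] < len(queues[w]):
            out.append(Token(w, queues[w][pointers[w]]))
            pointers[w] += 1
        else:
            out.append(Token(w))
    return tuple(out)


def _semantic_distance_maps(
    context: StimulusSet, condition: str, master_seed: int, within_experiment: bool = True
) -> dict[str, str]:
    """Dataset-level replacement map for the semantic-distance conditions.

    For each experiment (or the pooled set when ``within_experiment`` is
    False), sentences are deranged within passages (RandSentFromPassage),
    within topics (RandSentFromTopic), or across the whole group (RandSent);
    singleton groups keep their own sentence.
    """
    mapping: dict[str, str] = {}
    scopes = (
        [context.experiment(e) for e in context.experiment_ids()]
        if within_experiment
        else [context]
    )
    for scope in scopes:
        ids = scope.sentence_ids
        rng = np.random.default_rng(
            seed_for(master_seed, condition, scope.sentences[0].experiment_id if within_experiment else "pooled")
        )
        if condition == "RandSent":
            group_of = {i: "all" for i in ids}
        elif condition == "RandSentFromPassage":
            group_of = scope.passage_of()
        elif condition == "RandSentFromTopic":
            group_of = scope.topic_of()
        else:
            raise ValueError(condition)
        m, _ = group_constrained_shuffle(ids, group_of, rng)
        mapping.update(m)
    return mapping


def _word_pool(context: StimulusSet, nouns_only: bool = False) -> list[str]:
    pool = []
    for s in context:
        for t in s.words:
            if not nouns_only or t.pos == "NOUN":
                pool.append(t.surface)
    return pool


def apply_condition(
    condition: str,
    sentence: Sentence,
    context: StimulusSet,
    rng_seed: int,
    counts: CountsProvider | None = None,
    pmi_cfg: PmiConfig | None = None,
    paraphrases: Mapping[str, Sequence[str]] | None = None,
    filler: str = "the",
) -> PerturbedStimulus:
    """Apply one perturbation condition to one sentence.

    ``rng_seed`` is the master seed for the whole perturbed data set: the
    per-sentence stream is derived from (seed, condition, sentence id), so
    results are bit-reproducible and independent across sentences and
    conditions.  Dataset-level conditions (semantic-distance replacements and
    word-pool controls) derive their shared structure from the same master
    seed, so applying the condition sentence-by-sentence agrees with
    :func:`perturb_stimulus_set`.
    """
    if condition not in CONDITION_CATEGORY:
        raise ValueError(f"unknown condition: {condition}")
    words = list(sentence.surfaces)
    tags = list(_tags_of(sentence))
    rng = np.random.default_rng(seed_for(rng_seed, condition, sentence.id))
    swap_distance: int | None = None
    score: float | None = None
    source_id: str | None = None

    if condition == "Original":
        out = words
    elif condition in _SWAP_K:
        k = _SWAP_K[condition]
        out = local_word_swaps(words, k, rng)
        swap_distance = adjacent_transposition_distance(words, out)
    elif condition == "ReverseOrder":
        out = reverse_order(words)
    elif condition == "LowPMI":
        out = low_pmi_deterministic(words, tags)
    elif condition == "LowPMIRandom":
        if counts is None:
            raise ValueError("LowPMIRandom needs a counts provider")
        cfg = pmi_cfg or PmiConfig()
        excluded = []
        for swap_cond, k in _SWAP_K.items():
            if len(words) >= k + 1:
                srng = np.random.default_rng(seed_for(rng_seed, swap_cond, sentence.id))
                try:
                    excluded.append(local_word_swaps(words, k, srng))
                except UngenerableCondition:
                    pass
        out, score = low_pmi_random(
            words, rng, lambda ws: pmi_score(ws, counts, cfg), excluded=excluded
        )
    elif condition in _KEEP_SETS:
        out = keep_pos_subset(words, tags, _KEEP_SETS[condition])
    elif condition == "KeepFunctionW":
        out = keep_pos_subset(words, tags, frozenset({"FUNCTION", "PUNCT", "UNKNOWN"}))
    elif condition in ("RandSent", "RandSentFromPassage", "RandSentFromTopic"):
        mapping = _semantic_distance_maps(context, condition, rng_seed)
        source_id = mapping[sentence.id]
        source = context[source_id]
        return PerturbedStimulus(
            condition=condition,
            sentence_id=sentence.id,
            words=source.words,
            seed=rng_seed,
            source_sentence_id=source_id,
        )
    elif condition == "Paraphrase":
        if paraphrases is None or sentence.id not in paraphrases:
            raise ValueError(f"no paraphrase supplied for sentence {sentence.id}")
        out = list(paraphrases[sentence.id])
    elif condition == "RandWordList":
        out = make_control(condition, words, rng, pool=_word_pool(context))
    elif condition == "RandN":
        keep_n = keep_pos_subset(words, tags, frozenset({"NOUN"}))
        out = make_control(
            condition, words, rng, pool=_word_pool(context, nouns_only=True),
            target_length=len(keep_n),
        )
    elif condition == "LengthControl":
        out = make_control(condition, words, rng, filler=filler)
    else:  # pragma: no cover
        raise ValueError(condition)

    if not out:
        warnings.warn(
            f"condition {condition} empties sentence {sentence.id}; keeping empty output"
        )
    return PerturbedStimulus(
        condition=condition,
        sentence_id=sentence.id,
        words=_retag(out, sentence),
        seed=rng_seed,
        achieved_swap_distance=swap_distance,
        pmi_score=score,
        source_sentence_id=source_id,
    )


def perturb_stimulus_set(
    stimuli: StimulusSet,
    condition: str,
    seed: int,
    counts: CountsProvider | None = None,
    pmi_cfg: PmiConfig | None = None,
    paraphrases: Mapping[str, Sequence[str]] | None = None,
    filler: str = "the",
    on_ungenerable: str = "skip",
) -> dict[str, PerturbedStimulus]:
    """Apply one condition to every sentence of a stimulus set.

    Returns sentence id -> perturbed stimulus.  Sentences for which the
    condition cannot be realized (e.g., too short for 7 local swaps) are
    skipped with a warning when ``on_ungenerable="skip"``, or raise when
    ``"raise"``.
    """
    if condition in ("RandSent", "RandSentFromPassage", "RandSentFromTopic"):
        mapping = _semantic_distance_maps(stimuli, condition, seed)
        return {
            s.id: PerturbedStimulus(
                condition=condition,
                sentence_id=s.id,
                words=stimuli[mapping[s.id]].words,
                seed=seed,
                source_sentence_id=mapping[s.id],
            )
            for s in stimuli
        }
    out: dict[str, PerturbedStimulus] = {}
    for s in stimuli:
        try:
            out[s.id] = apply_condition(
                condition, s, stimuli, seed,
                counts=counts, pmi_cfg=pmi_cfg, paraphrases=paraphrases, filler=filler,
            )
        except UngenerableCondition as exc:
            if on_ungenerable == "raise":
                raise
            warnings.warn(f"sentence {s.id}: {condition} ungenerable ({exc}); skipped")
    return out
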