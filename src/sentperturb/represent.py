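"""Per-layer sentence representations under a pluggable embedding provider.

An :class:`EmbeddingProvider` maps a token sequence to a stack of per-layer
token vectors (shape ``n_layers x n_tokens x dim``).  A sentence summary is
either the vector of the last token — the terminal-period token, since a
unidirectional encoder has already aggregated the sentence by then — or the
arithmetic mean over the sentence's tokens.

Sentences can be encoded *contextualized* (preceded by the perturbed
versions of the earlier sentences in their passage, mirroring how the
passage was presented to readers) or *decontextualized* (the sentence
alone).  The synthetic provider stands in for a pretrained network: each
word has a fixed pseudo-random base vector, and a token's layer-l vector is
a layer-specific squashed mixing of that base vector, a positional signal,
and a context term (the running average of preceding token vectors, weighted
by ``context_weight``).  It is deterministic given its seed, and layers are
related nonlinearly, so a linear readout planted at one layer is best
predicted from that layer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .corpus import Sentence, StimulusSet
from .perturb import PerturbedStimulus

__all__ = [
    "EmbeddingProvider",
    "SyntheticEmbeddingProvider",
    "RepresentationStore",
    "summarize",
    "build_input",
    "encode_condition",
    "encode_content_tokens",
]

CONTEXT_MODES = ("contextualized", "decontextualized")
SUMMARY_MODES = ("last_token", "mean_token")

#: Token used to render the terminal period when feeding a provider.
PERIOD = "."


class EmbeddingProvider(Protocol):
    """Contract: deterministic per-layer token embeddings."""

    n_layers: int
    dim: int

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        """Return an array of shape (n_layers, n_tokens, dim)."""
        ...


def summarize(token_vectors: np.ndarray, mode: str) -> np.ndarray:
    """Summarize token vectors (n_tokens x dim) into a single vector."""
    if token_vectors.ndim != 2 or token_vectors.shape[0] == 0:
        raise ValueError("need at least one token vector")
    if mode == "last_token":
        return np.asarray(token_vectors[-1])
    if mode == "mean_token":
        return np.asarray(token_vectors.mean(axis=0))
    raise ValueError(f"unknown summary mode: {mode}")


def build_input(
    sentence: Sentence,
    passage_sentences: Sequence[Sentence],
    context_mode: str,
    perturbed: Mapping[str, PerturbedStimulus] | None = None,
) -> tuple[list[str], slice]:
    """Assemble the provider input for one sentence.

    Contextualized inputs prepend the (equally perturbed) earlier sentences
    of the passage; decontextualized inputs contain the target alone.  The
    returned slice marks the target sentence's tokens (terminal period
    included) within the token sequence.
    """
    if context_mode not in CONTEXT_MODES:
        raise ValueError(f"unknown context mode: {context_mode}")

    def tokens_for(s: Sentence) -> list[str]:
        if perturbed is not None and s.id in perturbed:
            words = list(perturbed[s.id].surfaces)
        else:
            words = list(s.surfaces)
        if s.has_terminal_period:
            words.append(PERIOD)
        return words

    prefix: list[str] = []
    if context_mode == "contextualized":
        for prev in sorted(passage_sentences, key=lambda s: s.position_in_passage):
            if prev.position_in_passage < sentence.position_in_passage:
                prefix.extend(tokens_for(prev))
    target = tokens_for(sentence)
    return prefix + target, slice(len(prefix), len(prefix) + len(target))


def _hash_unit_vector(key: str, dim: int, seed: int) -> np.ndarray:
    h = hashlib.sha256(f"{seed}|{key}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(h[:8], "big"))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


@dataclass
class SyntheticEmbeddingProvider:
    """Deterministic word-hash embedding provider with tunable context use.

    Parameters
    ----------
    seed : master seed; fixes every base vector and mixing matrix.
    n_layers, dim : representation geometry.
    context_weight : weight (lambda in [0, 1]) of the running average of the
        preceding tokens' base vectors; 0 makes every token vector
        independent of its context.
    context_decay : recency discount of the running context average (weight
        of a token one step further back is multiplied by this); a value
        below 1 makes the context term — and hence the terminal-token
        summary — weakly sensitive to word order, not just word identity.
    positional_weight : weight of a per-position pseudo-random signal; 0
        makes mean-token summaries exactly order-invariant when
        context_weight is also 0.
    layer_gain : gain applied before the tanh squashing; larger gains
        saturate more, making layers less linearly redundant (so the layer
        carrying a planted readout is identifiable by the encoding model).
    token_noise : optional callable mapping a token sequence to per-token
        noise scales (>= 0).  Each token's vector is perturbed by its scale
        times a deterministic pseudo-random direction keyed on the token and
        its predecessor.  Wiring a surprisal model in here emulates how a
        trained network's representations degrade on inputs unlike its
        training distribution, planting a predictability-predictivity link.
    """

    seed: int = 0
    n_layers: int = 6
    dim: int = 32
    context_weight: float = 0.3
    positional_weight: float = 0.1
    context_decay: float = 0.8
    layer_gain: float = 2.5
    token_noise: Callable[[Sequence[str]], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.context_weight <= 1.0:
            raise ValueError("context_weight must be in [0, 1]")
        rng = np.random.default_rng(self.seed)
        # per-layer mixing matrices; tanh squashing makes layers nonlinearly
        # related so a readout planted at one layer is identifiable
        self._mix = rng.standard_normal((self.n_layers, self.dim, self.dim)) / np.sqrt(self.dim)
        self._word_cache: dict[str, np.ndarray] = {}
        self._pos_cache: dict[int, np.ndarray] = {}

    def _word_vec(self, word: str) -> np.ndarray:
        if word not in self._word_cache:
            self._word_cache[word] = _hash_unit_vector(f"word:{word}", self.dim, self.seed)
        return self._word_cache[word]

    def _pos_vec(self, t: int) -> np.ndarray:
        if t not in self._pos_cache:
            self._pos_cache[t] = _hash_unit_vector(f"pos:{t}", self.dim, self.seed)
        return self._pos_cache[t]

    def _noise_vec(self, word: str, prev: str | None) -> np.ndarray:
        return _hash_unit_vector(f"noise:{prev}|{word}", self.dim, self.seed)

    def encode(
        self, tokens: Sequence[str], context_mask: Sequence[bool] | None = None
    ) -> np.ndarray:
        """Per-layer token vectors (n_layers, n_tokens, dim).

        ``context_mask`` optionally restricts which tokens feed the running
        context average; masked-out tokens still occupy a time step (their
        recency discount is consumed), so deleting them from the input is
        not equivalent to masking them.
        """
        if len(tokens) == 0:
            raise ValueError("empty token sequence")
        n = len(tokens)
        if context_mask is not None and len(context_mask) != n:
            raise ValueError("context_mask length mismatch")
        base = np.stack([self._word_vec(w) for w in tokens])  # (n, dim)
        raw = base.copy()
        if self.positional_weight:
            # positions indexed from the sequence end: the target sentence is
            # always the suffix of the input, so with context_weight=0 its
            # token vectors do not depend on how much context precedes it
            raw = raw + self.positional_weight * np.stack(
                [self._pos_vec(n - 1 - t) for t in range(n)]
            )
        if self.context_weight:
            # recency-discounted running average of preceding base vectors
            # (strictly causal; discount < 1 makes it order-sensitive)
            ctx = np.zeros_like(base)
            running = np.zeros(self.dim)
            norm = 0.0
            g = self.context_decay
            for t in range(1, n):
                include = context_mask is None or context_mask[t - 1]
                running = g * running + (base[t - 1] if include else 0.0)
                norm = g * norm + (1.0 if include else 0.0)
                ctx[t] = running / norm if norm > 0 else 0.0
            raw = raw + self.context_weight * ctx
        if self.token_noise is not None:
            scales = np.asarray(self.token_noise(list(tokens)), dtype=float)
            if scales.shape != (n,):
                raise ValueError("token_noise must return one scale per token")
            if np.any(scales > 0):
                prevs = [None, *tokens[:-1]]
                noise = np.stack(
                    [
                        self._noise_vec(w, p) if s > 0 else np.zeros(self.dim)
                        for w, p, s in zip(tokens, prevs, scales)
                    ]
                )
                raw = raw + scales[:, None] * noise
        out = np.empty((self.n_layers, n, self.dim))
        for layer in range(self.n_layers):
            out[layer] = np.tanh(self.layer_gain * (raw @ self._mix[layer].T))
        return out


@dataclass
class RepresentationStore:
    """Summary vectors for one (condition, context mode, summary mode).

    ``array`` has shape (n_sentences, n_layers, dim); rows follow
    ``sentence_ids`` order.  Layers are 0-based internally and 1-based in
    reports.
    """

    condition: str
    context_mode: str
    summary_mode: str
    sentence_ids: list[str]
    array: np.ndarray
    provider_name: str = ""

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 3 or self.array.shape[0] != len(self.sentence_ids):
            raise ValueError("array must be (n_sentences, n_layers, dim) aligned to ids")
        if not np.all(np.isfinite(self.array)):
            raise ValueError("representation vectors must be finite")
        self._row = {sid: i for i, sid in enumerate(self.sentence_ids)}

    @property
    def n_layers(self) -> int:
        return self.array.shape[1]

    @property
    def dim(self) -> int:
        return self.array.shape[2]

    def layer(self, layer: int) -> np.ndarray:
        """Matrix (n_sentences x dim) at a 0-based layer index."""
        return self.array[:, layer, :]

    def vector(self, sentence_id: str, layer: int) -> np.ndarray:
        return self.array[self._row[sentence_id], layer, :]

    def rows(self, sentence_ids: Sequence[str], layer: int) -> np.ndarray:
        idx = [self._row[s] for s in sentence_ids]
        return self.array[idx, layer, :]

    def reindex(self, sentence_ids: Sequence[str]) -> "RepresentationStore":
        idx = [self._row[s] for s in sentence_ids]
        return RepresentationStore(
            self.condition, self.context_mode, self.summary_mode,
            list(sentence_ids), self.array[idx], self.provider_name,
        )

    # -- HDF5 round-trip -------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["condition"] = self.condition
            fh.attrs["context_mode"] = self.context_mode
            fh.attrs["summary_mode"] = self.summary_mode
            fh.attrs["provider_name"] = self.provider_name
            fh.create_dataset("sentence_ids", data=np.array(self.sentence_ids, dtype="S"))
            for layer in range(self.n_layers):
                fh.create_dataset(f"layer{layer:03d}", data=self.array[:, layer, :])

    # -- CSV-per-layer fallback dialect ---------------------------------
    def to_csv_dir(self, directory: str | Path) -> None:
        """One CSV per layer (rows: sentence_id followed by the vector)."""
        import csv as _csv
        import json as _json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "store.json").write_text(_json.dumps({
            "condition": self.condition,
            "context_mode": self.context_mode,
            "summary_mode": self.summary_mode,
            "provider_name": self.provider_name,
            "n_layers": self.n_layers,
        }))
        for layer in range(self.n_layers):
            with open(directory / f"layer{layer:03d}.csv", "w", newline="") as fh:
                writer = _csv.writer(fh)
                writer.writerow(["sentence_id", *range(self.dim)])
                for sid, row in zip(self.sentence_ids, self.array[:, layer, :]):
                    writer.writerow([sid, *(repr(float(v)) for v in row)])

    @classmethod
    def from_csv_dir(cls, directory: str | Path) -> "RepresentationStore":
        import csv as _csv
        import json as _json

        directory = Path(directory)
        meta = _json.loads((directory / "store.json").read_text())
        layers = []
        ids: list[str] = []
        for layer in range(meta["n_layers"]):
            with open(directory / f"layer{layer:03d}.csv", newline="") as fh:
                reader = _csv.reader(fh)
                next(reader)
                rows = list(reader)
            if layer == 0:
                ids = [r[0] for r in rows]
            layers.append(np.array([[float(v) for v in r[1:]] for r in rows]))
        return cls(
            condition=meta["condition"],
            context_mode=meta["context_mode"],
            summary_mode=meta["summary_mode"],
            sentence_ids=ids,
            array=np.stack(layers, axis=1),
            provider_name=meta.get("provider_name", ""),
        )

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "RepresentationStore":
        import h5py

        with h5py.File(path, "r") as fh:
            ids = [s.decode() for s in fh["sentence_ids"][()]]
            layers = sorted(k for k in fh.keys() if k.startswith("layer"))
            array = np.stack([fh[k][()] for k in layers], axis=1)
            return cls(
                condition=fh.attrs["condition"],
                context_mode=fh.attrs["context_mode"],
                summary_mode=fh.attrs["summary_mode"],
                sentence_ids=ids,
                array=array,
                provider_name=fh.attrs.get("provider_name", ""),
            )


def encode_content_tokens(
    stimuli: StimulusSet,
    provider: "SyntheticEmbeddingProvider",
    context_mode: str = "contextualized",
) -> RepresentationStore:
    """Content-word sentence representations for planting synthetic brains.

    Each sentence is summarized as the mean of its *content-word* token
    vectors, with the provider's context average restricted to content words
    while recency is still measured in full-sentence time (function words
    occupy time steps but contribute nothing).  This emulates a
    meaning-driven neural code: blind to function words as such, yet
    sensitive to the timing of content words around them — so deleting
    function words changes the code even though they are never read out.
    """
    from .corpus import CONTENT_POS

    ids: list[str] = []
    vectors: list[np.ndarray] = []
    for pid in stimuli.passage_ids():
        passage = stimuli.passage(pid)
        for sentence in passage:
            tokens, span = build_input(sentence, passage, context_mode, None)

            def content_flags(s: Sentence) -> list[bool]:
                flags = [t.pos in CONTENT_POS for t in s.words]
                if s.has_terminal_period:
                    flags.append(False)
                return flags

            mask: list[bool] = []
            if context_mode == "contextualized":
                for prev in sorted(passage, key=lambda s: s.position_in_passage):
                    if prev.position_in_passage < sentence.position_in_passage:
                        mask.extend(content_flags(prev))
            target_flags = content_flags(sentence)
            mask.extend(target_flags)
            if not any(target_flags):
                raise ValueError(f"sentence {sentence.id} has no content words")
            stack = provider.encode(tokens, context_mask=mask)[:, span, :]
            sel = stack[:, np.asarray(target_flags), :]
            vectors.append(sel.mean(axis=1))
            ids.append(sentence.id)
    order = {sid: i for i, sid in enumerate(ids)}
    perm = [order[sid] for sid in stimuli.sentence_ids]
    return RepresentationStore(
        condition="ContentTokens",
        context_mode=context_mode,
        summary_mode="mean_token",
        sentence_ids=list(stimuli.sentence_ids),
        array=np.stack(vectors)[perm],
        provider_name=type(provider).__name__,
    )


def encode_condition(
    stimuli: StimulusSet,
    perturbed: Mapping[str, PerturbedStimulus] | None,
    provider: EmbeddingProvider,
    context_mode: str = "contextualized",
    summary_mode: str = "last_token",
    condition: str | None = None,
) -> RepresentationStore:
    """Encode every sentence of a stimulus set under one condition.

    ``perturbed`` maps sentence id to its perturbed form (None or a missing
    id means the original words are used — the Original condition).
    Sentences whose perturbed form is empty are represented by the terminal
    period alone when present, else skipped with the provider's error.
    """
    if condition is None:
        condition = perturbed[next(iter(perturbed))].condition if perturbed else "Original"
    ids: list[str] = []
    vectors: list[np.ndarray] = []
    for pid in stimuli.passage_ids():
        passage = stimuli.passage(pid)
        for sentence in passage:
            tokens, span = build_input(sentence, passage, context_mode, perturbed)
            if span.stop == span.start:
                raise ValueError(f"sentence {sentence.id}: empty token sequence")
            stack = provider.encode(tokens)  # (n_layers, n_tokens, dim)
            target = stack[:, span, :]
            vectors.append(
                np.stack([summarize(target[l], summary_mode) for l in range(provider.n_layers)])
            )
            ids.append(sentence.id)
    order = {sid: i for i, sid in enumerate(ids)}
    # keep the stimulus set's global sentence order
    perm = [order[sid] for sid in stimuli.sentence_ids]
    array = np.stack(vectors)[perm]
    return RepresentationStore(
        condition=condition,
        context_mode=context_mode,
        summary_mode=summary_mode,
        sentence_ids=list(stimuli.sentence_ids),
        array=array,
        provider_name=type(provider).__name__,
    )
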