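"""Stimulus data model, text normalization, and stimulus file I/O.

The stimulus sets modeled here are hierarchically organized reading
materials: an *experiment* contains *topics*, a topic contains short
*passages*, and a passage is an ordered sequence of *sentences*.  Sentences
are normalized to lowercase, whitespace-delimited word tokens with all
sentence-internal punctuation removed except hyphens and apostrophes.  The
terminal sentence period is carried as metadata rather than as a word, so
word-level perturbations operate on words only and the period is re-appended
when a sentence is rendered back to text.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Token",
    "Sentence",
    "StimulusSet",
    "StimulusSchemaError",
    "normalize_text",
    "render_words",
    "read_stimuli",
    "write_stimuli",
    "CONTENT_POS",
    "POS_LABELS",
]

#: Coarse part-of-speech labels. Pronouns and proper names count as NOUN.
POS_LABELS = ("NOUN", "VERB", "ADJ", "ADV", "FUNCTION", "PUNCT", "UNKNOWN")

#: The content-word classes; everything else is treated as a function word.
CONTENT_POS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})

# Characters retained inside words: letters, digits, hyphen, apostrophe.
_STRIP_RE = re.compile(r"[^\w\s'\-]", re.UNICODE)
_QUOTES = str.maketrans({"’": "'", "‘": "'", "–": "-", "—": "-"})


@dataclass(frozen=True)
class Token:
    """A single lowercase word with an optional coarse POS label."""

    surface: str
    pos: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("Token surface must be non-empty")
        if self.pos not in POS_LABELS:
            raise ValueError(f"unknown POS label: {self.pos!r}")

    @property
    def is_content(self) -> bool:
        return self.pos in CONTENT_POS


def normalize_text(raw: str) -> tuple[list[str], bool]:
    """Normalize raw sentence text to word surfaces plus a period flag.

    Lowercases, strips all sentence-internal punctuation except hyphens and
    apostrophes, and records whether the sentence ended with a period.  The
    terminal period is metadata, not a word.

    Returns
    -------
    (words, has_terminal_period)

    Raises
    ------
    ValueError
        If the input is empty or normalizes to zero words.
    """
    if raw is None or not raw.strip():
        raise ValueError("empty stimulus text")
    text = raw.strip().translate(_QUOTES)
    has_period = text.endswith(".")
    text = text.lower()
    text = _STRIP_RE.sub(" ", text)
    # underscore sneaks through \w; it is punctuation for our purposes
    text = text.replace("_", " ")
    # interior hyphens/apostrophes survive; bare or edge punctuation is shed
    words = [w for w in (chunk.strip("'-") for chunk in text.split()) if w]
    if not words:
        raise ValueError(f"stimulus normalizes to zero words: {raw!r}")
    return words, has_period


def render_words(words: Sequence[str], has_terminal_period: bool = True) -> str:
    """Render a word sequence back to a flat string, re-appending the period."""
    text = " ".join(words)
    return text + "." if has_terminal_period else text


@dataclass(frozen=True)
class Sentence:
    """One stimulus sentence with its position in the hierarchy.

    ``words`` excludes the terminal period, which is tracked by
    ``has_terminal_period``.
    """

    id: str
    words: tuple[Token, ...]
    passage_id: str
    topic_id: str
    experiment_id: str
    position_in_passage: int
    has_terminal_period: bool = True

    def __post_init__(self) -> None:
        if len(self.words) < 1:
            raise ValueError(f"sentence {self.id}: needs at least one word")
        if self.position_in_passage < 0:
            raise ValueError(f"sentence {self.id}: negative position_in_passage")

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.words)

    @property
    def pos_tags(self) -> tuple[str, ...]:
        return tuple(t.pos for t in self.words)

    @property
    def text(self) -> str:
        return render_words(self.surfaces, self.has_terminal_period)

    def with_tags(self, tags: Sequence[str]) -> "Sentence":
        if len(tags) != len(self.words):
            raise ValueError("tag sequence length mismatch")
        toks = tuple(Token(t.surface, p) for t, p in zip(self.words, tags))
        return replace(self, words=toks)


class StimulusSchemaError(ValueError):
    """A stimulus record violates the file schema (reported with record number)."""


@dataclass
class StimulusSet:
    """Hierarchical container: experiments -> topics -> passages -> sentences.

    Sentences are stored in a stable global order (file/creation order);
    helper accessors slice by experiment, topic, and passage.
    """

    sentences: list[Sentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        seen_ids: set[str] = set()
        passage_topic: dict[str, tuple[str, str]] = {}
        topic_exp: dict[str, str] = {}
        for s in self.sentences:
            if s.id in seen_ids:
                raise StimulusSchemaError(f"duplicate sentence id: {s.id}")
            seen_ids.add(s.id)
            key = (s.topic_id, s.experiment_id)
            if s.passage_id in passage_topic and passage_topic[s.passage_id] != key:
                raise StimulusSchemaError(
                    f"passage {s.passage_id} assigned to more than one topic/experiment"
                )
            passage_topic[s.passage_id] = key
            if s.topic_id in topic_exp and topic_exp[s.topic_id] != s.experiment_id:
                raise StimulusSchemaError(
                    f"topic {s.topic_id} appears in more than one experiment"
                )
            topic_exp[s.topic_id] = s.experiment_id
        for pid in self.passage_ids():
            sents = self.passage(pid)
            positions = sorted(s.position_in_passage for s in sents)
            if positions != list(range(len(sents))):
                raise StimulusSchemaError(
                    f"passage {pid}: positions {positions} are not 0..{len(sents) - 1}"
                )

    # -- accessors -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    def __getitem__(self, sentence_id: str) -> Sentence:
        index = self.__dict__.get("_by_id")
        if index is None or len(index) != len(self.sentences):
            index = {s.id: s for s in self.sentences}
            self.__dict__["_by_id"] = index
        try:
            return index[sentence_id]
        except KeyError:
            raise KeyError(sentence_id) from None

    @property
    def sentence_ids(self) -> list[str]:
        return [s.id for s in self.sentences]

    def experiment_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.sentences:
            if s.experiment_id not in out:
                out.append(s.experiment_id)
        return out

    def experiment(self, experiment_id: str) -> "StimulusSet":
        return StimulusSet([s for s in self.sentences if s.experiment_id == experiment_id])

    def topic_ids(self, experiment_id: str | None = None) -> list[str]:
        out: list[str] = []
        for s in self.sentences:
            if experiment_id is not None and s.experiment_id != experiment_id:
                continue
            if s.topic_id not in out:
                out.append(s.topic_id)
        return out

    def passage_ids(self, topic_id: str | None = None) -> list[str]:
        out: list[str] = []
        for s in self.sentences:
            if topic_id is not None and s.topic_id != topic_id:
                continue
            if s.passage_id not in out:
                out.append(s.passage_id)
        return out

    def passage(self, passage_id: str) -> list[Sentence]:
        sents = [s for s in self.sentences if s.passage_id == passage_id]
        return sorted(sents, key=lambda s: s.position_in_passage)

    def passage_of(self) -> dict[str, str]:
        """sentence id -> passage id"""
        return {s.id: s.passage_id for s in self.sentences}

    def topic_of(self) -> dict[str, str]:
        return {s.id: s.topic_id for s in self.sentences}

    def structure_summary(self) -> dict:
        """Counts per hierarchy level, per experiment and overall."""
        per_exp = {}
        for eid in self.experiment_ids():
            sub = [s for s in self.sentences if s.experiment_id == eid]
            topics = {s.topic_id for s in sub}
            passages = {s.passage_id for s in sub}
            per_exp[eid] = {
                "n_topics": len(topics),
                "n_passages": len(passages),
                "n_sentences": len(sub),
                "mean_sentences_per_passage": len(sub) / len(passages),
            }
        return {
            "experiments": per_exp,
            "n_sentences": len(self.sentences),
            "n_passages": len({s.passage_id for s in self.sentences}),
            "n_topics": len({s.topic_id for s in self.sentences}),
        }


# -- file I/O ------------------------------------------------------------

_FIELDS = [
    "experiment_id",
    "topic_id",
    "passage_id",
    "position_in_passage",
    "sentence_id",
    "text",
]


def _sentence_from_record(rec: Mapping, recno: int) -> Sentence:
    missing = [f for f in _FIELDS if f not in rec or rec[f] in (None, "")]
    if missing:
        raise StimulusSchemaError(f"record {recno}: missing fields {missing}")
    try:
        pos = int(rec["position_in_passage"])
    except (TypeError, ValueError) as exc:
        raise StimulusSchemaError(f"record {recno}: bad position_in_passage") from exc
    try:
        words, period = normalize_text(str(rec["text"]))
    except ValueError as exc:
        raise StimulusSchemaError(f"record {recno}: {exc}") from exc
    tags = rec.get("pos_tags")
    if tags:
        if isinstance(tags, str):
            tags = tags.split()
        if len(tags) != len(words):
            raise StimulusSchemaError(
                f"record {recno}: pos_tags length {len(tags)} != {len(words)} words"
            )
        toks = tuple(Token(w, p) for w, p in zip(words, tags))
    else:
        toks = tuple(Token(w) for w in words)
    return Sentence(
        id=str(rec["sentence_id"]),
        words=toks,
        passage_id=str(rec["passage_id"]),
        topic_id=str(rec["topic_id"]),
        experiment_id=str(rec["experiment_id"]),
        position_in_passage=pos,
        has_terminal_period=bool(period),
    )


def read_stimuli(path: str | Path) -> StimulusSet:
    """Read a stimulus file (JSON-lines, or TSV when suffixed .tsv)."""
    path = Path(path)
    records: list[Mapping] = []
    if path.suffix.lower() == ".tsv":
        with open(path, newline="") as fh:
            records = list(csv.DictReader(fh, delimiter="\t"))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise StimulusSchemaError(f"record {lineno}: invalid JSON") from exc
    sentences = [_sentence_from_record(rec, i + 1) for i, rec in enumerate(records)]
    return StimulusSet(sentences)


def write_stimuli(stimuli: StimulusSet | Iterable[Sentence], path: str | Path) -> None:
    """Write stimuli as JSON-lines (or TSV when suffixed .tsv)."""
    path = Path(path)
    sents = list(stimuli)
    rows = []
    for s in sents:
        rows.append(
            {
                "experiment_id": s.experiment_id,
                "topic_id": s.topic_id,
                "passage_id": s.passage_id,
                "position_in_passage": s.position_in_passage,
                "sentence_id": s.id,
                "text": s.text,
                "pos_tags": " ".join(s.pos_tags),
            }
        )
    if path.suffix.lower() == ".tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()), delimiter="\t")
            writer.writeheader()
            writer.writerows(rows)
    else:
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
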