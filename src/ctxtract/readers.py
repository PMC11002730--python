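"""Reader contract and deterministic desk-scale readers.

A *reader* is any object with ``predict(question, context) ->
ReaderPrediction``: the pluggable machine-reading-comprehension model that
turns a question and a context string into an extractive answer plus a
real-valued confidence.  A fine-tuned transformer reader plugs in through
the same contract — a thin adapter mapping (question, context) to its
predicted span text and, for confidence, the sum of its start and end span
scores — but no test requires one; the two readers shipped here are
deterministic so that every downstream number is reproducible:

* :class:`ScriptedReader` — a controllable test double.  Each question has
  a planted answer sentence and support sentences; the answer is emitted
  iff the answer sentence is present in the context AND at least
  ``min_support`` support sentences are present, with confidence growing
  linearly in the number of supports.  This reproduces the qualitative
  behaviour of real extractive readers on partial contexts: relevant but
  insufficient context yields an abstention at low confidence.
* :class:`OverlapReader` — an unscripted fallback that answers with the
  context sentence sharing the most normalized tokens with the question.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

from . import metrics
from .corpus import segment_sentences

__all__ = [
    "ReaderPrediction",
    "Reader",
    "QuestionScript",
    "ScriptedReaderSpec",
    "ScriptedReader",
    "OverlapReader",
    "CachingReader",
]


@dataclass(frozen=True)
class ReaderPrediction:
    """An extractive answer (or abstention) with a confidence score.

    ``confidence`` is unbounded and only required to be comparable across
    contexts for the same question.  ``char_span`` (into the supplied
    context) is present only when the answer text was located verbatim.
    """

    answer_text: str | None
    confidence: float
    char_span: tuple[int, int] | None = None

    @property
    def is_abstention(self) -> bool:
        return metrics.is_abstention(self.answer_text)


@runtime_checkable
class Reader(Protocol):
    def predict(self, question: str, context: str) -> ReaderPrediction: ...


@dataclass(frozen=True)
class QuestionScript:
    """Planted behaviour for one question of a scripted reader."""

    answer_text: str
    answer_sentence: str
    support_sentences: tuple[str, ...]
    min_support: int

    def __post_init__(self):
        if self.answer_sentence in self.support_sentences:
            raise ValueError("answer sentence must not be listed as a support")
        if not 0 <= self.min_support <= len(self.support_sentences):
            raise ValueError("min_support must be within [0, #supports]")


@dataclass
class ScriptedReaderSpec:
    """Answer key for a synthetic corpus: per-question scripts + confidences."""

    questions: dict[str, QuestionScript] = field(default_factory=dict)
    c_base: float = 2.0
    c_per_support: float = 1.5
    c_abstain: float = 0.5

    def __post_init__(self):
        if self.c_base < 0 or self.c_per_support < 0:
            raise ValueError("confidence constants must be non-negative")

    def to_dict(self) -> dict:
        return {
            "c_base": self.c_base,
            "c_per_support": self.c_per_support,
            "c_abstain": self.c_abstain,
            "questions": {
                q: {
                    "answer_text": s.answer_text,
                    "answer_sentence": s.answer_sentence,
                    "support_sentences": list(s.support_sentences),
                    "min_support": s.min_support,
                }
                for q, s in self.questions.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScriptedReaderSpec":
        return cls(
            questions={
                q: QuestionScript(
                    answer_text=s["answer_text"],
                    answer_sentence=s["answer_sentence"],
                    support_sentences=tuple(s["support_sentences"]),
                    min_support=int(s["min_support"]),
                )
                for q, s in payload["questions"].items()
            },
            c_base=float(payload["c_base"]),
            c_per_support=float(payload["c_per_support"]),
            c_abstain=float(payload["c_abstain"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ScriptedReaderSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


class ScriptedReader:
    """Deterministic reader driven by a :class:`ScriptedReaderSpec`.

    Sentence membership is decided by exact sentence-text containment in
    the context string (contexts are assembled from whole sentences, so
    containment is unambiguous).
    """

    def __init__(self, spec: ScriptedReaderSpec):
        self.spec = spec

    def predict(self, question: str, context: str) -> ReaderPrediction:
        script = self.spec.questions.get(question)
        if script is None or not context:
            return ReaderPrediction(None, self.spec.c_abstain)
        present = sum(1 for s in script.support_sentences if s in context)
        if script.answer_sentence in context and present >= script.min_support:
            confidence = self.spec.c_base + self.spec.c_per_support * present
            start = context.find(script.answer_text)
            span = (start, start + len(script.answer_text)) if start >= 0 else None
            return ReaderPrediction(script.answer_text, confidence, span)
        return ReaderPrediction(None, self.spec.c_abstain)


class OverlapReader:
    """Answer with the context sentence most lexically similar to the question.

    Confidence is the multiset token overlap with the question; the answer
    is the best sentence's text with question tokens removed; zero overlap
    everywhere (or an empty context) yields an abstention.  Ties go to the
    earliest sentence.
    """

    def predict(self, question: str, context: str) -> ReaderPrediction:
        from collections import Counter

        q_counts = Counter(metrics.normalize(question))
        best_overlap, best_sentence = 0, None
        for sentence in segment_sentences(context):
            s_counts = Counter(metrics.normalize(sentence.text))
            overlap = sum((q_counts & s_counts).values())
            if overlap > best_overlap:
                best_overlap, best_sentence = overlap, sentence
        if best_sentence is None:
            return ReaderPrediction(None, 0.0)
        q_tokens = set(q_counts)
        answer_words = [
            w
            for w in best_sentence.text.split()
            if metrics.normalize(w) and metrics.normalize(w)[0] not in q_tokens
        ]
        answer = " ".join(answer_words) or best_sentence.text
        return ReaderPrediction(answer, float(best_overlap))


class CachingReader:
    """Memoizes predictions keyed on (question, exact context string).

    Leave-one-sentence-out utilities over S sentences need S+1 reader
    calls per question; the shared full-context call is computed once.
    """

    def __init__(self, reader: Reader):
        self.reader = reader
        self._cache: dict[tuple[str, str], ReaderPrediction] = {}

    def predict(self, question: str, context: str) -> ReaderPrediction:
        key = (question, context)
        if key not in self._cache:
            self._cache[key] = self.reader.predict(question, context)
        return self._cache[key]

    @property
    def n_calls(self) -> int:
        return len(self._cache)
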