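"""Token-level answer scoring for extractive question answering.

Predictions and gold references are compared after SQuAD-style
normalization: lowercase, strip punctuation (so hyphenated tokens merge),
drop the English articles ``a``/``an``/``the``, and split on whitespace.
Precision is the fraction of predicted tokens that occur in the gold
reference (multiset overlap), recall the fraction of gold tokens recovered,
and F1 their harmonic mean.  A reader that abstains scores 0 against a
non-empty gold answer and 1 against an empty one.
"""

from __future__ import annotations

import json
import unicodedata
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

__all__ = [
    "AnswerScore",
    "normalize",
    "token_f1",
    "best_over_references",
    "exact_match",
    "is_abstention",
    "write_scores_jsonl",
]

_ARTICLES = frozenset({"a", "an", "the"})


@dataclass(frozen=True)
class AnswerScore:
    """Precision/recall/F1 of one prediction against one (or the best) gold."""

    precision: float
    recall: float
    f1: float
    exact_match: bool

    def as_dict(self) -> dict:
        return asdict(self)


def is_abstention(text: str | None) -> bool:
    """True when the reader declined to answer (``None`` or blank string)."""
    return text is None or text.strip() == ""


def _strip_punctuation(text: str) -> str:
    # Unicode-aware: category P* covers ASCII punctuation plus en/em dashes,
    # curly quotes etc.  Removal (not replacement by space) deliberately
    # merges hyphenated tokens: "adjuvant-like" -> "adjuvantlike".
    return "".join(ch for ch in text if not unicodedata.category(ch).startswith("P"))


def normalize(text: str | None) -> list[str]:
    """Normalize a string to a token sequence.

    Lowercase, remove punctuation (merging across hyphens), drop articles,
    split on whitespace.  ``None`` and blank strings yield an empty list.
    """
    if text is None:
        return []
    tokens = _strip_punctuation(text.lower()).split()
    return [t for t in tokens if t not in _ARTICLES]


def token_f1(prediction: str | None, gold: str | None) -> AnswerScore:
    """Multiset token precision/recall/F1 between a prediction and one gold."""
    pred_abstains = is_abstention(prediction)
    gold_abstains = is_abstention(gold)
    if pred_abstains or gold_abstains:
        hit = pred_abstains and gold_abstains
        v = 1.0 if hit else 0.0
        return AnswerScore(precision=v, recall=v, f1=v, exact_match=hit)

    pred_tokens = normalize(prediction)
    gold_tokens = normalize(gold)
    if pred_tokens == gold_tokens:
        # Covers strings that normalize to the same sequence, including the
        # degenerate case where both collapse to nothing ("a" vs "the");
        # keeps exact_match => f1 == 1 unconditionally.
        return AnswerScore(precision=1.0, recall=1.0, f1=1.0, exact_match=True)
    overlap = sum((Counter(pred_tokens) & Counter(gold_tokens)).values())
    precision = overlap / len(pred_tokens) if pred_tokens else 0.0
    recall = overlap / len(gold_tokens) if gold_tokens else 0.0
    if precision + recall == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return AnswerScore(
        precision=precision,
        recall=recall,
        f1=f1,
        exact_match=pred_tokens == gold_tokens,
    )


def best_over_references(
    prediction: str | None, golds: Sequence[str]
) -> AnswerScore:
    """Best :func:`token_f1` over multiple gold references (ties: first)."""
    if not golds:
        raise ValueError("golds must be non-empty")
    best = None
    for gold in golds:
        score = token_f1(prediction, gold)
        if best is None or score.f1 > best.f1:
            best = score
    return best


def exact_match(prediction: str | None, golds: Sequence[str]) -> bool:
    """True iff the normalized prediction equals any normalized reference."""
    if not golds:
        raise ValueError("golds must be non-empty")
    return any(token_f1(prediction, gold).exact_match for gold in golds)


def write_scores_jsonl(records: Iterable[dict], path) -> None:
    """Write per-example score records as JSON-lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
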