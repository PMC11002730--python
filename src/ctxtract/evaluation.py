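"""Dataset-level answer evaluation under competing context policies.

Each policy decides which text the reader sees for a question:

``original``         the full article;
``retriever_topk``   the top-k retrieved paragraphs, concatenated;
``target_paragraph`` the paragraph(s) containing the gold sentence(s);
``extraction``       the utility-peak extracted context;
``random_paragraph`` a uniformly drawn paragraph (a floor reference).

Per-question records carry the reader prediction, its multi-reference
answer F1 and exact match, the context length in sentences, and whether
the gold sentence made it into the context — the last flag lets the
significant-change analysis separate failures of context selection from
failures of the reader itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import metrics
from .corpus import Article, QAExample, target_paragraphs
from .extraction import ExtractionParams, baseline_context, extract_context
from .readers import Reader, ReaderPrediction
from .scoring import Embedder, HashedBowEmbedder, SentenceScorer, rank_paragraphs

__all__ = [
    "POLICIES",
    "EvalRecord",
    "PolicyResult",
    "ChangeTally",
    "evaluate_policy",
    "significant_changes",
    "write_records_jsonl",
]

POLICIES = (
    "original",
    "retriever_topk",
    "target_paragraph",
    "extraction",
    "random_paragraph",
)


@dataclass(frozen=True)
class EvalRecord:
    qid: str
    context_policy: str
    prediction: ReaderPrediction
    answer_f1: float
    exact_match: bool
    context_len_sentences: int
    gold_in_context: bool

    def to_dict(self) -> dict:
        return {
            "qid": self.qid,
            "context_policy": self.context_policy,
            "answer_text": self.prediction.answer_text,
            "confidence": self.prediction.confidence,
            "answer_f1": self.answer_f1,
            "exact_match": self.exact_match,
            "context_len_sentences": self.context_len_sentences,
            "gold_in_context": self.gold_in_context,
        }


@dataclass(frozen=True)
class PolicyResult:
    policy: str
    mean_f1: float
    mean_em: float
    records: tuple[EvalRecord, ...]
    n_reader_failures: int = 0


@dataclass(frozen=True)
class ChangeTally:
    """Counts of significant answer-F1 changes between two policies."""

    better: int
    worse: int
    worse_with_good_context: int
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "better": self.better,
            "worse": self.worse,
            "worse_with_good_context": self.worse_with_good_context,
            "threshold": self.threshold,
        }


def _policy_context(
    example: QAExample,
    article: Article,
    policy: str,
    *,
    params: ExtractionParams | None,
    scorers: Mapping[str, SentenceScorer] | None,
    embedder: Embedder,
    k: int,
    rng: np.random.Generator | None,
) -> tuple[str, set[int]]:
    """Return (context string, selected article sentence indices)."""
    if policy == "original":
        return article.raw_text, {s.sent_index for s in article.sentences}
    if policy == "retriever_topk":
        text = baseline_context(example, article, "retriever_topk", k=k, embedder=embedder)
        paragraphs = rank_paragraphs(example.question, article, k, embedder)
        indices = {
            s.sent_index
            for p in paragraphs
            for s in article.paragraph_sentences(p.para_index)
        }
        return text, indices
    if policy == "target_paragraph":
        text = baseline_context(example, article, "target_paragraph")
        indices = {
            s.sent_index
            for p in target_paragraphs(example, article)
            for s in article.paragraph_sentences(p.para_index)
        }
        return text, indices
    if policy == "extraction":
        if params is None or scorers is None:
            raise ValueError("extraction policy needs params and scorers")
        extracted = extract_context(
            example.question,
            article,
            params,
            scorers,
            golds=example.gold_answers,
            embedder=embedder,
        )
        return extracted.text, set(extracted.sent_indices)
    if policy == "random_paragraph":
        if rng is None:
            raise ValueError("random_paragraph policy needs a seed")
        pi = int(rng.integers(0, len(article.paragraphs)))
        indices = {s.sent_index for s in article.paragraph_sentences(pi)}
        return article.paragraphs[pi].text, indices
    raise ValueError(f"unknown policy {policy!r}")


def evaluate_policy(
    examples: Sequence[QAExample],
    articles: Mapping[str, Article],
    reader: Reader,
    policy: str,
    *,
    params: ExtractionParams | None = None,
    scorers: Mapping[str, SentenceScorer] | None = None,
    embedder: Embedder | None = None,
    k: int = 6,
    seed: int | None = None,
) -> PolicyResult:
    """Run the reader under one context policy and score every example.

    A reader exception on one example is recorded as an abstention (and
    tallied), never a crash of the whole evaluation.
    """
    embedder = embedder or HashedBowEmbedder()
    rng = np.random.default_rng(seed) if seed is not None else None
    records: list[EvalRecord] = []
    failures = 0
    for example in examples:
        article = articles[example.article_ref]
        context, selected = _policy_context(
            example,
            article,
            policy,
            params=params,
            scorers=scorers,
            embedder=embedder,
            k=k,
            rng=rng,
        )
        try:
            prediction = reader.predict(example.question, context)
        except Exception:
            prediction = ReaderPrediction(None, float("-inf"))
            failures += 1
        score = metrics.best_over_references(
            prediction.answer_text, example.gold_answers
        )
        records.append(
            EvalRecord(
                qid=example.qid,
                context_policy=policy,
                prediction=prediction,
                answer_f1=score.f1,
                exact_match=metrics.exact_match(
                    prediction.answer_text, example.gold_answers
                ),
                context_len_sentences=len(selected),
                gold_in_context=any(
                    si in selected for si in example.gold_sent_indices
                ),
            )
        )
    mean_f1 = float(np.mean([r.answer_f1 for r in records])) if records else 0.0
    mean_em = float(np.mean([r.exact_match for r in records])) if records else 0.0
    return PolicyResult(
        policy=policy,
        mean_f1=mean_f1,
        mean_em=mean_em,
        records=tuple(records),
        n_reader_failures=failures,
    )


def significant_changes(
    records_a: Sequence[EvalRecord],
    records_b: Sequence[EvalRecord],
    threshold: float = 0.5,
) -> ChangeTally:
    """Count strict answer-F1 changes > threshold between two policies.

    ``records_a`` is the reference policy (typically the original article);
    ``better``/``worse`` count questions whose F1 moved by strictly more
    than the threshold (ties at the threshold are not counted), and
    ``worse_with_good_context`` counts worsened questions whose new context
    still contained the gold sentence — a worsening the context selection
    cannot be blamed for.
    """
    by_qid_a = {r.qid: r for r in records_a}
    by_qid_b = {r.qid: r for r in records_b}
    if set(by_qid_a) != set(by_qid_b):
        raise ValueError("record sets cover different qids")
    better = worse = worse_good = 0
    for qid, ra in by_qid_a.items():
        rb = by_qid_b[qid]
        delta = rb.answer_f1 - ra.answer_f1
        if delta > threshold:
            better += 1
        elif delta < -threshold:
            worse += 1
            if rb.gold_in_context:
                worse_good += 1
    return ChangeTally(
        better=better,
        worse=worse,
        worse_with_good_context=worse_good,
        threshold=threshold,
    )


def write_records_jsonl(records: Sequence[EvalRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")
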