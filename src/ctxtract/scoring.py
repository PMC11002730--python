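"""Sentence-utility signals, paragraph retrieval and the utility ensemble.

Three utility signals measure how much a sentence ``c`` inside a context
``D`` contributes to answering a question ``q``:

* ``u1 = F1(q, D) - F1(q, D \\ c)`` — drop in answer F1 when the sentence
  is deleted (needs gold answers),
* ``u2 = Conf(q, D) - Conf(q, D \\ c)`` — drop in reader confidence
  (needs no gold),
* ``u3 = cos(embed(q), embed(c))`` — question–sentence cosine similarity.

The three signals live on incompatible scales (u2 is unbounded and
reader-specific, u3 is bounded in [-1, 1]), so before the weighted
ensemble ``u = (w1 u1 + w2 u2 + w3 u3) / (w1 + w2 + w3)`` each signal is
min–max rescaled to [0, 1] across the candidate sentences of one
question.  That calibration makes the ensemble weights interpretable and
the peak threshold (a fraction of the maximum) meaningful.

Paragraph retrieval ranks an article's paragraphs by question–paragraph
cosine similarity under a pluggable embedder; the default embedder is a
deterministic hashed bag-of-words term-frequency encoder, a dependency-free
stand-in for a trained bi-encoder.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from . import metrics
from .corpus import Article, Paragraph, QAExample
from .readers import CachingReader, Reader

__all__ = [
    "SentenceScore",
    "Embedder",
    "HashedBowEmbedder",
    "cosine_score",
    "rank_paragraphs",
    "TopKAccuracy",
    "top_k_accuracy",
    "render_context",
    "utility_f1",
    "utility_conf",
    "utility_profile_f1",
    "utility_profile_conf",
    "minmax_rescale",
    "ensemble",
    "SentenceScorer",
    "OracleF1Scorer",
    "OracleConfScorer",
    "CosineSimilarityScorer",
    "EstimatorScorer",
    "RidgeUtilityEstimator",
    "load_object",
]


@dataclass(frozen=True)
class SentenceScore:
    """Per-sentence utility record; absent signals stay ``None``."""

    sent_index: int
    u1: float | None = None
    u2: float | None = None
    u3: float | None = None
    u: float | None = None


@runtime_checkable
class Embedder(Protocol):
    def embed(self, text: str) -> np.ndarray: ...


class HashedBowEmbedder:
    """Deterministic hashed bag-of-words TF embedder, L2-normalized.

    Tokens are normalized the same way as answer metrics; each token is
    hashed with a keyed blake2b digest into one of ``dim`` buckets.  Texts
    with no tokens embed to the zero vector (the one permitted departure
    from unit norm; cosine against it is defined as 0).
    """

    def __init__(self, dim: int = 2**16, seed: int = 0):
        self.dim = int(dim)
        self.seed = int(seed)
        self._key = str(seed).encode()

    def _bucket(self, token: str) -> int:
        digest = hashlib.blake2b(token.encode(), key=self._key, digest_size=8)
        return int.from_bytes(digest.digest(), "big") % self.dim

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in metrics.normalize(text):
            vec[self._bucket(token)] += 1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def cosine_score(question: str, text: str, embedder: Embedder) -> float:
    """Cosine similarity of two embedded texts (0 when either is empty)."""
    return float(np.dot(embedder.embed(question), embedder.embed(text)))


def rank_paragraphs(
    question: str,
    article: Article,
    k: int,
    embedder: Embedder,
    *,
    rank_order: bool = False,
) -> list[Paragraph]:
    """Top-k paragraphs by question–paragraph cosine similarity.

    Ties at the k-th rank keep the earlier paragraph.  By default the
    selected paragraphs come back in document order so that concatenating
    them preserves the article's flow; ``rank_order=True`` returns them
    by descending score instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = [cosine_score(question, p.text, embedder) for p in article.paragraphs]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    chosen = order[:k]
    if rank_order:
        return [article.paragraphs[i] for i in chosen]
    return [article.paragraphs[i] for i in sorted(chosen)]


@dataclass(frozen=True)
class TopKAccuracy:
    accuracies: dict[int, float]
    n_excluded: int


def top_k_accuracy(
    examples: Sequence[QAExample],
    articles: Mapping[str, Article],
    ks: Sequence[int],
    embedder: Embedder,
) -> TopKAccuracy:
    """Fraction of questions whose target paragraph is retrieved in the top k.

    A question scores a hit at k when any of its target paragraphs appears
    among the k highest-scoring paragraphs; examples without a locatable
    target are excluded and tallied.
    """
    ks = sorted(set(int(k) for k in ks))
    hits = {k: 0 for k in ks}
    counted = 0
    excluded = 0
    for example in examples:
        if not example.target_para_indices:
            excluded += 1
            continue
        counted += 1
        article = articles[example.article_ref]
        ranked = rank_paragraphs(
            example.question, article, max(ks), embedder, rank_order=True
        )
        targets = set(example.target_para_indices)
        # first rank (1-based) at which a target paragraph appears
        first_hit = next(
            (r + 1 for r, p in enumerate(ranked) if p.para_index in targets),
            None,
        )
        for k in ks:
            if first_hit is not None and first_hit <= k:
                hits[k] += 1
    accuracies = {k: (hits[k] / counted if counted else 0.0) for k in ks}
    return TopKAccuracy(accuracies=accuracies, n_excluded=excluded)


def render_context(sentences: Sequence[str]) -> str:
    """Join sentences into the flat context string fed to a reader."""
    return " ".join(sentences)


def _leave_one_out(sentences: Sequence[str], index: int) -> str:
    return render_context([s for i, s in enumerate(sentences) if i != index])


def utility_f1(
    question: str,
    sentences: Sequence[str],
    index: int,
    reader: Reader,
    golds: Sequence[str],
) -> float:
    """u1 of one sentence: answer-F1 drop when it is deleted from the context."""
    if not 0 <= index < len(sentences):
        raise IndexError(f"sentence index {index} outside context of {len(sentences)}")
    if not golds:
        raise ValueError("golds must be non-empty for F1-based utility")
    full = reader.predict(question, render_context(sentences))
    ablated = reader.predict(question, _leave_one_out(sentences, index))
    f_full = metrics.best_over_references(full.answer_text, golds).f1
    f_ablated = metrics.best_over_references(ablated.answer_text, golds).f1
    return f_full - f_ablated


def utility_conf(
    question: str, sentences: Sequence[str], index: int, reader: Reader
) -> float:
    """u2 of one sentence: confidence drop when it is deleted from the context."""
    if not 0 <= index < len(sentences):
        raise IndexError(f"sentence index {index} outside context of {len(sentences)}")
    full = reader.predict(question, render_context(sentences))
    ablated = reader.predict(question, _leave_one_out(sentences, index))
    return full.confidence - ablated.confidence


def _profile(
    question: str,
    sentences: Sequence[str],
    reader: Reader,
    one: Callable[[CachingReader, int], float],
) -> list[float]:
    cached = CachingReader(reader)
    values = []
    for i in range(len(sentences)):
        try:
            values.append(one(cached, i))
        except Exception as exc:  # attach the offending sentence index
            raise RuntimeError(f"reader failed while scoring sentence {i}") from exc
    return values


def utility_profile_f1(
    question: str, sentences: Sequence[str], reader: Reader, golds: Sequence[str]
) -> list[float]:
    """u1 for every sentence of the context (full-context call cached)."""
    return _profile(
        question,
        sentences,
        reader,
        lambda cached, i: utility_f1(question, sentences, i, cached, golds),
    )


def utility_profile_conf(
    question: str, sentences: Sequence[str], reader: Reader
) -> list[float]:
    """u2 for every sentence of the context (full-context call cached)."""
    return _profile(
        question,
        sentences,
        reader,
        lambda cached, i: utility_conf(question, sentences, i, cached),
    )


def minmax_rescale(values: Sequence[float]) -> np.ndarray:
    """Min–max rescale to [0, 1]; a constant signal rescales to all zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return arr
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def ensemble(
    u1: float, u2: float, u3: float, w1: float, w2: float, w3: float
) -> float:
    """Weighted mean of the three (already rescaled) utility signals."""
    total = w1 + w2 + w3
    if total <= 0:
        raise ValueError("ensemble weights must sum to a positive value")
    return (w1 * u1 + w2 * u2 + w3 * u3) / total


@runtime_checkable
class SentenceScorer(Protocol):
    """Scores every sentence of a candidate context for one question."""

    def score_sentences(
        self,
        question: str,
        sentences: Sequence[str],
        *,
        golds: Sequence[str] | None = None,
    ) -> list[float]: ...


class OracleF1Scorer:
    """u1 oracle: leave-one-out answer-F1 differences with a live reader."""

    def __init__(self, reader: Reader):
        self.reader = reader

    def score_sentences(self, question, sentences, *, golds=None):
        if not golds:
            raise ValueError("the u1 oracle requires gold answers")
        return utility_profile_f1(question, sentences, self.reader, golds)


class OracleConfScorer:
    """u2 oracle: leave-one-out confidence differences with a live reader."""

    def __init__(self, reader: Reader):
        self.reader = reader

    def score_sentences(self, question, sentences, *, golds=None):
        return utility_profile_conf(question, sentences, self.reader)


class CosineSimilarityScorer:
    """u3: question–sentence cosine similarity under an embedder."""

    def __init__(self, embedder: Embedder):
        self.embedder = embedder

    def score_sentences(self, question, sentences, *, golds=None):
        return [cosine_score(question, s, self.embedder) for s in sentences]


class EstimatorScorer:
    """Adapts an ``estimate_utility(q, sentence, context)`` regressor."""

    def __init__(self, estimator):
        self.estimator = estimator

    def score_sentences(self, question, sentences, *, golds=None):
        context = render_context(sentences)
        return [
            float(self.estimator.estimate_utility(question, s, context))
            for s in sentences
        ]


class RidgeUtilityEstimator:
    """Ridge regression on lexical features as a learned utility stand-in.

    Features per (question, sentence, context): multiset token overlap with
    the question, overlap normalized by sentence length, sentence length in
    tokens, relative position of the sentence within its context, and
    question–sentence cosine under the default embedder.  Trained on
    generated utility triplets (u1 or u2 labels).
    """

    FEATURE_NAMES = (
        "overlap",
        "overlap_frac",
        "sent_len",
        "rel_position",
        "cosine",
    )

    def __init__(self, alpha: float = 1.0, embedder: Embedder | None = None):
        self.alpha = float(alpha)
        self.embedder = embedder or HashedBowEmbedder()
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def _features(self, question: str, sentence: str, context: str) -> np.ndarray:
        from collections import Counter

        from .corpus import segment_sentences

        q_counts = Counter(metrics.normalize(question))
        s_tokens = metrics.normalize(sentence)
        overlap = sum((q_counts & Counter(s_tokens)).values())
        ctx_sents = [s.text for s in segment_sentences(context)]
        try:
            pos = ctx_sents.index(sentence.strip())
        except ValueError:
            pos = 0
        rel = pos / max(len(ctx_sents) - 1, 1)
        return np.array(
            [
                float(overlap),
                overlap / (len(s_tokens) + 1.0),
                float(len(s_tokens)),
                rel,
                cosine_score(question, sentence, self.embedder),
            ]
        )

    def fit(self, triplets, label: str = "u2") -> "RidgeUtilityEstimator":
        from sklearn.linear_model import Ridge

        X = np.stack(
            [
                self._features(t.question, t.focus_sentence, t.context_text)
                for t in triplets
            ]
        )
        y = np.array([getattr(t, f"{label}_label") for t in triplets], dtype=float)
        model = Ridge(alpha=self.alpha).fit(X, y)
        self.coef_ = model.coef_.copy()
        self.intercept_ = float(model.intercept_)
        return self

    def estimate_utility(self, question: str, sentence: str, context: str) -> float:
        if self.coef_ is None:
            raise RuntimeError("estimator is not fitted")
        x = self._features(question, sentence, context)
        return float(x @ self.coef_ + self.intercept_)

    def save(self, path) -> None:
        if self.coef_ is None:
            raise RuntimeError("estimator is not fitted")
        payload = {
            "alpha": self.alpha,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "features": list(self.FEATURE_NAMES),
            "embedder": {"dim": self.embedder.dim, "seed": self.embedder.seed},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RidgeUtilityEstimator":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        est = cls(
            alpha=payload["alpha"],
            embedder=HashedBowEmbedder(**payload["embedder"]),
        )
        est.coef_ = np.asarray(payload["coef"], dtype=float)
        est.intercept_ = float(payload["intercept"])
        return est


def load_object(dotted_name: str):
    """Instantiate an embedder/estimator/scorer by dotted name, e.g.
    ``ctxtract.scoring.HashedBowEmbedder``."""
    module_name, _, attr = dotted_name.rpartition(".")
    if not module_name:
        raise ValueError(f"not a dotted name: {dotted_name!r}")
    import importlib

    return getattr(importlib.import_module(module_name), attr)
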