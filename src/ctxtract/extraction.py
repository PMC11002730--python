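"""Context extraction by utility peaks and sentence windows.

Given a question and a long article, extraction proceeds in five steps:

1. retrieve the top-``k`` paragraphs by question–paragraph cosine; their
   sentences are the *candidates*;
2. score every candidate with the configured utility signals (oracle
   leave-one-out, learned estimator, and/or cosine), min–max rescale each
   signal across the candidates, and combine them with the weighted
   ensemble;
3. mark as *peaks* every candidate whose ensemble score is at least
   ``h`` times the maximum candidate score;
4. add, for each peak, the ``w`` sentences before and after it (distance
   measured in article sentence index, membership clipped to the candidate
   set so a window never imports an unscored sentence);
5. the extracted context is the union of peaks and windows, rendered in
   document order.

``h`` is a relative threshold: ``h = 0`` keeps every candidate, ``h = 1``
keeps only the maximal one(s).  When all candidates tie after rescaling
(every rescaled score is 0, an uninformative profile), the fallback keeps
only the earliest candidate and its window rather than the whole document.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import PARAGRAPH_SEPARATOR, Article, QAExample, target_paragraphs
from .scoring import (
    Embedder,
    HashedBowEmbedder,
    SentenceScore,
    SentenceScorer,
    minmax_rescale,
    rank_paragraphs,
    render_context,
)

__all__ = [
    "ExtractionParams",
    "ExtractedContext",
    "apply_peak_window",
    "extract_context",
    "baseline_context",
]

_SIGNALS = ("u1", "u2", "u3")


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable parameters of the extraction algorithm.

    k      -- number of retrieved paragraphs (>= 1)
    w      -- window radius in sentences around each peak (>= 1)
    h      -- peak threshold as a fraction of the tallest score, in [0, 1]
    omega1..omega3 -- positive ensemble weights for u1/u2/u3
    """

    k: int = 3
    w: int = 2
    h: float = 0.8
    omega1: float = 1.0
    omega2: float = 1.0
    omega3: float = 1.0

    def __post_init__(self):
        if self.k < 1 or self.w < 1:
            raise ValueError("k and w must be positive integers")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if min(self.omega1, self.omega2, self.omega3) <= 0:
            raise ValueError("ensemble weights must be positive")

    def weights(self) -> dict[str, float]:
        return {"u1": self.omega1, "u2": self.omega2, "u3": self.omega3}

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "w": self.w,
            "h": self.h,
            "omega1": self.omega1,
            "omega2": self.omega2,
            "omega3": self.omega3,
        }


@dataclass(frozen=True)
class ExtractedContext:
    """The selected sub-context: sentence indices, peaks, rendered text."""

    sent_indices: tuple[int, ...]
    peak_indices: tuple[int, ...]
    text: str
    scores: tuple[SentenceScore, ...]

    def __post_init__(self):
        if list(self.sent_indices) != sorted(set(self.sent_indices)):
            raise ValueError("sent_indices must be strictly increasing")
        if not set(self.peak_indices) <= set(self.sent_indices):
            raise ValueError("peaks must be selected sentences")


def _local_maxima(scores: np.ndarray) -> np.ndarray:
    """Positions that are >= both neighbours (plateau edges count)."""
    n = len(scores)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if i > 0 and scores[i] < scores[i - 1]:
            keep[i] = False
        if i < n - 1 and scores[i] < scores[i + 1]:
            keep[i] = False
    return keep


def apply_peak_window(
    scores: Sequence[float],
    sent_indices: Sequence[int],
    h: float,
    w: int,
    *,
    local_maxima: bool = False,
) -> tuple[list[int], list[int]]:
    """Core peak/window selection on a raw score vector.

    Returns ``(selected sentence indices, peak sentence indices)`` both in
    increasing order.  ``sent_indices`` are the article-wide indices of the
    candidates, used to measure window distance.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no candidate sentences to select from")
    if len(sent_indices) != scores.size:
        raise ValueError("scores and sent_indices must align")
    top = scores.max()
    if top > 0:
        is_peak = scores >= h * top
        if local_maxima:
            is_peak &= _local_maxima(scores)
        peak_positions = [i for i in range(scores.size) if is_peak[i]]
    else:
        # Degenerate profile (all candidates tie at <= 0 after rescaling):
        # keep only the earliest argmax and its window.
        peak_positions = [int(np.argmax(scores))]
    candidate_set = list(sent_indices)
    selected: set[int] = set()
    for pos in peak_positions:
        anchor = candidate_set[pos]
        for si in candidate_set:
            if abs(si - anchor) <= w:
                selected.add(si)
        selected.add(anchor)
    peaks = sorted(candidate_set[p] for p in peak_positions)
    return sorted(selected), peaks


def extract_context(
    question: str,
    article: Article,
    params: ExtractionParams,
    scorers: Mapping[str, SentenceScorer],
    *,
    golds: Sequence[str] | None = None,
    embedder: Embedder | None = None,
    local_maxima: bool = False,
) -> ExtractedContext:
    """Run the full extraction pipeline for one question.

    ``scorers`` maps signal names ("u1", "u2", "u3") to sentence scorers;
    absent signals are dropped from the ensemble together with their
    weights.  ``golds`` is forwarded to scorers that need gold answers
    (the u1 oracle).
    """
    if not article.sentences:
        raise ValueError(f"article {article.article_id!r} has no sentences")
    unknown = set(scorers) - set(_SIGNALS)
    if unknown:
        raise ValueError(f"unknown utility signals: {sorted(unknown)}")
    if not scorers:
        raise ValueError("at least one sentence scorer is required")

    embedder = embedder or HashedBowEmbedder()
    retrieved = rank_paragraphs(question, article, params.k, embedder)
    candidates = [
        s for p in retrieved for s in article.paragraph_sentences(p.para_index)
    ]
    candidates.sort(key=lambda s: s.sent_index)
    texts = [s.text for s in candidates]
    sent_indices = [s.sent_index for s in candidates]

    weights = params.weights()
    raw: dict[str, list[float]] = {}
    rescaled: dict[str, np.ndarray] = {}
    for name in _SIGNALS:
        if name in scorers:
            raw[name] = list(
                scorers[name].score_sentences(question, texts, golds=golds)
            )
            rescaled[name] = minmax_rescale(raw[name])
    total_weight = sum(weights[name] for name in rescaled)
    combined = sum(
        weights[name] * rescaled[name] for name in rescaled
    ) / total_weight

    selected, peaks = apply_peak_window(
        combined, sent_indices, params.h, params.w, local_maxima=local_maxima
    )
    selected_sentences = [s for s in candidates if s.sent_index in set(selected)]
    pos_of = {si: i for i, si in enumerate(sent_indices)}
    scores = tuple(
        SentenceScore(
            sent_index=si,
            u1=raw["u1"][pos_of[si]] if "u1" in raw else None,
            u2=raw["u2"][pos_of[si]] if "u2" in raw else None,
            u3=raw["u3"][pos_of[si]] if "u3" in raw else None,
            u=float(combined[pos_of[si]]),
        )
        for si in sent_indices
    )
    return ExtractedContext(
        sent_indices=tuple(selected),
        peak_indices=tuple(peaks),
        text=render_context([s.text for s in selected_sentences]),
        scores=scores,
    )


def baseline_context(
    example: QAExample,
    article: Article,
    mode: str,
    *,
    k: int = 6,
    embedder: Embedder | None = None,
) -> str:
    """The three reference context policies.

    ``original``         -- the full article text (worst case, longest);
    ``retriever_topk``   -- top-k retrieved paragraphs concatenated in
                            document order (default k = 6);
    ``target_paragraph`` -- the paragraph(s) containing the gold
                            sentence(s), a near-ideal human-quality context.
    """
    if mode == "original":
        return article.raw_text
    if mode == "retriever_topk":
        embedder = embedder or HashedBowEmbedder()
        paragraphs = rank_paragraphs(example.question, article, k, embedder)
        return PARAGRAPH_SEPARATOR.join(p.text for p in paragraphs)
    if mode == "target_paragraph":
        paragraphs = target_paragraphs(example, article)
        return PARAGRAPH_SEPARATOR.join(p.text for p in paragraphs)
    raise ValueError(f"unknown baseline mode {mode!r}")
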