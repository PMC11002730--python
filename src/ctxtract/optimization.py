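"""Context-quality objectives and seeded parameter search.

Answer F1 on a validation set is too expensive an objective for tuning the
six extraction parameters (k, w, h, omega1..3), so the search optimizes a
cheap two-part proxy:

* ``obj1`` — gold-sentence selection accuracy: the fraction of questions
  whose extracted context contains the gold sentence;
* ``obj2`` — mean *context F1*: word-multiset precision/recall/F1 of the
  extracted context against the target paragraph, which stands in for a
  near-ideal human-selected context.

The two are scalarized as ``L = -(alpha*obj1 + (1-alpha)*obj2)`` and L is
minimized for each alpha on a grid (default 0.05..0.95 step 0.05); the
overall best breakdown is the global minimum across the sweep.  An
alternative sign convention ``as_printed``, ``L = -(alpha*obj1) +
(1-alpha)*obj2``, rewards *small* context F1; both are implemented because
the scalarization can reasonably be read either way, and the default
(maximize both objectives) is the one consistent with the target paragraph
being a desirable context.

Context-F1 tokenization is plain words — lowercase, punctuation stripped,
whitespace split — with no article removal: unlike answer scoring, the
objective counts every word of the selected context.

The default search backend is seeded random search over configurable
bounds; a model-based backend (Gaussian-process surrogate with expected
improvement) is available behind the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import metrics
from .corpus import PARAGRAPH_SEPARATOR, Article, QAExample, target_paragraphs
from .extraction import ExtractedContext, ExtractionParams, extract_context
from .scoring import Embedder, HashedBowEmbedder, SentenceScorer

__all__ = [
    "ObjectiveBreakdown",
    "SearchConfig",
    "context_f1",
    "obj1_accuracy",
    "loss",
    "default_alpha_grid",
    "evaluate_params",
    "search_params",
]


def _context_tokens(text: str) -> list[str]:
    # lowercase + punctuation stripping + whitespace split; NO article
    # removal (a plain word count, unlike answer normalization)
    return metrics._strip_punctuation(text.lower()).split()


def context_f1(selected_text: str, target_text: str) -> tuple[float, float, float]:
    """Word-multiset precision/recall/F1 of a selection vs the target text."""
    from collections import Counter

    target_tokens = _context_tokens(target_text)
    if not target_tokens:
        raise ValueError("target text has no words")
    selected_tokens = _context_tokens(selected_text)
    if not selected_tokens:
        return (0.0, 0.0, 0.0)
    correct = sum(
        (Counter(selected_tokens) & Counter(target_tokens)).values()
    )
    precision = correct / len(selected_tokens)
    recall = correct / len(target_tokens)
    if precision + recall == 0.0:
        return (0.0, 0.0, 0.0)
    return (
        precision,
        recall,
        2.0 * precision * recall / (precision + recall),
    )


def obj1_accuracy(
    contexts: Mapping[str, ExtractedContext], examples: Sequence[QAExample]
) -> float:
    """Fraction of examples whose gold sentence is in the extracted context."""
    missing = [ex.qid for ex in examples if ex.qid not in contexts]
    if missing:
        raise KeyError(f"missing extracted contexts for qids: {missing}")
    hits = 0
    for ex in examples:
        if not ex.gold_sent_indices:
            raise ValueError(f"example {ex.qid} has no gold sentence")
        selected = set(contexts[ex.qid].sent_indices)
        if any(si in selected for si in ex.gold_sent_indices):
            hits += 1
    return hits / len(examples) if examples else 0.0


def loss(
    obj1: float, obj2: float, alpha: float, sign_convention: str = "maximize_both"
) -> float:
    """Scalarized objective; lower is better under both conventions."""
    if sign_convention == "maximize_both":
        return -(alpha * obj1 + (1.0 - alpha) * obj2)
    if sign_convention == "as_printed":
        return -(alpha * obj1) + (1.0 - alpha) * obj2
    raise ValueError(f"unknown sign convention {sign_convention!r}")


def default_alpha_grid() -> list[float]:
    """0.05, 0.10, ..., 0.95."""
    return [round(0.05 * i, 2) for i in range(1, 20)]


@dataclass(frozen=True)
class ObjectiveBreakdown:
    obj1: float
    obj2: float
    alpha: float
    loss: float
    params: ExtractionParams

    def to_dict(self) -> dict:
        return {
            "obj1": self.obj1,
            "obj2": self.obj2,
            "alpha": self.alpha,
            "loss": self.loss,
            "params": self.params.to_dict(),
        }


@dataclass
class SearchConfig:
    """Bounds, backend and budget of the parameter search."""

    k_bounds: tuple[int, int] = (1, 10)
    w_bounds: tuple[int, int] = (1, 5)
    h_bounds: tuple[float, float] = (0.0, 1.0)
    omega_bounds: tuple[float, float] = (0.05, 1.0)
    backend: str = "random"  # or "model_based"
    budget: int = 50
    seed: int = 0
    alpha_grid: list[float] = field(default_factory=default_alpha_grid)
    sign_convention: str = "maximize_both"

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.backend not in ("random", "model_based"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if any(not 0.0 <= a <= 1.0 for a in self.alpha_grid):
            raise ValueError("alpha grid must lie in [0, 1]")


def _draw_params(rng: np.random.Generator, config: SearchConfig) -> ExtractionParams:
    lo, hi = config.omega_bounds
    return ExtractionParams(
        k=int(rng.integers(config.k_bounds[0], config.k_bounds[1] + 1)),
        w=int(rng.integers(config.w_bounds[0], config.w_bounds[1] + 1)),
        h=float(rng.uniform(*config.h_bounds)),
        omega1=float(rng.uniform(lo, hi)),
        omega2=float(rng.uniform(lo, hi)),
        omega3=float(rng.uniform(lo, hi)),
    )


def _params_vector(p: ExtractionParams) -> list[float]:
    return [p.k, p.w, p.h, p.omega1, p.omega2, p.omega3]


def evaluate_params(
    params: ExtractionParams,
    examples: Sequence[QAExample],
    articles: Mapping[str, Article],
    scorers: Mapping[str, SentenceScorer],
    embedder: Embedder,
) -> tuple[float, float]:
    """Extract for every example and measure (obj1, obj2)."""
    contexts: dict[str, ExtractedContext] = {}
    ctx_f1s: list[float] = []
    for ex in examples:
        article = articles[ex.article_ref]
        extracted = extract_context(
            ex.question,
            article,
            params,
            scorers,
            golds=ex.gold_answers,
            embedder=embedder,
        )
        contexts[ex.qid] = extracted
        target_text = PARAGRAPH_SEPARATOR.join(
            p.text for p in target_paragraphs(ex, article)
        )
        ctx_f1s.append(context_f1(extracted.text, target_text)[2])
    return obj1_accuracy(contexts, examples), float(np.mean(ctx_f1s))


def search_params(
    examples: Sequence[QAExample],
    articles: Mapping[str, Article],
    scorers: Mapping[str, SentenceScorer],
    config: SearchConfig,
    embedder: Embedder | None = None,
) -> tuple[ObjectiveBreakdown, list[ObjectiveBreakdown]]:
    """Sweep alpha, search params at each alpha, return (best, full trace).

    Deterministic given ``config.seed``: two runs with the same inputs
    produce identical traces.  Failed extractions at a parameter draw void
    that draw; if every draw of an alpha fails the search errors out.
    """
    embedder = embedder or HashedBowEmbedder()
    rng = np.random.default_rng(config.seed)
    trace: list[ObjectiveBreakdown] = []
    best: ObjectiveBreakdown | None = None
    # objective values don't depend on alpha, so cache per params draw
    cache: dict[tuple, tuple[float, float]] = {}

    def measure(params: ExtractionParams) -> tuple[float, float] | None:
        key = tuple(_params_vector(params))
        if key not in cache:
            try:
                cache[key] = evaluate_params(
                    params, examples, articles, scorers, embedder
                )
            except (ValueError, RuntimeError):
                return None
        return cache[key]

    for alpha in config.alpha_grid:
        evaluated = 0
        if config.backend == "random":
            for _ in range(config.budget):
                params = _draw_params(rng, config)
                objectives = measure(params)
                if objectives is None:
                    continue
                obj1, obj2 = objectives
                entry = ObjectiveBreakdown(
                    obj1, obj2, alpha, loss(obj1, obj2, alpha, config.sign_convention), params
                )
                trace.append(entry)
                evaluated += 1
                if best is None or entry.loss < best.loss:
                    best = entry
        else:
            entries = _model_based_search(
                rng, config, alpha, measure
            )
            trace.extend(entries)
            evaluated = len(entries)
            for entry in entries:
                if best is None or entry.loss < best.loss:
                    best = entry
        if evaluated == 0:
            raise RuntimeError(
                f"all {config.budget} evaluations failed at alpha={alpha}"
            )
    assert best is not None
    return best, trace


def _model_based_search(
    rng: np.random.Generator,
    config: SearchConfig,
    alpha: float,
    measure,
) -> list[ObjectiveBreakdown]:
    """Expected-improvement search over a Gaussian-process surrogate."""
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    import warnings

    n_init = max(3, config.budget // 3)
    entries: list[ObjectiveBreakdown] = []
    X: list[list[float]] = []
    y: list[float] = []

    def record(params: ExtractionParams) -> None:
        objectives = measure(params)
        if objectives is None:
            return
        obj1, obj2 = objectives
        value = loss(obj1, obj2, alpha, config.sign_convention)
        entries.append(ObjectiveBreakdown(obj1, obj2, alpha, value, params))
        X.append(_params_vector(params))
        y.append(value)

    for _ in range(n_init):
        record(_draw_params(rng, config))
    for _ in range(config.budget - n_init):
        if len(X) < 2:
            record(_draw_params(rng, config))
            continue
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            gp.fit(np.asarray(X), np.asarray(y))
        candidates = [_draw_params(rng, config) for _ in range(128)]
        cand_X = np.asarray([_params_vector(p) for p in candidates])
        mu, sigma = gp.predict(cand_X, return_std=True)
        best_y = min(y)
        from scipy.stats import norm

        sigma = np.maximum(sigma, 1e-12)
        z = (best_y - mu) / sigma
        ei = (best_y - mu) * norm.cdf(z) + sigma * norm.pdf(z)
        record(candidates[int(np.argmax(ei))])
    return entries


def save_breakdown(breakdown: ObjectiveBreakdown, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(breakdown.to_dict(), fh, indent=2, sort_keys=True)
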