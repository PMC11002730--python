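"""Question–sentence–context triplet generation for utility estimators.

A learned utility estimator needs supervision pairs of (question, focus
sentence, context) with leave-one-out utility labels.  Contexts are built
under four scenarios spanning the quality spectrum, from sufficient to
irrelevant:

``target_paragraph``       the paragraph containing the gold sentence,
                           verbatim (sufficient information);
``neighborhood_excl_gold`` a contiguous run of 1–5 sentences around the
                           gold sentence, excluding the gold sentence
                           itself (relevant but insufficient);
``adjacent_paragraph``     a paragraph adjacent to the target paragraph
                           (somewhat relevant, not needed);
``distant_or_foreign``     the paragraph furthest from the target, or a
                           paragraph from another article, with equal
                           probability (irrelevant).

The focus sentence is drawn uniformly from the built context and its
u1/u2 labels are computed with the live reader via the leave-one-out
utilities, so recomputing any stored triplet's labels from its stored
context reproduces them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Article, QAExample
from .readers import Reader
from .scoring import render_context, utility_conf, utility_f1

__all__ = [
    "SCENARIOS",
    "UtilityTriplet",
    "GenerationReport",
    "generate_triplets",
    "label_distribution_report",
    "write_triplets_jsonl",
    "read_triplets_jsonl",
]

SCENARIOS = (
    "target_paragraph",
    "neighborhood_excl_gold",
    "adjacent_paragraph",
    "distant_or_foreign",
)


@dataclass(frozen=True)
class UtilityTriplet:
    qid: str
    question: str
    focus_sentence: str
    focus_sent_index: int  # index of the focus sentence within the context
    context_text: str
    context_sentences: tuple[str, ...]
    scenario: str
    u1_label: float
    u2_label: float
    seed_info: str  # "<seed>:<draw index>"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["context_sentences"] = list(self.context_sentences)
        return d


@dataclass
class GenerationReport:
    n_generated: int
    skipped: dict[str, int]  # reason -> count


def _context_sentences_for_scenario(
    rng: np.random.Generator,
    scenario: str,
    example: QAExample,
    article: Article,
    articles: Sequence[Article],
) -> tuple[list[str], str | None]:
    """Build the scenario's context sentence list, or (None, reason)."""
    gold_si = example.gold_sent_indices[0]
    target_pi = example.target_para_indices[0]
    paragraphs = article.paragraphs

    if scenario == "target_paragraph":
        return [s.text for s in article.paragraph_sentences(target_pi)], None

    if scenario == "neighborhood_excl_gold":
        para_sents = article.paragraph_sentences(target_pi)
        if len(para_sents) < 2:
            return None, "target paragraph has no non-gold sentence"
        length = int(rng.integers(1, 6))  # 1..5 sentences
        length = min(length, len(para_sents))
        offset = int(rng.integers(0, len(para_sents) - length + 1))
        run = para_sents[offset : offset + length]
        run = [s for s in run if s.sent_index != gold_si]
        if not run:
            # the run covered only the gold sentence: take its neighbours
            run = [s for s in para_sents if s.sent_index != gold_si][:1]
        return [s.text for s in run], None

    if scenario == "adjacent_paragraph":
        if len(paragraphs) < 2:
            return None, "single-paragraph article has no adjacent paragraph"
        # deterministic preference: preceding paragraph when it exists
        pi = target_pi - 1 if target_pi > 0 else target_pi + 1
        return [s.text for s in article.paragraph_sentences(pi)], None

    if scenario == "distant_or_foreign":
        other_articles = [a for a in articles if a.article_id != article.article_id]
        take_foreign = bool(other_articles) and rng.random() < 0.5
        if take_foreign:
            foreign = other_articles[int(rng.integers(0, len(other_articles)))]
            pi = int(rng.integers(0, len(foreign.paragraphs)))
            return [s.text for s in foreign.paragraph_sentences(pi)], None
        if len(paragraphs) < 2:
            return None, "single-paragraph article has no distant paragraph"
        distances = [abs(p.para_index - target_pi) for p in paragraphs]
        pi = int(np.argmax(distances))  # ties: earlier paragraph
        return [s.text for s in article.paragraph_sentences(pi)], None

    raise ValueError(f"unknown scenario {scenario!r}")


def generate_triplets(
    examples: Sequence[QAExample],
    articles: Mapping[str, Article],
    reader: Reader,
    per_question: Mapping[str, int],
    seed: int,
) -> tuple[list[UtilityTriplet], GenerationReport]:
    """Sample labelled triplets for every example under every scenario.

    ``per_question`` maps scenario name to the number of triplets drawn per
    question.  Unsatisfiable (question, scenario) pairs are skipped and
    tallied.  Deterministic given the seed.
    """
    unknown = set(per_question) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenarios: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    article_list = list(articles.values())
    triplets: list[UtilityTriplet] = []
    skipped: dict[str, int] = {}
    draw = 0
    for example in examples:
        if not example.gold_sent_indices or not example.target_para_indices:
            skipped["no locatable gold sentence"] = (
                skipped.get("no locatable gold sentence", 0)
                + sum(per_question.values())
            )
            continue
        article = articles[example.article_ref]
        for scenario in SCENARIOS:
            for _ in range(per_question.get(scenario, 0)):
                sentences, reason = _context_sentences_for_scenario(
                    rng, scenario, example, article, article_list
                )
                if sentences is None:
                    skipped[reason] = skipped.get(reason, 0) + 1
                    continue
                focus = int(rng.integers(0, len(sentences)))
                u1 = utility_f1(
                    example.question, sentences, focus, reader, example.gold_answers
                )
                u2 = utility_conf(example.question, sentences, focus, reader)
                triplets.append(
                    UtilityTriplet(
                        qid=example.qid,
                        question=example.question,
                        focus_sentence=sentences[focus],
                        focus_sent_index=focus,
                        context_text=render_context(sentences),
                        context_sentences=tuple(sentences),
                        scenario=scenario,
                        u1_label=u1,
                        u2_label=u2,
                        seed_info=f"{seed}:{draw}",
                    )
                )
                draw += 1
    return triplets, GenerationReport(n_generated=len(triplets), skipped=skipped)


def label_distribution_report(triplets: Sequence[UtilityTriplet]) -> pd.DataFrame:
    """Per-scenario mean/sd of the u1 and u2 labels."""
    if not triplets:
        return pd.DataFrame(
            columns=["scenario", "n", "u1_mean", "u1_sd", "u2_mean", "u2_sd"]
        ).set_index("scenario")
    frame = pd.DataFrame(
        {
            "scenario": [t.scenario for t in triplets],
            "u1": [t.u1_label for t in triplets],
            "u2": [t.u2_label for t in triplets],
        }
    )
    grouped = frame.groupby("scenario")
    report = pd.DataFrame(
        {
            "n": grouped.size(),
            "u1_mean": grouped["u1"].mean(),
            "u1_sd": grouped["u1"].std(ddof=0),
            "u2_mean": grouped["u2"].mean(),
            "u2_sd": grouped["u2"].std(ddof=0),
        }
    )
    order = [s for s in SCENARIOS if s in report.index]
    return report.loc[order]


def write_triplets_jsonl(triplets: Sequence[UtilityTriplet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triplets:
            fh.write(json.dumps(t.to_dict(), sort_keys=True) + "\n")


def read_triplets_jsonl(path) -> list[UtilityTriplet]:
    triplets = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            d["context_sentences"] = tuple(d["context_sentences"])
            triplets.append(UtilityTriplet(**d))
    return triplets
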