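"""Seeded synthetic QA corpora with planted answer/support structure.

The generator emulates the document structure the extraction method
assumes: articles of paragraphs of sentences, where each question has one
*target paragraph* containing a gold answer sentence plus nearby support
sentences, and the remaining paragraphs are topically-similar distractors.

Concretely, every question gets

* a unique nonsense answer span planted mid-sentence in the target
  paragraph (globally unique tokens, so both offset-based and
  token-matching gold location are unambiguous);
* ``n_support`` support sentences planted contiguously around the answer
  sentence, each carrying some of the question's tokens — emulating that
  the information needed to answer is local to the answer;
* distractor paragraphs that leak a fraction ``distractor_overlap_rate``
  of the question's tokens, so retrieval is realistic rather than trivial.

Alongside the SQuAD-dialect corpus the generator emits the matching
scripted-reader answer key (answer emitted iff the answer sentence and at
least half of the supports are present), a BioASQ-style variant with the
offsets stripped, and a truth manifest with every planted index.  All
output is deterministic per seed and byte-identical across runs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .corpus import Article, QAExample, build_article
from .readers import QuestionScript, ScriptedReaderSpec

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "make_corpus",
    "write_corpus",
    "default_corpus",
    "make_degenerate_cases",
]

_LETTERS = "bcdfghjklmnpqrstvwxz"
_VOWELS = "aeiou"
_RESERVED_ENGLISH = frozenset({"a", "an", "the", "which", "statement", "mentions"})


@dataclass(frozen=True)
class GeneratorConfig:
    n_articles: int = 4
    paragraphs_per_article: int = 8
    sentences_per_paragraph: int = 6
    questions_per_article: int = 3
    n_support: int = 2
    question_token_count: int = 6
    answer_token_count: int = 2
    distractor_overlap_rate: float = 0.2  # fraction of question tokens leaked
    vocabulary_size: int = 400
    sentence_words: tuple[int, int] = (6, 9)
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_articles,
            self.paragraphs_per_article,
            self.sentences_per_paragraph,
            self.questions_per_article,
            self.n_support,
            self.question_token_count,
            self.answer_token_count,
            self.vocabulary_size,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all generator counts must be >= 1")
        if not 0.0 <= self.distractor_overlap_rate <= 1.0:
            raise ValueError("distractor_overlap_rate must lie in [0, 1]")
        if self.questions_per_article > self.paragraphs_per_article:
            raise ValueError("need one distinct target paragraph per question")
        if self.n_support + 1 > self.sentences_per_paragraph:
            raise ValueError("target paragraph too short for answer + supports")


@dataclass
class SyntheticCorpus:
    squad: dict
    bioasq: list
    reader_spec: ScriptedReaderSpec
    truth: dict


def _fresh_word(rng: np.random.Generator, used: set[str]) -> str:
    """A pronounceable nonsense word not generated before."""
    for _ in range(10_000):
        n_syllables = int(rng.integers(2, 5))
        word = "".join(
            _LETTERS[int(rng.integers(len(_LETTERS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(n_syllables)
        )
        if word not in used and word not in _RESERVED_ENGLISH:
            used.add(word)
            return word
    raise RuntimeError("exhausted attempts to generate a fresh word")


def _render_sentence(words: Sequence[str]) -> str:
    text = " ".join(words)
    return text[0].upper() + text[1:] + "."


def make_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a corpus, its scripted-reader answer key and truth manifest."""
    if config.vocabulary_size < 30:
        raise ValueError(
            f"vocabulary_size {config.vocabulary_size} too small to guarantee "
            f"unique answers and distinctive filler text (need >= 30)"
        )
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()
    fillers = [_fresh_word(rng, used) for _ in range(config.vocabulary_size)]

    def sample_fillers(n: int) -> list[str]:
        return [fillers[int(i)] for i in rng.integers(0, len(fillers), size=n)]

    spec = ScriptedReaderSpec()
    truth_questions: dict[str, dict] = {}
    squad_data = []
    bioasq_records = []

    for ai in range(config.n_articles):
        article_id = f"article_{ai:03d}"
        # word lists per sentence, mutated during planting/leaking
        words: list[list[list[str]]] = [
            [
                sample_fillers(int(rng.integers(*config.sentence_words)))
                for _ in range(config.sentences_per_paragraph)
            ]
            for _ in range(config.paragraphs_per_article)
        ]
        planted: set[tuple[int, int]] = set()  # (para, sent) never mutated later
        target_paras = rng.choice(
            config.paragraphs_per_article,
            size=config.questions_per_article,
            replace=False,
        )
        questions: list[dict] = []
        for qi in range(config.questions_per_article):
            qid = f"q_{ai:03d}_{qi}"
            target_pi = int(target_paras[qi])
            q_tokens = [
                _fresh_word(rng, used) for _ in range(config.question_token_count)
            ]
            answer_words = [
                _fresh_word(rng, used) for _ in range(config.answer_token_count)
            ]
            question = "Which statement mentions " + " ".join(q_tokens) + "?"

            n_sents = config.sentences_per_paragraph
            answer_pos = int(rng.integers(0, n_sents))
            # supports: the nearest positions around the answer sentence
            neighbours = sorted(
                (p for p in range(n_sents) if p != answer_pos),
                key=lambda p: (abs(p - answer_pos), p),
            )
            support_pos = sorted(neighbours[: config.n_support])

            # answer sentence: fillers + half the question tokens, with the
            # answer span inserted contiguously away from position 0 (so
            # sentence-initial capitalization never touches answer tokens)
            n_q_in_answer = max(1, config.question_token_count // 2)
            base = sample_fillers(2) + q_tokens[:n_q_in_answer]
            rng.shuffle(base)
            insert_at = int(rng.integers(1, len(base) + 1))
            words[target_pi][answer_pos] = (
                base[:insert_at] + answer_words + base[insert_at:]
            )
            planted.add((target_pi, answer_pos))

            n_q_in_support = max(1, config.question_token_count // 3)
            for sp in support_pos:
                chosen = [
                    q_tokens[int(i)]
                    for i in rng.choice(
                        config.question_token_count,
                        size=n_q_in_support,
                        replace=False,
                    )
                ]
                body = sample_fillers(int(rng.integers(*config.sentence_words)) - n_q_in_support)
                mixed = body + chosen
                rng.shuffle(mixed)
                words[target_pi][sp] = mixed
                planted.add((target_pi, sp))

            questions.append(
                {
                    "qid": qid,
                    "question": question,
                    "q_tokens": q_tokens,
                    "answer_words": answer_words,
                    "target_pi": target_pi,
                    "answer_pos": answer_pos,
                    "support_pos": support_pos,
                }
            )

            # leak question tokens into distractor paragraphs
            n_leak = round(config.distractor_overlap_rate * config.question_token_count)
            if n_leak:
                for pi in range(config.paragraphs_per_article):
                    if pi == target_pi:
                        continue
                    free = [
                        s
                        for s in range(n_sents)
                        if (pi, s) not in planted
                    ]
                    if not free:
                        continue
                    leak_tokens = [
                        q_tokens[int(i)]
                        for i in rng.choice(
                            config.question_token_count, size=n_leak, replace=False
                        )
                    ]
                    for token in leak_tokens:
                        s = free[int(rng.integers(0, len(free)))]
                        words[pi][s].append(token)

        # render (leaks may have landed before later questions were planted,
        # but planted sentences themselves are final)
        sentence_texts = [
            [_render_sentence(ws) for ws in para_words] for para_words in words
        ]
        paragraph_texts = [" ".join(sts) for sts in sentence_texts]
        article = build_article(article_id, paragraph_texts)

        squad_paragraphs = [{"context": t, "qas": []} for t in paragraph_texts]
        for q in questions:
            answer_text = " ".join(q["answer_words"])
            para_text = paragraph_texts[q["target_pi"]]
            local_start = para_text.find(answer_text)
            assert local_start > 0, "planted answer must occur in its paragraph"
            squad_paragraphs[q["target_pi"]]["qas"].append(
                {
                    "id": q["qid"],
                    "question": q["question"],
                    "answers": [{"text": answer_text, "answer_start": local_start}],
                }
            )
            bioasq_records.append(
                {
                    "id": q["qid"],
                    "question": q["question"],
                    "answers": [answer_text],
                    "article": {"id": article_id, "paragraphs": paragraph_texts},
                }
            )
            answer_sentence = sentence_texts[q["target_pi"]][q["answer_pos"]]
            supports = tuple(
                sentence_texts[q["target_pi"]][sp] for sp in q["support_pos"]
            )
            spec.questions[q["question"]] = QuestionScript(
                answer_text=answer_text,
                answer_sentence=answer_sentence,
                support_sentences=supports,
                min_support=math.ceil(config.n_support / 2),
            )
            sent_base = article.paragraphs[q["target_pi"]].sent_range[0]
            truth_questions[q["qid"]] = {
                "article_id": article_id,
                "answer": answer_text,
                "target_para_index": q["target_pi"],
                "gold_sent_index": sent_base + q["answer_pos"],
                "support_sent_indices": [sent_base + sp for sp in q["support_pos"]],
            }
        squad_data.append({"title": article_id, "paragraphs": squad_paragraphs})

    truth = {"config": asdict(config), "questions": truth_questions}
    return SyntheticCorpus(
        squad={"data": squad_data},
        bioasq=bioasq_records,
        reader_spec=spec,
        truth=truth,
    )


def write_corpus(corpus: SyntheticCorpus, out_dir) -> dict[str, str]:
    """Write squad.json, bioasq.json, reader_spec.json and truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    payloads = {
        "squad.json": corpus.squad,
        "bioasq.json": corpus.bioasq,
        "reader_spec.json": corpus.reader_spec.to_dict(),
        "truth.json": corpus.truth,
    }
    for name, payload in payloads.items():
        path = os.path.join(out_dir, name)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths[name] = path
    return paths


def default_corpus(n_questions: int = 200, seed: int = 0) -> SyntheticCorpus:
    """The study-scale corpus: 200 questions over 50 eight-paragraph articles."""
    questions_per_article = 4
    n_articles = math.ceil(n_questions / questions_per_article)
    return make_corpus(
        GeneratorConfig(
            n_articles=n_articles,
            questions_per_article=questions_per_article,
            seed=seed,
        )
    )


def make_degenerate_cases() -> dict[str, tuple[Article, QAExample]]:
    """Edge-case fixtures exercised by unit tests.

    single_sentence       one-sentence article;
    answer_spans_sentences gold answer crossing a sentence boundary;
    all_ties              every sentence identical under any embedder;
    multi_reference       two gold reference strings for one answer.
    """
    from .corpus import attach_gold

    cases: dict[str, tuple[Article, QAExample]] = {}

    art = build_article("single", ["Lone zovu sentence here."])
    ex = QAExample(
        qid="single_q",
        question="Which statement mentions zovu?",
        article_ref="single",
        gold_answers=["zovu"],
        answer_char_start=art.raw_text.find("zovu"),
    )
    cases["single_sentence"] = (art, attach_gold(ex, art))

    art = build_article(
        "spanning",
        ["Filler opening words. The answer starts here. And it continues into this one."],
    )
    ans = "answer starts here. And it continues"
    ex = QAExample(
        qid="span_q",
        question="Which statement mentions answer?",
        article_ref="spanning",
        gold_answers=[ans],
        answer_char_start=art.raw_text.find("answer starts"),
    )
    cases["answer_spans_sentences"] = (art, attach_gold(ex, art))

    same = "Same tied words repeat."
    art = build_article("ties", [" ".join([same] * 4), " ".join([same] * 4)])
    ex = QAExample(
        qid="ties_q",
        question="Which statement mentions nothing shared?",
        article_ref="ties",
        gold_answers=["tied words"],
        answer_char_start=art.raw_text.find("tied words"),
    )
    cases["all_ties"] = (art, attach_gold(ex, art))

    art = build_article(
        "multiref", ["Protein phosphatase one binds the heat shock protein."]
    )
    ex = QAExample(
        qid="multiref_q",
        question="Which protein phosphatase binds the heat shock protein?",
        article_ref="multiref",
        gold_answers=["Protein phosphatase one", "PP1"],
        answer_char_start=art.raw_text.find("Protein phosphatase"),
    )
    cases["multi_reference"] = (art, attach_gold(ex, art))

    return cases
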