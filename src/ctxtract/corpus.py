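"""Document model and question-answering dataset I/O.

An :class:`Article` is raw text partitioned into paragraphs, each paragraph
into sentences; every sentence carries a half-open character span into the
article's raw text so that answer character offsets, sentence selection and
context rendering all share one coordinate system.  Articles loaded from
SQuAD-dialect JSON join the file's paragraph contexts with a fixed
two-newline separator and remap every ``answer_start`` into the joined
coordinates.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import metrics

__all__ = [
    "PARAGRAPH_SEPARATOR",
    "Sentence",
    "Paragraph",
    "Article",
    "QAExample",
    "CorpusFormatError",
    "segment_sentences",
    "build_article",
    "locate_gold_sentence",
    "find_answer_sentences_by_token_match",
    "target_paragraphs",
    "attach_gold",
    "parse_squad",
    "load_squad_json",
    "to_squad_dict",
    "parse_bioasq",
    "load_bioasq_json",
]

PARAGRAPH_SEPARATOR = "\n\n"

#: Tokens that end with a period without terminating the sentence.
ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "etc", "cf", "vs", "al", "ca", "approx",
        "fig", "figs", "eq", "eqs", "ref", "refs", "no", "vol",
        "dr", "mr", "mrs", "ms", "prof", "st",
    }
)

_BOUNDARY = re.compile(r"[.!?]+[\)\]\"']*(?=\s|$)")


class CorpusFormatError(ValueError):
    """Raised when an input dataset violates the expected schema."""


@dataclass(frozen=True)
class Sentence:
    text: str
    sent_index: int
    para_index: int
    char_span: tuple[int, int]


@dataclass(frozen=True)
class Paragraph:
    para_index: int
    sent_range: tuple[int, int]  # half-open range of article-wide sent_index
    text: str


@dataclass
class Article:
    article_id: str
    raw_text: str
    paragraphs: list[Paragraph]
    sentences: list[Sentence]

    def paragraph_sentences(self, para_index: int) -> list[Sentence]:
        lo, hi = self.paragraphs[para_index].sent_range
        return self.sentences[lo:hi]

    def paragraph_char_offsets(self) -> list[int]:
        """Start offset of each paragraph's text within raw_text."""
        offsets, pos = [], 0
        for para in self.paragraphs:
            offsets.append(pos)
            pos += len(para.text) + len(PARAGRAPH_SEPARATOR)
        return offsets


@dataclass
class QAExample:
    qid: str
    question: str
    article_ref: str
    gold_answers: list[str]
    answer_char_start: int | None = None
    gold_sent_indices: tuple[int, ...] = ()
    target_para_indices: tuple[int, ...] = ()


def _is_abbreviation(text: str, boundary_start: int) -> bool:
    """Is the terminator at ``boundary_start`` part of a guarded abbreviation?"""
    head = text[:boundary_start].rstrip(".")
    token = head.split()[-1] if head.split() else ""
    return token.lower().lstrip("([\"'") in ABBREVIATIONS


def segment_sentences(
    raw_text: str, *, offset: int = 0, para_index: int = 0, start_index: int = 0
) -> list[Sentence]:
    """Split text into sentences with character spans.

    Rule-based and deterministic: a run of sentence-final punctuation
    followed by whitespace (or end of text) closes a sentence unless the
    preceding token is a known abbreviation.  Trailing text without a
    terminator forms a final sentence.  Whitespace-only input yields an
    empty list.
    """
    sentences: list[Sentence] = []
    cursor = 0
    n = len(raw_text)

    def emit(start: int, end: int) -> None:
        chunk = raw_text[start:end]
        stripped = chunk.strip()
        if not stripped:
            return
        lead = len(chunk) - len(chunk.lstrip())
        span = (offset + start + lead, offset + start + lead + len(stripped))
        sentences.append(
            Sentence(
                text=stripped,
                sent_index=start_index + len(sentences),
                para_index=para_index,
                char_span=span,
            )
        )

    for match in _BOUNDARY.finditer(raw_text):
        if match.group().startswith(".") and _is_abbreviation(raw_text, match.start()):
            continue
        emit(cursor, match.end())
        cursor = match.end()
    if cursor < n:
        emit(cursor, n)
    return sentences


def build_article(article_id: str, paragraph_texts: Sequence[str]) -> Article:
    """Assemble an Article from paragraph strings (two-newline join)."""
    raw_text = PARAGRAPH_SEPARATOR.join(paragraph_texts)
    sentences: list[Sentence] = []
    paragraphs: list[Paragraph] = []
    pos = 0
    for pi, text in enumerate(paragraph_texts):
        para_sents = segment_sentences(
            text, offset=pos, para_index=pi, start_index=len(sentences)
        )
        lo = len(sentences)
        sentences.extend(para_sents)
        paragraphs.append(Paragraph(para_index=pi, sent_range=(lo, len(sentences)), text=text))
        pos += len(text) + len(PARAGRAPH_SEPARATOR)
    return Article(
        article_id=article_id,
        raw_text=raw_text,
        paragraphs=paragraphs,
        sentences=sentences,
    )


def locate_gold_sentence(example: QAExample, article: Article) -> list[int]:
    """Sentence index containing the answer's start character.

    An offset in inter-sentence whitespace is assigned to the following
    sentence; an offset beyond the text raises.
    """
    if example.answer_char_start is None:
        raise ValueError(f"example {example.qid} has no answer_char_start")
    pos = example.answer_char_start
    if not 0 <= pos < len(article.raw_text):
        raise ValueError(
            f"answer_char_start {pos} outside article {article.article_id!r} "
            f"of length {len(article.raw_text)}"
        )
    for sentence in article.sentences:
        if pos < sentence.char_span[1]:
            return [sentence.sent_index]
    raise ValueError(
        f"answer_char_start {pos} beyond the last sentence of {article.article_id!r}"
    )


def _contains_subsequence(haystack: list[str], needle: list[str]) -> bool:
    if not needle:
        return False
    limit = len(haystack) - len(needle)
    return any(haystack[i : i + len(needle)] == needle for i in range(limit + 1))


def find_answer_sentences_by_token_match(
    example: QAExample, article: Article
) -> list[int]:
    """All sentences whose normalized tokens contain a gold answer's tokens.

    Used for datasets that give answer strings but no character offsets;
    an answer may match several sentences (or none).
    """
    needles = [metrics.normalize(g) for g in example.gold_answers]
    hits = []
    for sentence in article.sentences:
        tokens = metrics.normalize(sentence.text)
        if any(_contains_subsequence(tokens, needle) for needle in needles):
            hits.append(sentence.sent_index)
    return hits


def target_paragraphs(example: QAExample, article: Article) -> list[Paragraph]:
    """Paragraphs owning the gold sentence(s), in document order."""
    if not example.gold_sent_indices:
        raise ValueError(
            f"example {example.qid} has no locatable gold sentence; "
            "it cannot supply a target paragraph"
        )
    para_indices = sorted(
        {article.sentences[si].para_index for si in example.gold_sent_indices}
    )
    return [article.paragraphs[pi] for pi in para_indices]


def attach_gold(example: QAExample, article: Article) -> QAExample:
    """Derive gold sentence indices and target paragraphs in place."""
    if example.answer_char_start is not None:
        gold = locate_gold_sentence(example, article)
    else:
        gold = find_answer_sentences_by_token_match(example, article)
    example.gold_sent_indices = tuple(gold)
    if gold:
        example.target_para_indices = tuple(
            p.para_index for p in target_paragraphs(example, article)
        )
    else:
        example.target_para_indices = ()
    return example


def _require(obj, key, path: str):
    if not isinstance(obj, dict) or key not in obj:
        raise CorpusFormatError(f"missing key {key!r} at {path}")
    return obj[key]


def _ws_norm(s: str) -> str:
    return " ".join(s.split())


def parse_squad(payload: Mapping) -> tuple[list[Article], list[QAExample]]:
    """Parse a SQuAD v1 dialect object into articles and examples.

    One Article per ``data`` entry; its paragraphs' contexts are joined with
    the two-newline separator and every ``answer_start`` is remapped into
    the joined coordinates.
    """
    data = _require(payload, "data", "$")
    articles: list[Article] = []
    examples: list[QAExample] = []
    for ai, entry in enumerate(data):
        path = f"data[{ai}]"
        article_id = str(entry.get("title", f"article_{ai}")) if isinstance(entry, dict) else ""
        paragraphs = _require(entry, "paragraphs", path)
        contexts = []
        for pi, para in enumerate(paragraphs):
            contexts.append(_require(para, "context", f"{path}.paragraphs[{pi}]"))
        article = build_article(article_id, contexts)
        para_offsets = article.paragraph_char_offsets()
        for pi, para in enumerate(paragraphs):
            ppath = f"{path}.paragraphs[{pi}]"
            for qi, qa in enumerate(_require(para, "qas", ppath)):
                qpath = f"{ppath}.qas[{qi}]"
                qid = str(_require(qa, "id", qpath))
                question = _require(qa, "question", qpath)
                answers = _require(qa, "answers", qpath)
                if not answers:
                    raise CorpusFormatError(f"empty answers at {qpath}")
                gold_answers = []
                starts = []
                for ti, ans in enumerate(answers):
                    apath = f"{qpath}.answers[{ti}]"
                    text = _require(ans, "text", apath)
                    start = _require(ans, "answer_start", apath)
                    if not 0 <= start <= len(contexts[pi]) - 1:
                        raise CorpusFormatError(
                            f"answer_start {start} outside its paragraph at {apath}"
                        )
                    global_start = para_offsets[pi] + start
                    slice_ = article.raw_text[global_start : global_start + len(text) + 8]
                    if not _ws_norm(slice_).startswith(_ws_norm(text)[: len(_ws_norm(text))]):
                        raise CorpusFormatError(
                            f"answer text does not match context slice at {apath}"
                        )
                    gold_answers.append(text)
                    starts.append(global_start)
                example = QAExample(
                    qid=qid,
                    question=question,
                    article_ref=article_id,
                    gold_answers=gold_answers,
                    answer_char_start=starts[0],
                )
                attach_gold(example, article)
                examples.append(example)
        articles.append(article)
    return articles, examples


def load_squad_json(path) -> tuple[list[Article], list[QAExample]]:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_squad(json.load(fh))


def to_squad_dict(
    articles: Sequence[Article], examples: Sequence[QAExample]
) -> dict:
    """Serialize back to the SQuAD dialect (round-trip inverse of parse)."""
    by_article: dict[str, list[QAExample]] = {}
    for ex in examples:
        by_article.setdefault(ex.article_ref, []).append(ex)
    data = []
    for article in articles:
        para_offsets = article.paragraph_char_offsets()
        paragraphs = [
            {"context": p.text, "qas": []} for p in article.paragraphs
        ]
        for ex in by_article.get(article.article_id, []):
            if ex.answer_char_start is None:
                raise ValueError(f"example {ex.qid} lacks an offset; cannot serialize")
            pi = next(
                i
                for i in reversed(range(len(para_offsets)))
                if ex.answer_char_start >= para_offsets[i]
            )
            local = ex.answer_char_start - para_offsets[pi]
            paragraphs[pi]["qas"].append(
                {
                    "id": ex.qid,
                    "question": ex.question,
                    "answers": [
                        {"text": t, "answer_start": local} for t in ex.gold_answers
                    ],
                }
            )
        data.append({"title": article.article_id, "paragraphs": paragraphs})
    return {"data": data}


def parse_bioasq(payload) -> tuple[list[Article], list[QAExample]]:
    """Parse flat records {question, answers, article:{id, paragraphs}}.

    Answer offsets are absent; gold sentences are derived by token matching
    and target paragraphs aggregate every paragraph owning a match.
    """
    if not isinstance(payload, list):
        raise CorpusFormatError("expected a list of records at $")
    articles: dict[str, Article] = {}
    examples: list[QAExample] = []
    for ri, record in enumerate(payload):
        path = f"$[{ri}]"
        question = _require(record, "question", path)
        answers = _require(record, "answers", path)
        if not answers:
            raise CorpusFormatError(f"empty answers at {path}")
        article_obj = _require(record, "article", path)
        article_id = str(_require(article_obj, "id", f"{path}.article"))
        if article_id not in articles:
            articles[article_id] = build_article(
                article_id, _require(article_obj, "paragraphs", f"{path}.article")
            )
        example = QAExample(
            qid=str(record.get("id", f"bioasq_{ri}")),
            question=question,
            article_ref=article_id,
            gold_answers=list(answers),
        )
        attach_gold(example, articles[article_id])
        examples.append(example)
    return list(articles.values()), examples


def load_bioasq_json(path) -> tuple[list[Article], list[QAExample]]:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_bioasq(json.load(fh))
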