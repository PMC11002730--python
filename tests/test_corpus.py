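"""Document model: segmentation, SQuAD/BioASQ I/O, gold-sentence derivation."""

import json

import pytest

from ctxtract import corpus
from ctxtract.corpus import (
    CorpusFormatError,
    QAExample,
    build_article,
    find_answer_sentences_by_token_match,
    locate_gold_sentence,
    parse_bioasq,
    parse_squad,
    segment_sentences,
    target_paragraphs,
    to_squad_dict,
)


class TestSegmentation:
    def test_two_terminated_clauses(self):
        sents = segment_sentences("A b. C d.")
        assert [(s.text, s.char_span) for s in sents] == [
            ("A b.", (0, 4)),
            ("C d.", (5, 9)),
        ]

    def test_no_terminator_single_sentence(self):
        sents = segment_sentences("One sentence only")
        assert len(sents) == 1
        assert sents[0].char_span == (0, 17)

    def test_abbreviation_guard(self):
        sents = segment_sentences("text with e.g. x. Next.")
        assert [s.text for s in sents] == ["text with e.g. x.", "Next."]

    def test_empty_and_whitespace(self):
        assert segment_sentences("") == []
        assert segment_sentences("   \n ") == []

    def test_spans_strictly_increasing_and_slice_matches(self):
        text = "First one. Second here! Third? Trailing tail"
        sents = segment_sentences(text)
        assert len(sents) == 4
        for prev, cur in zip(sents, sents[1:]):
            assert prev.char_span[1] <= cur.char_span[0]
        for s in sents:
            assert text[slice(*s.char_span)].strip() == s.text

    def test_idempotent_on_extracted_sentence(self, small_corpus):
        for article in small_corpus.articles.values():
            for sentence in article.sentences[:5]:
                again = segment_sentences(sentence.text)
                assert len(again) == 1
                assert again[0].text == sentence.text


class TestArticleModel:
    def test_paragraphs_partition_sentences(self, small_corpus):
        for article in small_corpus.articles.values():
            covered = []
            for p in article.paragraphs:
                assert p.sent_range[0] < p.sent_range[1]
                covered.extend(range(*p.sent_range))
            assert covered == list(range(len(article.sentences)))

    def test_sentence_spans_match_raw_text(self, small_corpus):
        for article in small_corpus.articles.values():
            for s in article.sentences:
                assert article.raw_text[slice(*s.char_span)] == s.text


def _minimal_squad(context2_answer_start=3):
    # paragraph 0 has exactly 10 characters; answer sits in paragraph 1
    para0 = "Alpha one."
    para1 = "Go bold words here."
    return {
        "data": [
            {
                "title": "art",
                "paragraphs": [
                    {"context": para0, "qas": []},
                    {
                        "context": para1,
                        "qas": [
                            {
                                "id": "q1",
                                "question": "Which words are bold?",
                                "answers": [
                                    {
                                        "text": para1[context2_answer_start:][:10],
                                        "answer_start": context2_answer_start,
                                    }
                                ],
                            }
                        ],
                    },
                ],
            }
        ]
    }


class TestSquadIO:
    def test_minimal_fixture_loads(self):
        articles, examples = parse_squad(_minimal_squad())
        assert len(articles) == 1 and len(examples) == 1
        assert len(articles[0].paragraphs) == 2

    def test_answer_start_remapped_across_two_newline_join(self):
        # paragraph 0 is 10 chars; local offset 3 -> global 10 + 2 + 3 = 15
        _, examples = parse_squad(_minimal_squad(context2_answer_start=3))
        assert examples[0].answer_char_start == 15

    def test_multiple_answers_kept(self):
        payload = _minimal_squad()
        qas = payload["data"][0]["paragraphs"][1]["qas"][0]
        qas["answers"].append(dict(qas["answers"][0]))
        _, examples = parse_squad(payload)
        assert len(examples[0].gold_answers) == 2

    def test_schema_violation_names_path(self):
        with pytest.raises(CorpusFormatError, match=r"data\[0\]"):
            parse_squad({"data": [{"title": "x"}]})
        with pytest.raises(CorpusFormatError, match="answers"):
            parse_squad(
                {
                    "data": [
                        {
                            "paragraphs": [
                                {"context": "Hi there.", "qas": [{"id": "q", "question": "?"}]}
                            ]
                        }
                    ]
                }
            )

    def test_answer_start_outside_paragraph_rejected(self):
        payload = _minimal_squad()
        payload["data"][0]["paragraphs"][1]["qas"][0]["answers"][0]["answer_start"] = 999
        with pytest.raises(CorpusFormatError, match="answer_start"):
            parse_squad(payload)

    def test_round_trip(self, small_corpus):
        articles = list(small_corpus.articles.values())
        payload = to_squad_dict(articles, small_corpus.examples)
        re_articles, re_examples = parse_squad(payload)
        assert [a.raw_text for a in re_articles] == [a.raw_text for a in articles]
        for a, b in zip(re_articles, articles):
            assert [s.char_span for s in a.sentences] == [s.char_span for s in b.sentences]
        assert [e.qid for e in re_examples] == [e.qid for e in small_corpus.examples]
        assert [e.answer_char_start for e in re_examples] == [
            e.answer_char_start for e in small_corpus.examples
        ]
        assert [e.gold_sent_indices for e in re_examples] == [
            e.gold_sent_indices for e in small_corpus.examples
        ]

    def test_gold_answer_tokens_in_gold_sentence(self, small_corpus):
        from ctxtract import metrics

        for ex in small_corpus.examples:
            article = small_corpus.articles[ex.article_ref]
            (si,) = locate_gold_sentence(ex, article)
            sent_tokens = metrics.normalize(article.sentences[si].text)
            gold_tokens = metrics.normalize(ex.gold_answers[0])
            assert all(t in sent_tokens for t in gold_tokens)


class TestGoldLocation:
    def setup_method(self):
        self.article = build_article("a", ["One two. Three four. Five six."])

    def _ex(self, start):
        return QAExample(
            qid="q", question="?", article_ref="a", gold_answers=["x"],
            answer_char_start=start,
        )

    def test_offset_inside_second_sentence(self):
        start = self.article.raw_text.find("Three")
        assert locate_gold_sentence(self._ex(start + 2), self.article) == [1]

    def test_offset_at_sentence_first_character(self):
        start = self.article.raw_text.find("Five")
        assert locate_gold_sentence(self._ex(start), self.article) == [2]

    def test_offset_in_gap_assigned_to_following_sentence(self):
        gap = self.article.raw_text.find(".") + 1  # the space after "two."
        assert locate_gold_sentence(self._ex(gap), self.article) == [1]

    def test_offset_beyond_text_errors(self):
        with pytest.raises(ValueError):
            locate_gold_sentence(self._ex(10_000), self.article)

    def test_answer_spanning_sentences_anchors_at_start(self):
        art = build_article("s", ["Head part. The answer starts here. And continues on."])
        start = art.raw_text.find("answer starts")
        ex = QAExample(
            qid="q", question="?", article_ref="s",
            gold_answers=["answer starts here. And continues"],
            answer_char_start=start,
        )
        assert locate_gold_sentence(ex, art) == [1]


class TestTokenMatch:
    def test_matches_every_mentioning_sentence(self):
        art = build_article(
            "a", ["PP1 binds here. Nothing relevant. The PP1 complex forms."]
        )
        ex = QAExample(qid="q", question="?", article_ref="a", gold_answers=["PP1"])
        assert find_answer_sentences_by_token_match(ex, art) == [0, 2]

    def test_absent_answer_empty(self):
        art = build_article("a", ["Alpha beta. Gamma delta."])
        ex = QAExample(qid="q", question="?", article_ref="a", gold_answers=["zeta"])
        assert find_answer_sentences_by_token_match(ex, art) == []

    def test_normalization_merges_hyphenated_tokens(self):
        art = build_article("a", ["The T-UCstem1 KD result was clear."])
        ex = QAExample(
            qid="q", question="?", article_ref="a", gold_answers=["T-UCstem1"]
        )
        assert find_answer_sentences_by_token_match(ex, art) == [0]


class TestTargetParagraphs:
    def test_offset_case_single_paragraph(self, small_corpus):
        for ex in small_corpus.examples[:5]:
            article = small_corpus.articles[ex.article_ref]
            paras = target_paragraphs(ex, article)
            assert len(paras) == 1
            assert paras[0].para_index == small_corpus.truth[ex.qid]["target_para_index"]

    def test_token_match_case_document_order(self):
        art = build_article(
            "a", ["No hit here.", "PP1 mention one.", "Still nothing.", "PP1 again twice."]
        )
        ex = QAExample(qid="q", question="?", article_ref="a", gold_answers=["PP1"])
        corpus.attach_gold(ex, art)
        assert [p.para_index for p in target_paragraphs(ex, art)] == [1, 3]

    def test_no_match_errors(self):
        art = build_article("a", ["Nothing here."])
        ex = QAExample(qid="q", question="?", article_ref="a", gold_answers=["zeta"])
        corpus.attach_gold(ex, art)
        with pytest.raises(ValueError, match="target"):
            target_paragraphs(ex, art)


class TestBioasq:
    def test_parse_and_aggregate(self, small_corpus):
        articles, examples = parse_bioasq(small_corpus.corpus.bioasq)
        amap = {a.article_id: a for a in articles}
        assert set(amap) == set(small_corpus.articles)
        for ex in examples:
            truth = small_corpus.truth[ex.qid]
            assert truth["gold_sent_index"] in ex.gold_sent_indices
            assert truth["target_para_index"] in ex.target_para_indices

    def test_schema_error(self):
        with pytest.raises(CorpusFormatError):
            parse_bioasq([{"question": "?"}])
        with pytest.raises(CorpusFormatError):
            parse_bioasq({"not": "a list"})

    def test_round_trip_text(self, small_corpus):
        articles, _ = parse_bioasq(small_corpus.corpus.bioasq)
        for a in articles:
            assert a.raw_text == small_corpus.articles[a.article_id].raw_text


def test_json_serializable(small_corpus):
    payload = to_squad_dict(
        list(small_corpus.articles.values()), small_corpus.examples
    )
    json.dumps(payload)  # must not raise
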