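"""Utility signals, retrieval, the ensemble, and the learned estimator."""

import numpy as np
import pytest

from ctxtract import metrics
from ctxtract.corpus import build_article
from ctxtract.extraction import ExtractionParams, extract_context
from ctxtract.readers import QuestionScript, ScriptedReader, ScriptedReaderSpec
from ctxtract.scoring import (
    CosineSimilarityScorer,
    EstimatorScorer,
    HashedBowEmbedder,
    OracleConfScorer,
    RidgeUtilityEstimator,
    cosine_score,
    ensemble,
    minmax_rescale,
    rank_paragraphs,
    top_k_accuracy,
    utility_conf,
    utility_f1,
    utility_profile_conf,
    utility_profile_f1,
)

S_SUPPORT = "Relevant support facts appear here."
S_NOISE = "Totally unrelated filler text sits around."
S_ANSWER = "The crucial answerspan lives in this sentence."
THREE = [S_SUPPORT, S_NOISE, S_ANSWER]


@pytest.fixture()
def reader():
    return ScriptedReader(
        ScriptedReaderSpec(
            questions={
                "Q?": QuestionScript(
                    answer_text="answerspan",
                    answer_sentence=S_ANSWER,
                    support_sentences=(S_SUPPORT,),
                    min_support=1,
                )
            },
            c_base=2.0,
            c_per_support=1.5,
            c_abstain=0.5,
        )
    )


class TestLeaveOneOutUtilities:
    def test_u1_of_answer_sentence_is_one(self, reader):
        assert utility_f1("Q?", THREE, 2, reader, ["answerspan"]) == 1.0

    def test_u1_of_irrelevant_sentence_is_zero(self, reader):
        assert utility_f1("Q?", THREE, 1, reader, ["answerspan"]) == 0.0

    def test_u2_of_support_equals_per_support_constant(self, reader):
        four = THREE + ["Another support also here."]
        spec = reader.spec.questions["Q?"]
        reader.spec.questions["Q?"] = QuestionScript(
            answer_text=spec.answer_text,
            answer_sentence=spec.answer_sentence,
            support_sentences=(S_SUPPORT, "Another support also here."),
            min_support=1,
        )
        assert utility_conf("Q?", four, 0, reader) == 1.5

    def test_u2_of_irrelevant_sentence_is_zero(self, reader):
        assert utility_conf("Q?", THREE, 1, reader) == 0.0

    def test_u2_of_answer_sentence_is_largest(self, reader):
        # with two supports and min_support=1, removing one support keeps the
        # answer (u2 = 1.5) while removing the answer loses everything
        other = "Another support also here."
        spec = reader.spec.questions["Q?"]
        reader.spec.questions["Q?"] = QuestionScript(
            answer_text=spec.answer_text,
            answer_sentence=spec.answer_sentence,
            support_sentences=(S_SUPPORT, other),
            min_support=1,
        )
        four = [S_SUPPORT, S_NOISE, S_ANSWER, other]
        profile = utility_profile_conf("Q?", four, reader)
        assert np.argmax(profile) == 2
        # answer removal: (base + 2 supports) - abstain = 2 + 3 - 0.5
        assert profile[2] == pytest.approx(4.5)
        assert profile[0] == profile[3] == 1.5
        assert profile[1] == 0.0

    def test_profiles_match_uncached_single_calls(self, reader):
        p1 = utility_profile_f1("Q?", THREE, reader, ["answerspan"])
        p2 = [utility_f1("Q?", THREE, i, reader, ["answerspan"]) for i in range(3)]
        assert p1 == p2
        c1 = utility_profile_conf("Q?", THREE, reader)
        c2 = [utility_conf("Q?", THREE, i, reader) for i in range(3)]
        assert c1 == c2

    def test_index_and_gold_validation(self, reader):
        with pytest.raises(IndexError):
            utility_conf("Q?", THREE, 9, reader)
        with pytest.raises(ValueError):
            utility_f1("Q?", THREE, 0, reader, [])

    def test_reader_failure_reports_sentence_index(self):
        class Boom:
            def predict(self, q, c):
                raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="sentence 0"):
            utility_profile_conf("Q?", THREE, Boom())


class TestEmbedderAndCosine:
    def test_unit_norm_and_determinism(self):
        emb = HashedBowEmbedder(dim=256, seed=1)
        v1, v2 = emb.embed("alpha beta gamma"), emb.embed("alpha beta gamma")
        assert np.allclose(v1, v2)
        assert abs(np.linalg.norm(v1) - 1.0) < 1e-9

    def test_identical_texts_score_one(self):
        emb = HashedBowEmbedder(dim=256)
        assert cosine_score("some words here", "some words here", emb) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_vocabulary_scores_zero(self):
        emb = HashedBowEmbedder(dim=2**16)
        assert cosine_score("alpha beta", "gamma delta", emb) == pytest.approx(0.0)

    def test_articles_removed_before_hashing(self):
        # "a b" vs "a c" reduce to "b" vs "c": disjoint
        emb = HashedBowEmbedder(dim=2**16)
        assert cosine_score("a b", "a c", emb) == pytest.approx(0.0)

    def test_empty_text_scores_zero(self):
        emb = HashedBowEmbedder(dim=64)
        assert cosine_score("", "anything", emb) == 0.0


class _LookupEmbedder:
    """Test stub mapping known texts to fixed unit vectors."""

    def __init__(self, table):
        self.table = table

    def embed(self, text):
        return np.asarray(self.table[text], dtype=float)


class TestRankParagraphs:
    def _article(self, texts):
        return build_article("a", texts)

    def test_returns_all_when_k_large(self):
        art = self._article(["One here.", "Two here.", "Three here."])
        emb = HashedBowEmbedder(dim=64)
        assert len(rank_paragraphs("q", art, 10, emb)) == 3

    def test_top2_in_document_order(self):
        art = self._article(["P zero.", "P one.", "P two."])
        q = "q"
        table = {
            "P zero.": [1, 0], "P one.": [0, 1], "P two.": [0.7, 0.714],
            q: [1, 0],
        }
        # scores: 1.0, 0.0, 0.7 -> top-2 = paragraphs {0, 2}, document order
        emb = _LookupEmbedder(table)
        chosen = rank_paragraphs(q, art, 2, emb)
        assert [p.para_index for p in chosen] == [0, 2]
        ranked = rank_paragraphs(q, art, 2, emb, rank_order=True)
        assert [p.para_index for p in ranked] == [0, 2]

    def test_tie_at_kth_rank_keeps_earlier(self):
        art = self._article(["Same tie text.", "Same tie text.", "Other words."])
        emb = HashedBowEmbedder(dim=256)
        chosen = rank_paragraphs("same tie", art, 1, emb)
        assert [p.para_index for p in chosen] == [0]


class TestTopKAccuracy:
    def test_perfect_on_clean_corpus(self, small_corpus):
        result = top_k_accuracy(
            small_corpus.examples,
            small_corpus.articles,
            ks=[1, 3, 8],
            embedder=HashedBowEmbedder(),
        )
        assert result.accuracies[8] == 1.0
        assert result.n_excluded == 0
        values = [result.accuracies[k] for k in sorted(result.accuracies)]
        assert values == sorted(values)  # monotone non-decreasing in k

    def test_excluded_examples_tallied(self, small_corpus):
        import copy

        examples = [copy.copy(e) for e in small_corpus.examples[:4]]
        examples[0].target_para_indices = ()
        result = top_k_accuracy(
            examples, small_corpus.articles, ks=[1], embedder=HashedBowEmbedder()
        )
        assert result.n_excluded == 1


class TestEnsemble:
    def test_weighted_mean(self):
        assert ensemble(0.3, 0.6, 0.9, 0.2, 0.3, 0.5) == pytest.approx(0.69)

    def test_equal_weights_are_arithmetic_mean(self):
        assert ensemble(0.3, 0.6, 0.9, 1, 1, 1) == pytest.approx(0.6)

    def test_dominant_weight_recovers_signal(self):
        assert ensemble(0.3, 0.6, 0.9, 1 - 1e-12, 1e-12, 1e-12) == pytest.approx(0.3, abs=1e-9)

    def test_zero_weights_error(self):
        with pytest.raises(ValueError):
            ensemble(0.1, 0.2, 0.3, 0, 0, 0)

    def test_minmax_rescale(self):
        assert list(minmax_rescale([1, 3, 2])) == [0.0, 1.0, 0.5]
        assert list(minmax_rescale([5, 5, 5])) == [0.0, 0.0, 0.0]


class TestEstimator:
    def test_ranks_gold_above_random_sentences(self, small_corpus):
        """MRR >= 0.5 for the gold sentence against distractor sentences,
        with the ridge estimator trained on a held-out split of triplets."""
        from ctxtract.training_data import generate_triplets

        examples = small_corpus.examples
        train_ex, test_ex = examples[: len(examples) // 2], examples[len(examples) // 2 :]
        per_question = {
            "target_paragraph": 1,
            "neighborhood_excl_gold": 2,
            "adjacent_paragraph": 1,
            "distant_or_foreign": 1,
        }
        triplets, _ = generate_triplets(
            train_ex, small_corpus.articles, small_corpus.reader, per_question, seed=0
        )
        estimator = RidgeUtilityEstimator().fit(triplets, label="u2")
        rng = np.random.default_rng(0)
        rr = []
        for ex in test_ex:
            article = small_corpus.articles[ex.article_ref]
            gold = article.sentences[ex.gold_sent_indices[0]]
            others = [s for s in article.sentences if s.para_index != gold.para_index]
            pool = [gold] + list(rng.choice(others, size=5, replace=False))
            context = " ".join(s.text for s in pool)
            scores = [
                estimator.estimate_utility(ex.question, s.text, context) for s in pool
            ]
            rank = 1 + sum(1 for s in scores[1:] if s >= scores[0])
            rr.append(1.0 / rank)
        assert np.mean(rr) >= 0.5

    def test_estimator_as_u2_oracle_matches_oracle_extraction(self, small_corpus):
        """Plugging an exact u2 oracle through the estimator seam yields the
        same extraction as the native oracle scorer."""
        from ctxtract.corpus import segment_sentences
        from ctxtract.scoring import utility_conf as uc

        reader = small_corpus.reader

        class OracleEstimator:
            def estimate_utility(self, question, sentence, context):
                sents = [s.text for s in segment_sentences(context)]
                return uc(question, sents, sents.index(sentence), reader)

        params = ExtractionParams(k=3, w=2, h=0.8)
        for ex in small_corpus.examples[:5]:
            article = small_corpus.articles[ex.article_ref]
            via_oracle = extract_context(
                ex.question, article, params, {"u2": OracleConfScorer(reader)}
            )
            via_estimator = extract_context(
                ex.question, article, params, {"u2": EstimatorScorer(OracleEstimator())}
            )
            assert via_oracle.sent_indices == via_estimator.sent_indices

    def test_save_load_round_trip(self, tmp_path, small_corpus):
        from ctxtract.training_data import generate_triplets

        triplets, _ = generate_triplets(
            small_corpus.examples[:3],
            small_corpus.articles,
            small_corpus.reader,
            {"target_paragraph": 1},
            seed=0,
        )
        est = RidgeUtilityEstimator().fit(triplets)
        path = tmp_path / "est.json"
        est.save(path)
        loaded = RidgeUtilityEstimator.load(path)
        t = triplets[0]
        assert loaded.estimate_utility(
            t.question, t.focus_sentence, t.context_text
        ) == pytest.approx(est.estimate_utility(t.question, t.focus_sentence, t.context_text))

    def test_unfitted_estimator_errors(self):
        with pytest.raises(RuntimeError):
            RidgeUtilityEstimator().estimate_utility("q", "s", "s")
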