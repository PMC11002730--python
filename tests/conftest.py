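from dataclasses import dataclass

import pytest

from ctxtract.corpus import Article, QAExample, parse_squad
from ctxtract.readers import ScriptedReader, ScriptedReaderSpec
from ctxtract.synthetic import GeneratorConfig, SyntheticCorpus, make_corpus


@dataclass
class LoadedCorpus:
    corpus: SyntheticCorpus
    articles: dict[str, Article]
    examples: list[QAExample]
    reader: ScriptedReader

    @property
    def spec(self) -> ScriptedReaderSpec:
        return self.corpus.reader_spec

    @property
    def truth(self) -> dict:
        return self.corpus.truth["questions"]


def load(corpus: SyntheticCorpus) -> LoadedCorpus:
    articles, examples = parse_squad(corpus.squad)
    return LoadedCorpus(
        corpus=corpus,
        articles={a.article_id: a for a in articles},
        examples=examples,
        reader=ScriptedReader(corpus.reader_spec),
    )


@pytest.fixture(scope="session")
def small_corpus() -> LoadedCorpus:
    """Five articles, fifteen questions; shared by most integration tests."""
    return load(make_corpus(GeneratorConfig(n_articles=5, seed=7)))


@pytest.fixture(scope="session")
def tiny_corpus() -> LoadedCorpus:
    """Two articles, six questions; for the slower oracle comparisons."""
    return load(make_corpus(GeneratorConfig(n_articles=2, seed=3)))
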