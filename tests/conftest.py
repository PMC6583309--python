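import numpy as np
import pytest

from titletrends.ngrams import TokenizerConfig
from titletrends.records import ArticleRecord


def make_xml(records: str) -> bytes:
    return f"<?xml version='1.0' encoding='utf-8'?><PubmedArticleSet>{records}</PubmedArticleSet>".encode()


def citation(
    pmid="1",
    title="A study",
    year="1980",
    journal="JAMA",
    pub_types=("Journal Article",),
    medline_date=None,
    omit_title=False,
) -> str:
    date = f"<Year>{year}</Year>" if medline_date is None else f"<MedlineDate>{medline_date}</MedlineDate>"
    title_xml = "" if omit_title else f"<ArticleTitle>{title}</ArticleTitle>"
    pts = "".join(f"<PublicationType>{t}</PublicationType>" for t in pub_types)
    return (
        f"<PubmedArticle><MedlineCitation><PMID>{pmid}</PMID><Article>"
        f"<Journal><Title>{journal}</Title><JournalIssue><PubDate>{date}</PubDate></JournalIssue></Journal>"
        f"{title_xml}<PublicationTypeList>{pts}</PublicationTypeList>"
        f"</Article></MedlineCitation></PubmedArticle>"
    )


@pytest.fixture
def tokenizer():
    return TokenizerConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_record(pmid="1", journal="JAMA", year=1980, title="A study",
                pub_types=("Journal Article",)) -> ArticleRecord:
    return ArticleRecord(pmid=pmid, journal=journal, year=year, title=title,
                        pub_types=frozenset(pub_types))


def random_titles(rng: np.random.Generator, n: int, vocab_size: int = 40) -> list[str]:
    """Random lowercase token-sequence titles for counting oracles."""
    vocab = [f"w{i}" for i in range(vocab_size)]
    titles = []
    for _ in range(n):
        length = int(rng.integers(1, 12))
        titles.append(" ".join(rng.choice(vocab, size=length)))
    return titles
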