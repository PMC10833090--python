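"""Shared fixtures: small corpora and the sample lexicon table."""

from __future__ import annotations

import datetime as dt
import textwrap

import pytest

from sentispace.corpus import Corpus, Document, load_lexicon

# The six-row sample of the emotion ontology's layout: word, POS,
# subcategory, intensity, polarity, auxiliary subcategory.
SAMPLE_LEXICON_TSV = textwrap.dedent(
    """\
    word\tpos\tsense_count\tsubcategory\tintensity\tpolarity\tauxiliary
    Anger\tAdjective\t1\tNAU\t7\t-1\t
    Fear\tAdjective\t1\tNI\t5\t-1\tNG
    Grief\tVerb\t1\tNB\t7\t-1\tNJ
    Surprise\tAdjective\t1\tPC\t6\t1\t
    Hope\tNoun\t1\tPD\t4\t1\tPH
    Pleasure\tVerb\t1\tPA\t4\t1\tPE
    """
)


@pytest.fixture
def sample_lexicon(tmp_path):
    path = tmp_path / "lexicon.tsv"
    path.write_text(SAMPLE_LEXICON_TSV, encoding="utf-8")
    with pytest.warns(UserWarning):  # intensities 4 and 6 are off the 5-level grid
        return load_lexicon(path)


@pytest.fixture
def tiny_corpus():
    """Four dated, regioned comments mirroring crawled sample rows."""
    return Corpus(
        documents=[
            Document("u1", "test reagents for every city", date=dt.date(2020, 10, 15), region="Jilin Province"),
            Document("u2", "the virus is still mutating", date=dt.date(2021, 1, 24), region="Guangdong Province"),
            Document("u3", "control the price of masks", date=dt.date(2021, 4, 8), region="Beijing City"),
            Document("u4", "scientific prevention and treatment", date=dt.date(2021, 6, 17), region="Sichuan Province"),
        ]
    )


def make_token_corpus(token_lists, **doc_kwargs):
    """Corpus from raw token lists (text joined by spaces)."""
    docs = []
    for i, toks in enumerate(token_lists):
        docs.append(
            Document(f"d{i}", " ".join(toks), tokens=list(toks), **doc_kwargs)
        )
    return Corpus(documents=docs)
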