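import io

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from apstyle import (
    Corpus,
    Document,
    SynthConfig,
    default_attribute_table,
    parse_ap_code,
    simulate_corpus,
)


@pytest.fixture(scope="session")
def table():
    return default_attribute_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210511)


def make_document(doc_id, textbook, disease, mentions):
    """Build a Document from a {code string: count} mapping."""
    return Document(
        doc_id=doc_id,
        textbook=textbook,
        disease=disease,
        mentions={parse_ap_code(c): n for c, n in mentions.items()},
    )


def make_corpus(spec):
    """Build a Corpus from (doc_id, textbook, disease, {code: count}) tuples."""
    return Corpus([make_document(*row) for row in spec])


def corpus_csv(rows, header="doc_id,textbook,disease,ap_code,count"):
    """An in-memory corpus CSV from (doc_id, textbook, disease, code, count) rows."""
    lines = [header] + [",".join(str(v) for v in row) for row in rows]
    return io.StringIO("\n".join(lines) + "\n")


@pytest.fixture(scope="session")
def null_corpus():
    """One 42-document corpus drawn under the exchangeable null."""
    corpus, _ = simulate_corpus(SynthConfig(seed=97))
    return corpus


@pytest.fixture(scope="session")
def style_corpus():
    """One corpus with a strong planted style effect and no disease effect."""
    corpus, truth = simulate_corpus(SynthConfig(style_strength=2.0, seed=11))
    return corpus, truth
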