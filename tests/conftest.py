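from __future__ import annotations

import pytest

from regumine import datasets
from regumine.corpus import Document, Sentence
from regumine.terminology import Lexicon, LexiconEntry, annotate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return datasets.load_builtin_lexicon()


@pytest.fixture()
def example_corpus(lexicon):
    docs = datasets.load_example_corpus()
    annotate_corpus(docs, lexicon)
    return docs


@pytest.fixture()
def mntr_doc(example_corpus):
    return next(d for d in example_corpus if d.doc_id == "mntr-efflux")


@pytest.fixture()
def oxyr_sentence(example_corpus):
    doc = next(d for d in example_corpus if d.doc_id == "oxyr-binding-modes")
    return doc.sentences[0]


def make_sentence(text: str, lexicon: Lexicon | None = None, doc_id: str = "doc1"):
    """One-sentence document helper; annotates when a lexicon is given."""
    sent = Sentence(sentence_id="S1", ordinal=1, text=text)
    doc = Document(doc_id=doc_id, sentences=[sent])
    if lexicon is not None:
        annotate_corpus([doc], lexicon)
    return doc.sentences[0]


def tiny_lexicon(*rows: tuple) -> Lexicon:
    """Lexicon from (surface, canonical, class[, polarity[, parent]]) tuples."""
    entries = []
    refs_needed = {}
    for row in rows:
        surface, canonical, cls = row[0], row[1], row[2]
        polarity = row[3] if len(row) > 3 else "not_applicable"
        parent = row[4] if len(row) > 4 else None
        entries.append(
            LexiconEntry(
                surface=surface,
                canonical=canonical,
                entity_class=cls,
                polarity=polarity,
                parent=parent,
                is_reference_term=(surface == canonical),
            )
        )
        refs_needed.setdefault(canonical, surface == canonical)
        refs_needed[canonical] = refs_needed[canonical] or surface == canonical
    return Lexicon(entries=entries)
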