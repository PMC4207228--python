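import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regumine.corpus import Sentence
from regumine.terminology import (
    Lexicon,
    LexiconEntry,
    LexiconError,
    generalize_gc,
    generate_variants,
    load_lexicon,
    match_terms,
    normalize,
    resolve_system_alias,
)

from .conftest import make_sentence
from .oracles import brute_force_matches


class TestLoadLexicon:
    def test_builtin_lexicon_loads(self, lexicon):
        assert len(lexicon) > 100
        assert "fold" in lexicon.stoplist

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("surface\tcanonical\nfoo\tfoo\n")
        with pytest.raises(LexiconError, match="entity_class"):
            load_lexicon(path)

    def test_duplicate_surface_class_rejected(self):
        entry = LexiconEntry("katG", "katG", "gene", is_reference_term=True)
        with pytest.raises(LexiconError, match="duplicate"):
            Lexicon(entries=[entry, entry])

    def test_cyclic_parent_links_rejected(self):
        entries = [
            LexiconEntry("a cond", "a cond", "growth_condition",
                         parent="b cond", is_reference_term=True),
            LexiconEntry("b cond", "b cond", "growth_condition",
                         parent="a cond", is_reference_term=True),
        ]
        with pytest.raises(LexiconError, match="cyclic"):
            Lexicon(entries=entries)

    def test_effect_rows_carry_polarity(self, lexicon):
        upreg = [e for e in lexicon.entries if e.surface == "upregulated"]
        assert upreg and upreg[0].polarity == "positive"
        assert upreg[0].canonical == "activation"


class TestVariants:
    def test_multiword_gets_hyphen_space_interchange(self):
        entry = LexiconEntry(
            "hydrogen peroxide", "hydrogen peroxide treatment", "growth_condition"
        )
        variants = generate_variants(entry)
        assert "hydrogen peroxide" in variants
        assert "hydrogen-peroxide" in variants

    def test_short_entry_exact_case_only(self):
        entry = LexiconEntry("dps", "dps", "gene", is_reference_term=True)
        assert generate_variants(entry) == {"dps"}

    def test_long_entry_gets_case_variants(self):
        entry = LexiconEntry(
            "oxidative stress", "oxidative stress", "growth_condition",
            is_reference_term=True,
        )
        assert "Oxidative stress" in generate_variants(entry)


class TestMatchTerms:
    def test_worked_example_annotations(self, lexicon):
        sent = make_sentence(
            "We additionally found that expression of the mntP gene is "
            "upregulated by manganese through MntR.",
            lexicon,
        )
        found = {(a.surface, a.entity_class) for a in sent.annotations}
        assert ("mntP", "gene") in found
        assert ("upregulated", "effect") in found
        assert ("manganese", "growth_condition") in found
        assert ("MntR", "tf") in found

    def test_fold_suppressed_in_numeric_context(self, lexicon):
        sent = make_sentence("Expression increased two-fold after treatment.", lexicon)
        assert not any(a.canonical == "fold" for a in sent.annotations)

    def test_fold_annotated_outside_numeric_context(self, lexicon):
        sent = make_sentence("The fold gene encodes a product.", lexicon)
        assert any(
            a.canonical == "fold" and a.entity_class == "gene"
            for a in sent.annotations
        )

    def test_empty_lexicon_empty_annotations(self):
        sent = Sentence("S1", 1, "OxyR activates katG.")
        assert match_terms(sent, Lexicon(entries=[])) == []

    def test_short_names_are_case_sensitive(self, lexicon):
        sent = make_sentence("The OXYS transcript accumulates.", lexicon)
        assert not any(a.canonical == "oxyS" for a in sent.annotations)

    def test_dual_membership_resolved_by_capitalization(self, lexicon):
        sent = make_sentence("OxyR represses oxyR transcription.", lexicon)
        classes = {(a.surface, a.entity_class) for a in sent.annotations}
        assert ("OxyR", "tf") in classes
        assert ("oxyR", "gene") in classes

    def test_longest_match_wins(self, lexicon):
        sent = make_sentence(
            "Cells were exposed to hydrogen peroxide during growth.", lexicon
        )
        surfaces = {a.surface for a in sent.annotations}
        assert "hydrogen peroxide" in surfaces

    def test_annotations_pairwise_disjoint(self, lexicon, example_corpus):
        for doc in example_corpus:
            for sent in doc.sentences:
                anns = sorted(sent.annotations, key=lambda a: a.start)
                for a, b in zip(anns, anns[1:]):
                    assert a.end <= b.start


# -- property: match_terms equals the brute-force gazetteer oracle ----------

_WORDS = [
    "mntp", "katg", "oxyr", "stress", "peroxide", "growth", "cells",
    "activates", "during", "the", "manganese", "treatment", "gene", "xx",
]
_CLASSES = ["gene", "tf", "operon", "effect", "growth_condition"]


@st.composite
def lexicon_and_sentence(draw):
    n_entries = draw(st.integers(1, 12))
    surfaces = draw(
        st.lists(
            st.text(alphabet=string.ascii_letters, min_size=2, max_size=10),
            min_size=n_entries,
            max_size=n_entries,
            unique_by=lambda s: s.lower(),
        )
    )
    entries = []
    for surface in surfaces:
        cls = draw(st.sampled_from(_CLASSES))
        polarity = "positive" if cls == "effect" else "not_applicable"
        entries.append(
            LexiconEntry(
                surface=surface,
                canonical=surface,
                entity_class=cls,
                polarity=polarity,
                is_reference_term=True,
            )
        )
    lexicon = Lexicon(entries=entries)
    n_tokens = draw(st.integers(1, 40))
    tokens = draw(
        st.lists(
            st.sampled_from(_WORDS + surfaces),
            min_size=n_tokens,
            max_size=n_tokens,
        )
    )
    return lexicon, " ".join(tokens) + "."


@settings(max_examples=500, deadline=None, derandomize=True)
@given(lexicon_and_sentence())
def test_match_terms_equals_brute_force_oracle(case):
    """Dictionary matching agrees with exhaustive per-position scanning."""
    lexicon, text = case
    sent = Sentence("S1", 1, text)
    got = [
        (a.start, a.end, a.canonical, a.entity_class)
        for a in match_terms(sent, lexicon)
    ]
    assert got == brute_force_matches(sent.text, lexicon)


class TestNormalization:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("oxidizing conditions", "oxidative stress"),
            ("logarithmic phase", "exponential phase"),
            ("oxidative stress", "oxidative stress"),
            ("H2O2", "hydrogen peroxide treatment"),
        ],
    )
    def test_synonyms_map_to_reference_terms(self, lexicon, term, expected):
        assert normalize(term, lexicon) == expected

    def test_idempotent_on_all_reference_terms(self, lexicon):
        for canonical in lexicon.canonicals_of("growth_condition", "effect"):
            assert normalize(canonical, lexicon) == canonical

    def test_unknown_term_raises_unless_lenient(self, lexicon):
        with pytest.raises(LexiconError):
            normalize("warp drive", lexicon)
        assert normalize("warp drive", lexicon, lenient=True) == "warp drive"


class TestGeneralization:
    @pytest.mark.parametrize(
        "gc,parent",
        [
            ("hydrogen peroxide treatment", "oxidative stress"),
            ("paraquat treatment", "oxidative stress"),
            ("oxidative stress", None),
        ],
    )
    def test_one_step_up_the_hierarchy(self, lexicon, gc, parent):
        assert generalize_gc(gc, lexicon) == parent

    def test_unknown_gc_raises(self, lexicon):
        with pytest.raises(LexiconError):
            generalize_gc("warp drive", lexicon)

    def test_normalize_then_generalize_stays_in_lexicon(self, lexicon):
        known = lexicon.canonicals_of("growth_condition")
        for gc in known:
            parent = generalize_gc(normalize(gc, lexicon), lexicon)
            assert parent is None or parent in known


class TestSystemAliases:
    def test_arcab_system_maps_to_arca(self, lexicon):
        assert resolve_system_alias("ArcAB", lexicon) == "ArcA"

    def test_tf_name_is_identity(self, lexicon):
        assert resolve_system_alias("OxyR", lexicon) == "OxyR"

    def test_unknown_alias_raises(self, lexicon):
        with pytest.raises(LexiconError):
            resolve_system_alias("QrsT", lexicon)
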