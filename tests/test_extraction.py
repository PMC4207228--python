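import pytest

from regumine.extraction import (
    DEFAULT_CONFIG,
    GC_UNDERSPECIFIED,
    SIGMA_NEGATIVE,
    TARGET_NOT_IN_DICTIONARY,
    apply_exclusions,
    distribute_conjunctions,
    extract_structures,
    flag_mutant_context,
)
from regumine.filters import FilterConfig, parse_filter
from regumine.pipeline import run_pipeline
from regumine.synthetic import SyntheticConfig, generate_synthetic_corpus

from .conftest import make_sentence


def extract(sentence, lexicon):
    raw = extract_structures(sentence, lexicon)
    return apply_exclusions(raw, lexicon)


class TestWorkedExamples:
    def test_every_mntr_sentence_yields_the_same_tuple(self, mntr_doc, lexicon):
        """Four differently-worded sentences normalize to one structure."""
        for sentence in mntr_doc.sentences:
            kept, _ = extract(sentence, lexicon)
            assert [(s.tf, s.effect, s.target, s.gc) for s in kept] == [
                ("MntR", "positive", "mntP", "manganese")
            ]
            assert kept[0].form == "TF_EFFECT_GENE_GC"

    def test_contrast_sentence_yields_six_structures(self, oxyr_sentence, lexicon):
        """One sentence instantiates several structures: a demoted
        autoregulation tuple plus five coordinated activation tuples."""
        kept, excluded = extract(oxyr_sentence, lexicon)
        tuples = {(s.tf, s.effect, s.target, s.gc) for s in kept}
        assert tuples == {
            ("OxyR", "negative", "oxyR", None),
            ("OxyR", "positive", "katG", "oxidative stress"),
            ("OxyR", "positive", "ahpCF", "oxidative stress"),
            ("OxyR", "positive", "dps", "oxidative stress"),
            ("OxyR", "positive", "gorA", "oxidative stress"),
            ("OxyR", "positive", "oxyS", "oxidative stress"),
        }

    def test_out_of_dictionary_target_excluded(self, oxyr_sentence, lexicon):
        _, excluded = extract(oxyr_sentence, lexicon)
        mom = [s for s in excluded if s.target == "mom"]
        assert len(mom) == 1
        assert mom[0].exclusion_reason == TARGET_NOT_IN_DICTIONARY
        assert mom[0].tf == "OxyR" and mom[0].effect == "negative"

    def test_uninformative_gc_demotes_not_removes(self, oxyr_sentence, lexicon):
        kept, _ = extract(oxyr_sentence, lexicon)
        auto = next(s for s in kept if s.target == "oxyR")
        assert auto.gc is None and auto.form == "TF_EFFECT_GENE"
        assert auto.gc_dropped == "normal growth"

    def test_effect_word_without_dictionary_gene_yields_nothing(self, lexicon):
        sent = make_sentence("Expression was strongly activated afterwards.", lexicon)
        kept, excluded = extract(sent, lexicon)
        assert kept == [] and excluded == []


class TestConjunctions:
    def test_distributes_effect_over_targets(self):
        pairs = distribute_conjunctions(
            "positive", ["katG", "ahpCF", "dps", "gorA", "oxyS"]
        )
        assert len(pairs) == 5
        assert all(e == "positive" for e, _ in pairs)

    def test_pair_list_before_exclusion(self):
        assert distribute_conjunctions("negative", ["oxyR", "mom"]) == [
            ("negative", "oxyR"),
            ("negative", "mom"),
        ]

    def test_single_target(self):
        assert distribute_conjunctions("positive", ["x"]) == [("positive", "x")]


class TestExclusionRules:
    def test_negative_sigma_factor_excluded(self, lexicon):
        sent = make_sentence("SigmaS represses oxyR during stationary phase.", lexicon)
        kept, excluded = extract(sent, lexicon)
        assert kept == []
        assert excluded and excluded[0].exclusion_reason == SIGMA_NEGATIVE

    def test_positive_sigma_factor_kept(self, lexicon):
        sent = make_sentence("SigmaS activates katE during stationary phase.", lexicon)
        kept, _ = extract(sent, lexicon)
        assert [(s.tf, s.effect, s.target) for s in kept] == [
            ("SigmaS", "positive", "katE")
        ]

    def test_underspecified_gc_excludes_structure(self, lexicon):
        sent = make_sentence("The gntP gene is regulated by pH.", lexicon)
        kept, excluded = extract(sent, lexicon)
        assert kept == []
        assert excluded and excluded[0].exclusion_reason == GC_UNDERSPECIFIED

    def test_nondirectional_effect_kept_for_validation_only(self, lexicon):
        sent = make_sentence(
            "OxyR regulates katG during oxidative stress.", lexicon
        )
        kept, _ = extract(sent, lexicon)
        assert len(kept) == 1
        assert kept[0].effect == "nondirectional" and kept[0].validation_only

    def test_no_effect_record_kept_as_negative_result(self, lexicon):
        sent = make_sentence(
            "Superoxide treatment had no effect on mntH expression.", lexicon
        )
        kept, _ = extract(sent, lexicon)
        assert len(kept) == 1
        assert kept[0].effect == "no_effect"
        assert not kept[0].validation_only

    def test_kept_and_excluded_partition_raw_output(self, oxyr_sentence, lexicon):
        raw = extract_structures(oxyr_sentence, lexicon)
        kept, excluded = apply_exclusions(raw, lexicon)
        assert len(kept) + len(excluded) == len(raw)


class TestMutantFlag:
    def test_delta_mutant_flagged(self, lexicon):
        sent = make_sentence("Expression of ryhB rose in the Δfur mutant.", lexicon)
        assert flag_mutant_context(sent)

    def test_plain_assertion_not_flagged(self, mntr_doc):
        assert not flag_mutant_context(mntr_doc.sentences[0])

    def test_deletion_phrase_flagged(self, lexicon):
        sent = make_sentence("Upon deletion of oxyR the effect vanished.", lexicon)
        assert flag_mutant_context(sent)


class TestFormInvariant:
    def test_form_determined_by_component_presence(self, lexicon):
        config = SyntheticConfig(
            n_documents=3, sentences_per_document=40, distractor_rate=0.4,
            synonym_noise_rate=0.2, conjunction_rate=0.3, seed=3,
        )
        corpus, _ = generate_synthetic_corpus(config, lexicon)
        result = run_pipeline(corpus, lexicon)
        assert result.kept
        for s in result.kept:
            if s.tf is not None and s.gc is not None:
                assert s.form == "TF_EFFECT_GENE_GC"
            elif s.tf is not None:
                assert s.form == "TF_EFFECT_GENE"
            else:
                assert s.gc is not None and s.form == "EFFECT_GENE_GC"

    def test_kept_structures_come_from_filtered_sentences(self, example_corpus, lexicon):
        result = run_pipeline(example_corpus, lexicon, annotate=False)
        expr = parse_filter("class:gene AND class:effect")
        filtered_keys = {(s.doc_id, s.sentence_id) for s in result.filtered}
        for s in result.kept:
            assert (s.doc_id, s.sentence_id) in filtered_keys
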