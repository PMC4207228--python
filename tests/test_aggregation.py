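import random

import pytest

from regumine.aggregation import (
    InteractionRecord,
    aggregate,
    infer_complementary,
    partition_outputs,
    resolve_effect,
)
from regumine.extraction import SemanticStructure
from regumine.pipeline import run_pipeline
from regumine.synthetic import SyntheticConfig, generate_synthetic_corpus


def S(tf, effect, target, gc=None, doc="d1", sid="S1"):
    return SemanticStructure(
        tf=tf, effect=effect, target=target, gc=gc, doc_id=doc, sentence_id=sid
    )


class TestAggregate:
    def test_repeated_assertion_counts_support(self):
        structures = [
            S("MntR", "positive", "mntP", "manganese", sid=f"S{i}") for i in range(4)
        ]
        records = aggregate(structures)
        assert len(records) == 1
        rec = records[0]
        assert rec.support_positive == 4
        assert rec.gcs == [("manganese", 4)]
        assert rec.per_paper_counts == {"d1": 4}

    def test_empty_input_empty_output(self):
        assert aggregate([]) == []

    def test_order_independence(self, lexicon):
        config = SyntheticConfig(
            n_documents=3, sentences_per_document=40, distractor_rate=0.4,
            conjunction_rate=0.3, conflict_rate=0.2, seed=5,
        )
        corpus, _ = generate_synthetic_corpus(config, lexicon)
        result = run_pipeline(corpus, lexicon)
        shuffled = list(result.kept)
        random.Random(99).shuffle(shuffled)
        assert aggregate(shuffled) == aggregate(result.kept)

    def test_support_count_conservation(self, lexicon):
        config = SyntheticConfig(
            n_documents=4, sentences_per_document=40, distractor_rate=0.4,
            conjunction_rate=0.3, conflict_rate=0.3, seed=8,
        )
        corpus, _ = generate_synthetic_corpus(config, lexicon)
        result = run_pipeline(corpus, lexicon)
        records = aggregate(result.kept)
        keyed = {}
        for s in result.kept:
            if s.tf is not None:
                keyed.setdefault((s.tf, s.target), []).append(s)
        assert keyed
        for rec in records:
            assert rec.total_support == len(keyed[rec.key])


class TestResolveEffect:
    def test_strong_negative_majority_with_minority_flag(self):
        # 65 repression sentences against one activation: negative wins,
        # but the minority keeps the record flagged for review
        rec = InteractionRecord(
            "OxyR", "flu", support_positive=1, support_negative=65,
            support_nondirectional=3,
        )
        resolve_effect(rec)
        assert rec.resolved_effect == "negative" and rec.status == "conflicting"

    def test_strong_positive_majority(self):
        rec = InteractionRecord("OxyR", "oxyS", support_positive=18, support_negative=1)
        resolve_effect(rec)
        assert rec.resolved_effect == "positive" and rec.status == "conflicting"

    def test_tie_is_dual(self):
        rec = InteractionRecord("X", "y", support_positive=1, support_negative=1)
        resolve_effect(rec)
        assert rec.resolved_effect == "dual" and rec.status == "conflicting"

    def test_unanimous_is_supported(self):
        rec = InteractionRecord("X", "y", support_positive=3)
        resolve_effect(rec)
        assert rec.resolved_effect == "positive" and rec.status == "supported"

    def test_nondirectional_and_no_effect_never_vote(self):
        rec = InteractionRecord(
            "X", "y", support_nondirectional=10, support_no_effect=5
        )
        resolve_effect(rec)
        assert rec.resolved_effect == "unresolved"

    @pytest.mark.parametrize("pos,neg", [(9, 1), (5, 5), (1, 9), (20, 0)])
    def test_adding_resolved_polarity_never_flips(self, pos, neg):
        rec = resolve_effect(InteractionRecord("X", "y", support_positive=pos,
                                               support_negative=neg))
        before = rec.resolved_effect
        if before == "dual":
            return
        for _ in range(5):
            if before == "positive":
                rec.support_positive += 1
            else:
                rec.support_negative += 1
            resolve_effect(rec)
            assert rec.resolved_effect == before


class TestComplementarity:
    def test_partial_structures_complete_a_record(self):
        rec = resolve_effect(
            InteractionRecord("FNR", "yfgF", support_negative=1)
        )
        partial = S(None, "negative", "yfgF", "anaerobiosis")
        hyps = infer_complementary([rec], [partial])
        assert len(hyps) == 1
        hyp = hyps[0]
        assert hyp.key == ("FNR", "yfgF") and hyp.status == "hypothesized"
        assert hyp.gcs == [("anaerobiosis", 1)]

    def test_mntr_mnts_example(self):
        rec = resolve_effect(InteractionRecord("MntR", "mntS", support_negative=2))
        hyps = infer_complementary([rec], [S(None, "negative", "mntS", "manganese")])
        assert hyps and hyps[0].gcs == [("manganese", 1)]

    def test_polarity_mismatch_yields_no_hypothesis(self):
        rec = resolve_effect(InteractionRecord("FNR", "yfgF", support_negative=1))
        assert infer_complementary(
            [rec], [S(None, "positive", "yfgF", "anaerobiosis")]
        ) == []

    def test_never_overwrites_attested_gc(self):
        rec = resolve_effect(
            InteractionRecord(
                "FNR", "yfgF", support_negative=2, gcs=[("anaerobiosis", 2)]
            )
        )
        assert infer_complementary(
            [rec], [S(None, "negative", "yfgF", "anaerobiosis")]
        ) == []

    def test_end_to_end_over_worked_corpus(self, example_corpus, lexicon):
        result = run_pipeline(example_corpus, lexicon, annotate=False)
        hyps = infer_complementary(result.records, result.partials)
        assert {(h.tf, h.target, h.resolved_effect) for h in hyps} == {
            ("FNR", "yfgF", "negative")
        }


class TestPartition:
    def test_three_way_routing(self):
        full = resolve_effect(
            InteractionRecord("FNR", "yhjA", support_positive=1,
                              gcs=[("anaerobiosis", 1)])
        )
        no_gc = resolve_effect(InteractionRecord("CRP", "oxyR", support_positive=1))
        partial = S(None, "positive", "sodA", "manganese")
        got_full, got_nogc, got_gconly = partition_outputs(
            [full, no_gc], [partial]
        )
        assert got_full == [full] and got_nogc == [no_gc]
        assert len(got_gconly) == 1
        row = got_gconly[0]
        assert (row.gc, row.effect, row.target) == ("manganese", "induction", "sodA")

    def test_negative_partial_renders_inhibition(self):
        _, _, gc_only = partition_outputs([], [S(None, "negative", "mntS", "manganese")])
        assert gc_only[0].effect == "inhibition"


class TestConflictRecovery:
    def test_planted_effects_recovered_under_low_conflict(self, lexicon):
        """With conflict injection below 1 - majority_ratio, majority vote
        recovers every planted polarity."""
        config = SyntheticConfig(
            n_documents=6, sentences_per_document=60, distractor_rate=0.3,
            conflict_rate=0.05, seed=13,
        )
        corpus, truth = generate_synthetic_corpus(config, lexicon)
        result = run_pipeline(corpus, lexicon)
        by_key = {r.key: r for r in result.records}
        planted = {
            (tf, target): effect for tf, effect, target, _ in config.planted_tuples
        }
        checked = 0
        for key, effect in planted.items():
            rows = [t for t in truth if (t.tf, t.target) == key]
            if not rows:
                continue
            flip_fraction = sum(t.flipped for t in rows) / len(rows)
            if flip_fraction < 0.1:  # premise of the majority-vote guarantee
                assert by_key[key].resolved_effect == effect
                checked += 1
        assert checked >= 4

    def test_support_counts_match_generator_log(self, lexicon):
        config = SyntheticConfig(
            n_documents=4, sentences_per_document=50, distractor_rate=0.3,
            conflict_rate=0.3, seed=21,
        )
        corpus, truth = generate_synthetic_corpus(config, lexicon)
        result = run_pipeline(corpus, lexicon)
        by_key = {r.key: r for r in result.records}
        planted = {(tf, t) for tf, _, t, _ in config.planted_tuples}
        assert sum(t.flipped for t in truth) > 0
        for key in planted:
            rows = [t for t in truth if (t.tf, t.target) == key]
            if not rows:
                continue
            rec = by_key[key]
            assert rec.support_positive == sum(
                1 for t in rows if t.effect == "positive"
            )
            assert rec.support_negative == sum(
                1 for t in rows if t.effect == "negative"
            )
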