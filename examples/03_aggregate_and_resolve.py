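"""Aggregate sentence structures into interaction records and resolve conflicts.

Support counts per polarity accumulate across sentences; a 65-vs-1 split
resolves by majority while staying flagged for curator review, and
complementary partial statements hypothesize a full record.
"""

from regumine import datasets, infer_complementary, run_pipeline
from regumine.aggregation import InteractionRecord, resolve_effect

lexicon = datasets.load_builtin_lexicon()
result = run_pipeline(datasets.load_example_corpus(), lexicon)

for rec in result.records:
    print(f"  {rec.tf} -> {rec.target}: {rec.resolved_effect} "
          f"(+{rec.support_positive}/-{rec.support_negative}, {rec.status}) "
          f"gcs={rec.gcs}")

# conflict resolution on a heavily skewed split (65 repression sentences,
# one activation, three non-directional that never vote):
flu = resolve_effect(InteractionRecord(
    "OxyR", "flu", support_positive=1, support_negative=65,
    support_nondirectional=3,
))
print(f"\n  OxyR -> flu resolves {flu.resolved_effect} ({flu.status})")

hyps = infer_complementary(result.records, result.partials)
for h in hyps:
    print(f"  hypothesized: {h.tf} -> {h.target} {h.resolved_effect} gcs={h.gcs}")
# The FNR record and the TF-less "[−] yfgF [anaerobiosis]" partial complement
# each other into a hypothesized full statement.
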