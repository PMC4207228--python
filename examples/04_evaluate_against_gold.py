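"""Score extracted interaction records against the OxyR gold standard.

Reports interaction recall, effect agreement (dual resolutions count as
disagreement) and growth-condition coverage.
"""

from regumine import compare, datasets

lexicon = datasets.load_builtin_lexicon()
gold = datasets.load_oxyr_gold(lexicon)
extracted = datasets.load_oxyr_extracted(lexicon)
report = compare(
    extracted, gold, lexicon=lexicon,
    operon_members=datasets.load_operon_members(),
)
print(report)
# All 21 gold interactions are recalled (recall 100%); 19 effects agree (the
# two conflicted interactions resolve dual); 16 of 21 interactions have a
# matching growth condition (76% coverage).
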