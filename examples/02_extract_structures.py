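"""Map one sentence to its normalized semantic structures.

A single sentence with contrastive clauses and a coordinated gene list
instantiates several (TF, effect, target, condition) tuples; exclusion rules
drop an out-of-dictionary target and strip an uninformative condition.
"""

from regumine import datasets
from regumine.extraction import apply_exclusions, extract_structures
from regumine.terminology import annotate_corpus

lexicon = datasets.load_builtin_lexicon()
documents = [
    d for d in datasets.load_example_corpus() if d.doc_id == "oxyr-binding-modes"
]
annotate_corpus(documents, lexicon)
sentence = documents[0].sentences[0]
print(sentence.text, "\n")

raw = extract_structures(sentence, lexicon)
kept, excluded = apply_exclusions(raw, lexicon)
for s in kept:
    gc = f" [{s.gc}]" if s.gc else ""
    print(f"  kept: {s.tf} [{'+' if s.effect == 'positive' else '-'}] {s.target}{gc}  ({s.form})")
for s in excluded:
    print(f"  excluded: {s.tf} -> {s.target}  reason={s.exclusion_reason}")
# Six tuples are kept: the autoregulation tuple loses its uninformative
# "normal growth" condition (demoted to the no-condition form), and the
# coordinated activation distributes over five targets; "mom" is excluded
# because it is not an E. coli gene.
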