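"""Annotate a tiny corpus by dictionary lookup and keep informative sentences.

The filter "class:gene AND class:effect" keeps exactly the sentences that
name both a target gene and an effect word — the sentences worth a curator's
attention.
"""

from regumine import apply_filter, corpus_stats, datasets
from regumine.terminology import annotate_corpus

lexicon = datasets.load_builtin_lexicon()
documents = datasets.load_example_corpus()
annotate_corpus(documents, lexicon)

retained = apply_filter(documents, "class:gene AND class:effect")
stats = corpus_stats(documents, retained)
print(f"retained {stats.retained_sentences} of {stats.total_sentences} "
      f"sentences ({stats.retained_percent}%)")
for sentence in retained:
    entities = ", ".join(
        f"{a.surface}/{a.entity_class}" for a in sentence.annotations
    )
    print(f"  [{sentence.doc_id}:{sentence.sentence_id}] {entities}")
# Every retained sentence carries at least one gene and one effect annotation;
# the dropped ones carry no extractable regulatory assertion.
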