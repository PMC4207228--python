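"""Generate a synthetic corpus with planted truth and measure the pipeline.

With synonym noise only (every planted term may surface as a non-reference
synonym) the pipeline is exact; as planted surfaces leave the dictionary,
recall degrades while precision holds.
"""

from regumine import (
    SyntheticConfig,
    datasets,
    generate_synthetic_corpus,
    run_pipeline,
    score_against_truth,
)

lexicon = datasets.load_builtin_lexicon()
for unknown_rate in (0.0, 0.25, 0.5):
    config = SyntheticConfig(
        n_documents=4, sentences_per_document=50, distractor_rate=0.5,
        synonym_noise_rate=0.3, conjunction_rate=0.3,
        unknown_synonym_rate=unknown_rate, seed=11,
    )
    corpus, truth = generate_synthetic_corpus(config, lexicon)
    result = run_pipeline(corpus, lexicon)
    precision, recall = score_against_truth(result.kept, truth)
    print(f"unknown_synonym_rate={unknown_rate}: "
          f"precision={precision:.2f} recall={recall:.2f} "
          f"({len(truth)} planted structures)")
# Recall falls monotonically with the unknown-surface rate: dictionary lookup
# cannot recover a term it has never seen, which is exactly the failure mode
# real corpora exhibit for unlisted synonyms.
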