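"""End-to-end assisted-curation pipeline.

Wires the stages together: annotate every sentence by dictionary lookup,
retain informative sentences with a filter (default: a target gene AND an
effect word in the same sentence), map retained sentences to normalized
structures, apply the exclusion rules, aggregate TF-bearing structures into
interaction records, and resolve effect conflicts by majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .aggregation import InteractionRecord, aggregate, resolve_effect
from .corpus import CorpusStats, Document, Sentence, corpus_stats
from .extraction import (
    DEFAULT_CONFIG,
    ExtractionConfig,
    SemanticStructure,
    apply_exclusions,
    extract_structures,
)
from .filters import FilterConfig, apply_filter, parse_filter
from .terminology import Lexicon, annotate_corpus

DEFAULT_FILTER = "class:gene AND class:effect"


@dataclass
class PipelineResult:
    documents: list[Document]
    filtered: list[Sentence]
    stats: CorpusStats
    kept: list[SemanticStructure] = field(default_factory=list)
    excluded: list[SemanticStructure] = field(default_factory=list)
    records: list[InteractionRecord] = field(default_factory=list)

    @property
    def partials(self) -> list[SemanticStructure]:
        """Kept TF-less structures ([effect] gene [GC])."""
        return [s for s in self.kept if s.tf is None]


def run_pipeline(
    documents: Sequence[Document],
    lexicon: Lexicon,
    filter_expr: str = DEFAULT_FILTER,
    extraction_config: ExtractionConfig = DEFAULT_CONFIG,
    filter_config: FilterConfig | None = None,
    majority_ratio: float = 0.9,
    annotate: bool = True,
) -> PipelineResult:
    """Run the full pipeline over an in-memory corpus.

    Sentences are (re-)annotated unless ``annotate=False`` (useful when
    annotations were loaded or hand-corrected).  Directional structures whose
    sentences only validate others (non-directional effects) are kept but
    never vote in conflict resolution.
    """
    documents = list(documents)
    if annotate:
        annotate_corpus(documents, lexicon)
    expr = parse_filter(filter_expr)
    filtered = apply_filter(documents, expr, filter_config)
    stats = corpus_stats(documents, filtered)
    kept: list[SemanticStructure] = []
    excluded: list[SemanticStructure] = []
    for sentence in filtered:
        raw = extract_structures(sentence, lexicon, extraction_config)
        k, e = apply_exclusions(raw, lexicon, extraction_config)
        kept.extend(k)
        excluded.extend(e)
    # non-directional structures are tallied on the record but never vote
    records = [resolve_effect(r, majority_ratio) for r in aggregate(kept)]
    return PipelineResult(
        documents=documents,
        filtered=filtered,
        stats=stats,
        kept=kept,
        excluded=excluded,
        records=records,
    )
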