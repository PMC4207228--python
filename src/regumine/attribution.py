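"""Evidence classification and source-paper attribution.

Curating an interaction into a database requires the *original* paper that
experimentally supports it, not merely a paper that repeats it.  Three cues
help: sentences pointing at the paper's own figures or tables describe the
authors' experiments; explicit experimental-evidence phrasing ("we
demonstrated ...", assay names) likewise; and a paper asserting the same
interaction in three or more sentences is very likely reporting its own
result.  Conversely, a sentence that attaches a citation is usually relaying
someone else's finding — the cited paper becomes a candidate original.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .aggregation import InteractionRecord
from .corpus import Document, Sentence

EVIDENCE_LABELS = ("evidence", "figure_table", "reference", "reference_linked", "none")


@dataclass(frozen=True)
class EvidenceTag:
    label: str
    cues: tuple[str, ...] = ()


@dataclass(frozen=True)
class SourceCandidate:
    doc_id: str
    score: int
    rationale: str


@dataclass(frozen=True)
class AttributionWeights:
    """Additive scoring weights; the defaults rank a paper with three
    same-interaction sentences and in-sentence evidence far above passers-by."""

    per_sentence: int = 1
    any_evidence: int = 2
    frequency_bonus: int = 3
    frequency_threshold: int = 3  # per-paper sentence count needed for the bonus
    per_citation: int = 2  # credit to a paper cited by a supporting sentence


DEFAULT_WEIGHTS = AttributionWeights()

_FIGURE_TABLE = re.compile(r"\b(?:Figure|Figs?\.?|Table)\s*\d", re.IGNORECASE)
_EVIDENCE = re.compile(
    r"\bwe\s+(?:demonstrated|found|show(?:ed)?|observed|determined|identified)\b"
    r"|\bour\s+(?:results|data|experiments)\b"
    r"|\b(?:northern|western)\s+blot\b|\bfootprinting\b|\bgel\s+(?:mobility\s+)?shift\b"
    r"|\bprimer\s+extension\b|\breporter\s+fusion\b",
    re.IGNORECASE,
)
_CITATION_MARKER = re.compile(
    r"\[\d+(?:[,–-]\s*\d+)*\]|\(PMID:?\s*\d{6,8}\)|\(\w[\w\s.]*et al\.?,?\s*\d{4}\)"
)


def classify_evidence(sentence: Sentence) -> EvidenceTag:
    """Tag a sentence by its strongest evidence cue.

    Precedence figure_table > evidence > reference: a figure/table pointer is
    the most direct sign of the authors' own experiment, even when the
    sentence also cites prior work.
    """
    cues = tuple(m.group(0) for m in _FIGURE_TABLE.finditer(sentence.text))
    if cues:
        return EvidenceTag("figure_table", cues)
    cues = tuple(m.group(0) for m in _EVIDENCE.finditer(sentence.text))
    if cues:
        return EvidenceTag("evidence", cues)
    citation_cues = tuple(m.group(0) for m in _CITATION_MARKER.finditer(sentence.text))
    if sentence.cited_pmids or citation_cues:
        return EvidenceTag("reference", citation_cues)
    return EvidenceTag("none")


def tag_corpus(documents: Sequence[Document]) -> None:
    """Set ``evidence_tag`` on every sentence that does not already carry one."""
    for doc in documents:
        for sentence in doc.sentences:
            if sentence.evidence_tag is None:
                sentence.evidence_tag = classify_evidence(sentence).label


def attribute_sources(
    record: InteractionRecord,
    documents: Sequence[Document],
    weights: AttributionWeights = DEFAULT_WEIGHTS,
) -> list[SourceCandidate]:
    """Rank candidate source papers for an interaction record.

    Every paper whose sentences support the record scores the per-sentence
    weight for each distinct supporting sentence, the evidence bonus if any of
    them is tagged evidence or figure_table, and the frequency bonus when the
    per-paper sentence count reaches the threshold.  Papers *cited by*
    supporting sentences are added as candidate originals ("cited").  Sorted
    by descending score, ties by doc_id.
    """
    if not record.sentence_keys:
        return []
    index: dict[tuple[str, str], Sentence] = {}
    for doc in documents:
        for sentence in doc.sentences:
            index[(doc.doc_id, sentence.sentence_id)] = sentence
    per_paper_sentences: dict[str, set[str]] = {}
    evidence_papers: set[str] = set()
    citation_credit: dict[str, int] = {}
    for doc_id, sent_id in record.sentence_keys:
        per_paper_sentences.setdefault(doc_id, set()).add(sent_id)
        sentence = index.get((doc_id, sent_id))
        if sentence is None:
            continue
        tag = sentence.evidence_tag or classify_evidence(sentence).label
        if tag in ("evidence", "figure_table") or "evidence" in tag:
            evidence_papers.add(doc_id)
        for cited in sentence.cited_pmids:
            if cited != doc_id:
                citation_credit[cited] = (
                    citation_credit.get(cited, 0) + weights.per_citation
                )
    candidates: dict[str, tuple[int, list[str]]] = {}
    for doc_id, sentences in per_paper_sentences.items():
        score = weights.per_sentence * len(sentences)
        rationale = [f"{len(sentences)} supporting sentence(s)"]
        if doc_id in evidence_papers:
            score += weights.any_evidence
            rationale.append("in-sentence evidence")
        if len(sentences) >= weights.frequency_threshold:
            score += weights.frequency_bonus
            rationale.append(f"mentioned >= {weights.frequency_threshold} times")
        candidates[doc_id] = (score, rationale)
    for doc_id, credit in citation_credit.items():
        if doc_id in candidates:
            score, rationale = candidates[doc_id]
            candidates[doc_id] = (score + credit, rationale + ["cited"])
        else:
            candidates[doc_id] = (credit, ["cited"])
    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [
        SourceCandidate(doc_id=doc_id, score=score, rationale="; ".join(why))
        for doc_id, (score, why) in ranked
    ]


def write_attribution_tsv(
    record: InteractionRecord, candidates: Sequence[SourceCandidate], path
) -> None:
    from pathlib import Path

    lines = ["tf\ttarget\tcandidate_pmid\tscore\trationale"]
    for c in candidates:
        lines.append(
            f"{record.tf}\t{record.target}\t{c.doc_id}\t{c.score}\t{c.rationale}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
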