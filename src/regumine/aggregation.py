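"""Corpus-level consolidation of sentence structures into interaction records.

Sentence-level structures are aggregated per (TF, target) pair with support
counts per effect polarity.  Conflicts between sentences are resolved by
majority: if one direction carries at least ``majority_ratio`` of the
directional support (default 0.9), it wins — a 65-vs-1 split resolves cleanly
while the minority keeps the record flagged ``conflicting`` for curator
review.  Non-directional ("regulated") and explicit no-effect sentences are
tallied but never vote.

Partial structures complement each other across papers: a ``TF [e] gene``
record and an ``[e] gene [GC]`` association with matching target and polarity
jointly support the full ``TF [e] gene [GC]`` statement, emitted as a
*hypothesized* record.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .extraction import SemanticStructure

EFFECT_DISPLAY = {
    "positive": "induction",
    "negative": "inhibition",
    "nondirectional": "regulation",
    "no_effect": "no effect",
}


@dataclass
class InteractionRecord:
    """Aggregate of all structures asserting one (TF, target) interaction."""

    tf: str
    target: str
    support_positive: int = 0
    support_negative: int = 0
    support_nondirectional: int = 0
    support_no_effect: int = 0
    resolved_effect: str = "unresolved"
    status: str = "supported"
    gcs: list[tuple[str, int]] = field(default_factory=list)
    per_paper_counts: dict[str, int] = field(default_factory=dict)
    sentence_keys: list[tuple[str, str]] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.tf, self.target)

    @property
    def total_support(self) -> int:
        return (
            self.support_positive
            + self.support_negative
            + self.support_nondirectional
            + self.support_no_effect
        )

    @property
    def directional_support(self) -> int:
        return self.support_positive + self.support_negative


def aggregate(structures: Sequence[SemanticStructure]) -> list[InteractionRecord]:
    """One record per (TF, target) key among TF-bearing structures.

    Growth-condition lists are unions with per-condition counts.  The result
    is independent of input order: records are sorted by key and GC lists by
    descending count then name.
    """
    buckets: dict[tuple[str, str], list[SemanticStructure]] = {}
    for s in structures:
        if s.tf is None:
            continue
        buckets.setdefault((s.tf, s.target), []).append(s)
    records: list[InteractionRecord] = []
    for (tf, target), group in sorted(buckets.items()):
        rec = InteractionRecord(tf=tf, target=target)
        gc_counts: Counter[str] = Counter()
        papers: set[tuple[str, str]] = set()
        for s in group:
            if s.effect == "positive":
                rec.support_positive += 1
            elif s.effect == "negative":
                rec.support_negative += 1
            elif s.effect == "nondirectional":
                rec.support_nondirectional += 1
            elif s.effect == "no_effect":
                rec.support_no_effect += 1
            else:
                raise ValueError(f"unknown effect {s.effect!r}")
            if s.gc is not None:
                gc_counts[s.gc] += 1
            if s.doc_id is not None and s.sentence_id is not None:
                papers.add((s.doc_id, s.sentence_id))
        rec.gcs = sorted(gc_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rec.sentence_keys = sorted(papers)
        rec.per_paper_counts = dict(
            Counter(doc_id for doc_id, _ in papers)
        )
        records.append(rec)
    return records


def resolve_effect(
    record: InteractionRecord, majority_ratio: float = 0.9
) -> InteractionRecord:
    """Set ``resolved_effect`` and ``status`` by directional majority vote.

    A polarity whose share of directional support reaches ``majority_ratio``
    wins; any minority support still marks the record ``conflicting``.  Below
    the threshold the effect is ``dual``.  With no directional support at all
    the record stays ``unresolved``.  Mutates and returns the record.
    """
    pos, neg = record.support_positive, record.support_negative
    total = pos + neg
    if total == 0:
        record.resolved_effect = "unresolved"
        record.status = "supported"
        return record
    if pos / total >= majority_ratio:
        record.resolved_effect = "positive"
        record.status = "conflicting" if neg else "supported"
    elif neg / total >= majority_ratio:
        record.resolved_effect = "negative"
        record.status = "conflicting" if pos else "supported"
    else:
        record.resolved_effect = "dual"
        record.status = "conflicting"
    return record


def infer_complementary(
    records: Sequence[InteractionRecord],
    partials: Sequence[SemanticStructure],
) -> list[InteractionRecord]:
    """Hypothesize full records from complementary partial structures.

    For each ``TF [e] target`` record and each ``[e] target [GC]`` partial
    whose target and polarity match, a hypothesized ``TF [e] target [GC]``
    record is emitted — unless a full-form structure already attests that GC
    on the record, which is never overwritten.
    """
    attested = {
        (rec.tf, rec.target): {gc for gc, _ in rec.gcs} for rec in records
    }
    out: dict[tuple[str, str], InteractionRecord] = {}
    for rec in records:
        for partial in partials:
            if partial.tf is not None or partial.gc is None:
                continue
            if partial.target != rec.target:
                continue
            if partial.effect not in ("positive", "negative"):
                continue
            supported = (
                rec.support_positive if partial.effect == "positive" else rec.support_negative
            )
            if supported == 0:
                continue
            if partial.gc in attested[(rec.tf, rec.target)]:
                continue
            hyp = out.setdefault(
                (rec.tf, rec.target),
                InteractionRecord(
                    tf=rec.tf,
                    target=rec.target,
                    resolved_effect=partial.effect,
                    status="hypothesized",
                ),
            )
            gcs = dict(hyp.gcs)
            gcs[partial.gc] = gcs.get(partial.gc, 0) + 1
            hyp.gcs = sorted(gcs.items(), key=lambda kv: (-kv[1], kv[0]))
    return list(out.values())


@dataclass(frozen=True)
class GcAssociation:
    """A TF-less row: condition, display effect, target gene/operon."""

    gc: str
    effect: str  # "induction" / "inhibition" / "regulation" / "no effect"
    target: str


def partition_outputs(
    records: Sequence[InteractionRecord],
    partials: Sequence[SemanticStructure] = (),
) -> tuple[list[InteractionRecord], list[InteractionRecord], list[GcAssociation]]:
    """Split results into the three curation tables.

    (1) full RI+GC records (TF and at least one GC), (2) RI records without
    GC, and (3) GC-to-gene associations lacking a TF, whose effects are
    rendered "induction"/"inhibition" because the mechanism is unknown.
    """
    full = [r for r in records if r.gcs]
    no_gc = [r for r in records if not r.gcs]
    gc_only: list[GcAssociation] = []
    seen: set[tuple[str, str, str]] = set()
    for s in partials:
        if s.tf is not None or s.gc is None:
            continue
        row = GcAssociation(
            gc=s.gc, effect=EFFECT_DISPLAY[s.effect], target=s.target
        )
        key = (row.gc, row.effect, row.target)
        if key not in seen:
            seen.add(key)
            gc_only.append(row)
    return full, no_gc, gc_only


def write_interactions_tsv(
    records: Iterable[InteractionRecord], path: str | Path
) -> None:
    header = (
        "tf\ttarget\tresolved_effect\tstatus\tsupport_pos\tsupport_neg\t"
        "support_nondir\tsupport_noeffect\tgcs\tpapers"
    )
    lines = [header]
    for r in records:
        gcs = ";".join(f"{gc}:{n}" for gc, n in r.gcs)
        papers = ";".join(
            f"{doc}:{n}" for doc, n in sorted(r.per_paper_counts.items())
        )
        lines.append(
            "\t".join(
                [
                    r.tf,
                    r.target,
                    r.resolved_effect,
                    r.status,
                    str(r.support_positive),
                    str(r.support_negative),
                    str(r.support_nondirectional),
                    str(r.support_no_effect),
                    gcs,
                    papers,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
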