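"""Scoring extracted interaction records against a gold-standard table.

The gold standard is a curated reference list of regulatory interactions —
(TF, target, effect, growth-condition set) — such as a database export for
one transcription factor.  The report measures how much of it assisted
curation recovered: interaction recall, effect agreement (a dual/conflicting
resolution counts as disagreement), and growth-condition coverage, optionally
accepting a more general or more specific condition term as a match.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .aggregation import InteractionRecord
from .terminology import Lexicon, generalize_gc, normalize


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class GoldRecord:
    tf: str
    target: str
    effect: str  # positive / negative / dual
    gcs: frozenset[str] = frozenset()


_EFFECT_WORDS = {
    "activator": "positive",
    "activation": "positive",
    "positive": "positive",
    "repressor": "negative",
    "repression": "negative",
    "negative": "negative",
    "dual": "dual",
    "activator/repressor": "dual",
}


def _parse_effect(raw: str) -> str:
    word = raw.strip().strip("'‘’“”").lower()
    try:
        return _EFFECT_WORDS[word]
    except KeyError:
        raise EvaluationError(f"unknown effect label {raw!r}")


def load_gold(path: str | Path, lexicon: Lexicon | None = None) -> list[GoldRecord]:
    """Load a gold TSV (columns tf, target, effect, gcs).

    Effects accept curation-style labels ("Activator", "Repressor",
    "Activator/repressor").  GC cells hold comma-separated terms; the literal
    "Not found" (or an empty cell) means no condition is on record.  Terms
    are normalized to reference terms when a lexicon is given (leniently:
    unknown terms pass through).
    """
    records: list[GoldRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in ("tf", "target", "effect", "gcs"):
            if col not in (reader.fieldnames or []):
                raise EvaluationError(f"{path}: missing column {col!r}")
        for row in reader:
            gcs = _parse_gcs(row["gcs"], lexicon)
            rec = GoldRecord(
                tf=row["tf"].strip(),
                target=row["target"].strip(),
                effect=_parse_effect(row["effect"]),
                gcs=gcs,
            )
            if (rec.tf, rec.target) in seen:
                raise EvaluationError(
                    f"duplicate gold key ({rec.tf}, {rec.target})"
                )
            seen.add((rec.tf, rec.target))
            records.append(rec)
    return records


def _parse_gcs(cell: str, lexicon: Lexicon | None) -> frozenset[str]:
    cell = cell.strip()
    if not cell or cell.lower() == "not found":
        return frozenset()
    terms = [t.strip() for t in cell.split(",") if t.strip()]
    if lexicon is not None:
        terms = [normalize(t, lexicon, lenient=True) for t in terms]
    return frozenset(terms)


@dataclass
class EvaluationReport:
    n_gold: int
    n_extracted: int
    matched_keys: list[tuple[str, str]] = field(default_factory=list)
    effect_agreements: list[tuple[str, str]] = field(default_factory=list)
    gc_covered_keys: list[tuple[str, str]] = field(default_factory=list)
    novel_records: list[tuple[str, str]] = field(default_factory=list)

    @property
    def recall(self) -> float:
        return len(self.matched_keys) / self.n_gold

    @property
    def precision(self) -> float:
        if self.n_extracted == 0:
            return 0.0
        return len(self.matched_keys) / self.n_extracted

    @property
    def effect_agreement(self) -> int:
        return len(self.effect_agreements)

    @property
    def gc_coverage(self) -> float:
        return len(self.gc_covered_keys) / self.n_gold

    @property
    def gc_coverage_percent(self) -> int:
        """Coverage as a whole percentage (nearest integer)."""
        return round(100 * self.gc_coverage)

    @property
    def recall_percent(self) -> int:
        return round(100 * self.recall)

    def as_rows(self) -> list[tuple[str, str]]:
        return [
            ("gold_records", str(self.n_gold)),
            ("extracted_records", str(self.n_extracted)),
            ("matched", str(len(self.matched_keys))),
            ("recall_percent", str(self.recall_percent)),
            ("effect_agreement", str(self.effect_agreement)),
            ("gc_covered", str(len(self.gc_covered_keys))),
            ("gc_coverage_percent", str(self.gc_coverage_percent)),
            ("novel_records", str(len(self.novel_records))),
        ]

    def __str__(self) -> str:
        lines = [f"{k}: {v}" for k, v in self.as_rows()]
        return "\n".join(lines)


def compare(
    records: Sequence[InteractionRecord],
    gold: Sequence[GoldRecord],
    gc_match: str = "exact",
    lexicon: Lexicon | None = None,
    operon_members: Mapping[str, Sequence[str]] | None = None,
) -> EvaluationReport:
    """Score extracted records against a gold set.

    Matching key is (TF, target); a gene target matches an operon target (and
    vice versa) only through the explicit ``operon_members`` table.  With
    ``gc_match="general_ok"`` a gold condition also matches an extracted
    condition one step away in the general/specific hierarchy (requires a
    lexicon).
    """
    if not gold:
        raise EvaluationError("gold set is empty")
    if gc_match not in ("exact", "general_ok"):
        raise EvaluationError(f"unknown gc_match mode {gc_match!r}")
    members = {k: set(v) for k, v in (operon_members or {}).items()}

    def targets_match(a: str, b: str) -> bool:
        if a == b:
            return True
        return a in members.get(b, ()) or b in members.get(a, ())

    def gcs_match(extracted_gc: str, gold_gc: str) -> bool:
        if extracted_gc == gold_gc:
            return True
        if gc_match == "general_ok" and lexicon is not None:
            try:
                if generalize_gc(extracted_gc, lexicon) == gold_gc:
                    return True
                if generalize_gc(gold_gc, lexicon) == extracted_gc:
                    return True
            except Exception:
                return False
        return False

    report = EvaluationReport(n_gold=len(gold), n_extracted=len(records))
    matched_records: set[tuple[str, str]] = set()
    for g in gold:
        match = next(
            (
                r
                for r in records
                if r.tf == g.tf and targets_match(r.target, g.target)
            ),
            None,
        )
        if match is None:
            continue
        key = (g.tf, g.target)
        report.matched_keys.append(key)
        matched_records.add(match.key)
        if match.resolved_effect == g.effect and g.effect != "dual":
            report.effect_agreements.append(key)
        if any(
            gcs_match(gc, gold_gc)
            for gc, _ in match.gcs
            for gold_gc in g.gcs
        ):
            report.gc_covered_keys.append(key)
    report.novel_records = [
        r.key for r in records if r.key not in matched_records
    ]
    return report
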