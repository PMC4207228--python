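"""Entity dictionaries and lexical-lookup annotation.

Named entities (genes, TFs, operons, effect words, growth conditions) are
recognized by dictionary lookup with orthographic variants, the approach used
for assisted curation of bacterial regulatory interactions.  Each surface form
maps to a canonical identifier; synonym sets share one canonical (the
*reference term*), and growth-condition terms may carry a link to a more
general parent condition (e.g. "hydrogen peroxide treatment" is a specific
form of "oxidative stress").

Case policy: entries of four characters or fewer match case-sensitively at
word boundaries (short gene names such as "dps" or "fold" are too ambiguous
otherwise), longer entries match case-insensitively.  Overlapping hits are
resolved longest-match-wins, leftmost on ties.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Sentence, TermAnnotation

SHORT_NAME_LEN = 4

ENTRY_CLASSES = (
    "gene",
    "tf",
    "operon",
    "effect",
    "growth_condition",
    "system_alias",
    "stoplist",
)

_NUMBER_WORDS = (
    "one two three four five six seven eight nine ten eleven twelve "
    "twenty fifty hundred several many".split()
)


class LexiconError(ValueError):
    """Raised for malformed lexicon files or unknown terms."""


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    canonical: str
    entity_class: str
    polarity: str = "not_applicable"
    parent: str | None = None
    is_reference_term: bool = False

    def __post_init__(self) -> None:
        if self.entity_class not in ENTRY_CLASSES:
            raise LexiconError(f"unknown entity class {self.entity_class!r}")
        if self.polarity != "not_applicable" and self.entity_class != "effect":
            raise LexiconError(
                f"polarity set on non-effect entry {self.surface!r}"
            )

    @property
    def case_sensitive(self) -> bool:
        return len(self.surface) <= SHORT_NAME_LEN


def generate_variants(entry: LexiconEntry) -> set[str]:
    """Orthographic variants of an entry's surface form.

    Always includes the original.  Multi-token surfaces additionally get
    hyphen/space interchanges.  Entries longer than four characters also get
    case variants (lower-cased and sentence-case); matching for long entries
    is case-insensitive, so these enumerate the canonical spellings rather
    than every case permutation.
    """
    base = {entry.surface}
    if " " in entry.surface or "-" in entry.surface:
        base.add(entry.surface.replace(" ", "-"))
        base.add(entry.surface.replace("-", " "))
    if not entry.case_sensitive:
        for v in list(base):
            base.add(v.lower())
            if v:
                base.add(v[0].upper() + v[1:])
    return base


@dataclass
class Lexicon:
    """Indexed collection of lexicon entries plus an ambiguity stoplist."""

    entries: list[LexiconEntry] = field(default_factory=list)
    stoplist: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._by_class: dict[str, list[LexiconEntry]] = {}
        self._reference: dict[str, LexiconEntry] = {}
        self._surface_map: dict[str, list[LexiconEntry]] = {}
        seen: set[tuple[str, str]] = set()
        for entry in self.entries:
            key = (entry.surface, entry.entity_class)
            if key in seen:
                raise LexiconError(f"duplicate lexicon row {key!r}")
            seen.add(key)
            self._register(entry)
        self._validate()

    def _register(self, entry: LexiconEntry) -> None:
        self._by_class.setdefault(entry.entity_class, []).append(entry)
        if entry.is_reference_term:
            if entry.canonical in self._reference:
                raise LexiconError(
                    f"multiple reference terms for canonical {entry.canonical!r}"
                )
            self._reference[entry.canonical] = entry
        self._surface_map.setdefault(entry.surface.lower(), []).append(entry)

    def _validate(self) -> None:
        for canonical in {e.canonical for e in self.entries if e.entity_class != "stoplist"}:
            if canonical not in self._reference:
                raise LexiconError(
                    f"no reference term designated for canonical {canonical!r}"
                )
        # parent links must be acyclic
        parents = {
            e.canonical: e.parent
            for e in self.entries
            if e.is_reference_term and e.parent
        }
        for start in parents:
            slow: str | None = start
            seen_chain: set[str] = set()
            while slow is not None:
                if slow in seen_chain:
                    raise LexiconError(f"cyclic parent links at {start!r}")
                seen_chain.add(slow)
                slow = parents.get(slow)
        for surface in self.stoplist:
            hits = self._surface_map.get(surface.lower(), [])
            if not any(len(e.surface) <= SHORT_NAME_LEN for e in hits):
                raise LexiconError(
                    f"stoplist surface {surface!r} is not a short lexicon entry"
                )

    # -- lookup ------------------------------------------------------------

    def entries_of(self, *classes: str) -> list[LexiconEntry]:
        out: list[LexiconEntry] = []
        for cls in classes:
            out.extend(self._by_class.get(cls, []))
        return out

    def canonicals_of(self, *classes: str) -> set[str]:
        return {e.canonical for e in self.entries_of(*classes)}

    def reference_entry(self, canonical: str) -> LexiconEntry:
        try:
            return self._reference[canonical]
        except KeyError:
            raise LexiconError(f"unknown canonical {canonical!r}")

    def lookup_surface(self, surface: str) -> list[LexiconEntry]:
        return list(self._surface_map.get(surface.lower(), []))

    def __len__(self) -> int:
        return len(self.entries)


_COLUMNS = ("surface", "canonical", "entity_class", "polarity", "parent", "is_reference_term")


def load_lexicon(paths: str | Path | Sequence[str | Path]) -> Lexicon:
    """Load one or more lexicon TSV files into a single :class:`Lexicon`.

    Columns: surface, canonical, entity_class, polarity, parent,
    is_reference_term.  Rows with entity_class ``stoplist`` populate the
    ambiguity stoplist instead of the entry table.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    entries: list[LexiconEntry] = []
    stoplist: set[str] = set()
    for path in paths:
        path = Path(path)
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = [c for c in _COLUMNS if c not in (reader.fieldnames or [])]
            if missing:
                raise LexiconError(f"{path}: missing columns {missing}")
            for row in reader:
                if not row["surface"]:
                    continue
                if row["entity_class"] == "stoplist":
                    stoplist.add(row["surface"])
                    continue
                entries.append(
                    LexiconEntry(
                        surface=row["surface"],
                        canonical=row["canonical"] or row["surface"],
                        entity_class=row["entity_class"],
                        polarity=row["polarity"] or "not_applicable",
                        parent=row["parent"] or None,
                        is_reference_term=row["is_reference_term"].strip().lower()
                        in ("1", "true", "yes"),
                    )
                )
    return Lexicon(entries=entries, stoplist=stoplist)


def _boundary_pattern(variant: str) -> re.Pattern:
    # \b fails at non-alphanumeric edges (e.g. "2,2'-dipyridyl"); anchor on
    # the absence of adjacent word characters instead.
    return re.compile(rf"(?<!\w){re.escape(variant)}(?!\w)")


_NUMERIC_BEFORE = re.compile(
    r"(?:\d+(?:\.\d+)?|" + "|".join(_NUMBER_WORDS) + r")[\s-]*$",
    re.IGNORECASE,
)


def _in_numeric_context(text: str, start: int) -> bool:
    return bool(_NUMERIC_BEFORE.search(text[:start]))


def match_terms(sentence: Sentence, lexicon: Lexicon) -> list[TermAnnotation]:
    """Annotate a sentence by dictionary lookup with variants.

    Returns all dictionary hits at word boundaries after overlap resolution
    (longest match wins, leftmost on ties).  Short entries (<= 4 characters)
    require the exact case of the lexicon surface; stoplisted short surfaces
    are additionally dropped in numeric contexts ("two-fold").  A surface
    registered as both gene and TF is classed tf when it appears in
    capitalized protein form and gene otherwise.
    """
    text = sentence.text
    candidates: list[tuple[int, int, LexiconEntry]] = []
    for entry in lexicon.entries:
        if entry.entity_class == "stoplist":
            continue
        flags = 0 if entry.case_sensitive else re.IGNORECASE
        for variant in generate_variants(entry):
            pattern = re.compile(
                rf"(?<!\w){re.escape(variant)}(?!\w)", flags
            )
            for m in pattern.finditer(text):
                candidates.append((m.start(), m.end(), entry))
    # collapse duplicates per span, resolving gene/TF dual membership
    by_span: dict[tuple[int, int], list[LexiconEntry]] = {}
    for start, end, entry in candidates:
        by_span.setdefault((start, end), []).append(entry)
    resolved: list[tuple[int, int, LexiconEntry]] = []
    for (start, end), entries in by_span.items():
        surface = text[start:end]
        entry = _pick_entry(surface, entries)
        if entry is None:
            continue
        if surface in lexicon.stoplist and _in_numeric_context(text, start):
            continue
        resolved.append((start, end, entry))
    # longest match wins; ties leftmost
    resolved.sort(key=lambda item: (-(item[1] - item[0]), item[0]))
    kept: list[tuple[int, int, LexiconEntry]] = []
    for start, end, entry in resolved:
        if all(end <= s or e <= start for s, e, _ in kept):
            kept.append((start, end, entry))
    kept.sort(key=lambda item: item[0])
    return [
        TermAnnotation(
            start=start,
            end=end,
            surface=text[start:end],
            canonical=entry.canonical,
            entity_class=entry.entity_class,
            polarity=entry.polarity,
        )
        for start, end, entry in kept
        if entry.entity_class in ("gene", "tf", "operon", "effect", "growth_condition")
    ]


def _pick_entry(surface: str, entries: list[LexiconEntry]) -> LexiconEntry | None:
    """Resolve competing entries for one span.

    Gene/TF dual membership is decided by orthography: capitalized protein
    form ("OxyR") annotates as tf, lower-case gene form ("oxyR") as gene.
    Otherwise the first matching class in a fixed priority order wins.
    """
    classes = {e.entity_class for e in entries}
    if "gene" in classes and "tf" in classes:
        wanted = "tf" if surface[:1].isupper() else "gene"
        for e in entries:
            if e.entity_class == wanted:
                return e
    priority = ("tf", "operon", "gene", "effect", "growth_condition")
    for cls in priority:
        for e in entries:
            if e.entity_class == cls:
                return e
    return entries[0] if entries else None


def annotate_corpus(documents: Iterable, lexicon: Lexicon) -> None:
    """Annotate every sentence of a corpus in place."""
    for doc in documents:
        for sentence in doc.sentences:
            sentence.annotations = match_terms(sentence, lexicon)


def normalize(term: str, lexicon: Lexicon, lenient: bool = False) -> str:
    """Map a surface form or canonical identifier to its reference term.

    Idempotent: reference terms map to themselves.  Unknown terms raise
    :class:`LexiconError` unless ``lenient``, in which case they pass through
    unchanged.
    """
    hits = lexicon.lookup_surface(term)
    if hits:
        for e in hits:  # exact case first: gene/TF pairs differ only by case
            if e.surface == term:
                return e.canonical
        return hits[0].canonical
    if term in lexicon._reference:
        return term
    if lenient:
        return term
    raise LexiconError(f"unknown term {term!r}")


def generalize_gc(canonical: str, lexicon: Lexicon) -> str | None:
    """One step up the general/specific growth-condition hierarchy.

    Returns the parent canonical, or None at a root condition.
    """
    entry = lexicon.reference_entry(normalize(canonical, lexicon))
    return entry.parent


def resolve_system_alias(alias: str, lexicon: Lexicon) -> str:
    """Map a regulatory-system name (e.g. "ArcAB system") to its DNA-binding TF."""
    for e in lexicon.lookup_surface(alias):
        if e.entity_class == "system_alias":
            return e.canonical
        if e.entity_class == "tf":
            return e.canonical
    raise LexiconError(f"unknown system alias {alias!r}")
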