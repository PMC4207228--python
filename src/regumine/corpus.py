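"""Documents, sentences and standoff term annotations.

A corpus is an ordered list of :class:`Document` objects, each holding
individually enumerated :class:`Sentence` objects.  Annotations are standoff:
character spans into the sentence text, 0-based half-open.  Sentence text is
normalized to Unicode NFC before annotation so dictionary matching is stable.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ENTITY_CLASSES = ("gene", "tf", "operon", "effect", "growth_condition")
POLARITIES = ("positive", "negative", "nondirectional", "no_effect", "not_applicable")


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid document structure."""


@dataclass
class TermAnnotation:
    """One dictionary hit: a character span with its canonical identity."""

    start: int
    end: int
    surface: str
    canonical: str
    entity_class: str
    polarity: str = "not_applicable"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(f"invalid span [{self.start}, {self.end})")
        if self.entity_class not in ENTITY_CLASSES:
            raise CorpusError(f"unknown entity class {self.entity_class!r}")
        if self.polarity not in POLARITIES:
            raise CorpusError(f"unknown polarity {self.polarity!r}")
        if self.polarity != "not_applicable" and self.entity_class != "effect":
            raise CorpusError("polarity is only meaningful for effect annotations")

    def overlaps(self, other: "TermAnnotation") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Sentence:
    """A unit of text with a stable identifier and standoff annotations."""

    sentence_id: str
    ordinal: int
    text: str
    annotations: list[TermAnnotation] = field(default_factory=list)
    cited_pmids: list[str] = field(default_factory=list)
    evidence_tag: str | None = None
    doc_id: str | None = None

    def __post_init__(self) -> None:
        self.text = unicodedata.normalize("NFC", self.text)
        for ann in self.annotations:
            self._check_span(ann)

    def _check_span(self, ann: TermAnnotation) -> None:
        if ann.end > len(self.text):
            raise CorpusError(
                f"annotation [{ann.start}, {ann.end}) outside sentence "
                f"{self.sentence_id!r} of length {len(self.text)}"
            )
        if self.text[ann.start : ann.end] != ann.surface:
            raise CorpusError(
                f"annotation surface {ann.surface!r} does not match text slice "
                f"{self.text[ann.start:ann.end]!r}"
            )

    def annotations_of(self, *classes: str) -> list[TermAnnotation]:
        return [a for a in self.annotations if a.entity_class in classes]


@dataclass
class Document:
    doc_id: str
    sentences: list[Sentence] = field(default_factory=list)
    title: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, sent in enumerate(self.sentences, start=1):
            if sent.sentence_id in seen:
                raise CorpusError(
                    f"duplicate sentence id {sent.sentence_id!r} in {self.doc_id!r}"
                )
            seen.add(sent.sentence_id)
            if sent.ordinal != i:
                raise CorpusError(
                    f"sentence ordinals in {self.doc_id!r} must be consecutive from 1"
                )
            sent.doc_id = self.doc_id


# Protected abbreviations: a sentence boundary is never placed after these.
_ABBREVIATIONS = (
    "E.",      # E. coli
    "Fig.",
    "Figs.",
    "al.",     # et al.
    "i.e.",
    "e.g.",
    "vs.",
    "ca.",
    "approx.",
    "no.",
    "sp.",
    "spp.",
    "St.",
)

_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9Δ])")


def segment_sentences(raw: str) -> list[str]:
    """Split raw text into sentences at sentence-final punctuation.

    Boundaries require terminal punctuation followed by whitespace and an
    upper-case (or digit) start; a protected abbreviation list keeps spans
    such as "E. coli" and "Fig. 3" intact.  Degenerate input (no terminal
    punctuation) yields a single segment.  The concatenation of the segments,
    modulo the stripped inter-sentence whitespace, equals the input.
    """
    if not raw or not raw.strip():
        raise CorpusError("cannot segment empty text")
    text = unicodedata.normalize("NFC", raw.strip())
    pieces: list[str] = []
    start = 0
    for match in _BOUNDARY.finditer(text):
        candidate = text[start : match.start()]
        if any(candidate.endswith(abbr) for abbr in _ABBREVIATIONS):
            continue
        pieces.append(candidate)
        start = match.end()
    pieces.append(text[start:])
    return [p for p in pieces if p]


def _sentence_from_record(rec: dict, ordinal: int) -> Sentence:
    return Sentence(
        sentence_id=str(rec.get("sentence_id") or f"S{ordinal}"),
        ordinal=ordinal,
        text=rec["text"],
        cited_pmids=[str(p) for p in rec.get("cited_pmids", [])],
    )


def load_corpus(path: str | Path, format: str = "jsonl") -> list[Document]:
    """Load a corpus from a JSON-lines file or a plain-text document.

    JSON-lines: one object per document, ``{"doc_id": ..., "title": ...,
    "sentences": [{"sentence_id": ..., "text": ..., "cited_pmids": [...]}]}``.
    Pre-segmented sentences are preserved verbatim.  Plain text: the whole
    file is one document (doc_id = file stem) segmented automatically.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"no such corpus file: {path}")
    documents: list[Document] = []
    if format == "jsonl":
        seen_ids: set[str] = set()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"{path}:{lineno}: malformed JSON record: {exc}")
                if "doc_id" not in rec:
                    raise CorpusError(f"{path}:{lineno}: record lacks doc_id")
                doc_id = str(rec["doc_id"])
                if doc_id in seen_ids:
                    raise CorpusError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
                seen_ids.add(doc_id)
                sentences = [
                    _sentence_from_record(s, i)
                    for i, s in enumerate(rec.get("sentences", []), start=1)
                ]
                documents.append(
                    Document(doc_id=doc_id, sentences=sentences, title=rec.get("title"))
                )
    elif format == "plain_text":
        raw = path.read_text(encoding="utf-8")
        texts = segment_sentences(raw) if raw.strip() else []
        sentences = [
            Sentence(sentence_id=f"S{i}", ordinal=i, text=t)
            for i, t in enumerate(texts, start=1)
        ]
        documents.append(Document(doc_id=path.stem, sentences=sentences))
    else:
        raise CorpusError(f"unknown corpus format {format!r}")
    return documents


def write_corpus(documents: Sequence[Document], path: str | Path) -> None:
    """Write a corpus as JSON-lines (inverse of :func:`load_corpus`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            rec = {
                "doc_id": doc.doc_id,
                "sentences": [
                    {
                        "sentence_id": s.sentence_id,
                        "text": s.text,
                        "cited_pmids": s.cited_pmids,
                    }
                    for s in doc.sentences
                ],
            }
            if doc.title is not None:
                rec["title"] = doc.title
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def iter_sentences(documents: Iterable[Document]) -> Iterable[Sentence]:
    for doc in documents:
        yield from doc.sentences


@dataclass(frozen=True)
class CorpusStats:
    total_sentences: int
    retained_sentences: int

    @property
    def retained_fraction(self) -> float:
        return self.retained_sentences / self.total_sentences

    @property
    def retained_percent(self) -> float:
        """Retained share as a percentage, rounded to one decimal place."""
        return round(100.0 * self.retained_fraction, 1)


def corpus_stats(
    documents: Sequence[Document], filtered: Sequence[Sentence]
) -> CorpusStats:
    """Summarize how much of the corpus a sentence filter retained."""
    total = sum(len(d.sentences) for d in documents)
    if total == 0:
        raise CorpusError("corpus has no sentences")
    all_keys = {(s.doc_id, s.sentence_id) for s in iter_sentences(documents)}
    for sent in filtered:
        if (sent.doc_id, sent.sentence_id) not in all_keys:
            raise CorpusError(
                f"filtered sentence {sent.sentence_id!r} is not in the corpus"
            )
    return CorpusStats(total_sentences=total, retained_sentences=len(filtered))


def write_annotations_tsv(documents: Sequence[Document], path: str | Path) -> None:
    """Standoff annotation export: one row per annotation."""
    header = "doc_id\tsentence_id\tstart\tend\tsurface\tcanonical\tentity_class\tpolarity"
    lines = [header]
    for doc in documents:
        for sent in doc.sentences:
            for a in sent.annotations:
                lines.append(
                    "\t".join(
                        [
                            doc.doc_id,
                            sent.sentence_id,
                            str(a.start),
                            str(a.end),
                            a.surface,
                            a.canonical,
                            a.entity_class,
                            a.polarity,
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
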