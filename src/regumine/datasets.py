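"""Built-in datasets: a curated OxyR benchmark and the default lexicon.

The package ships, as plain TSV/JSONL under ``regumine/data``:

* the default entity lexicon for the *E. coli* oxidative-stress literature
  (genes, TFs, operons, effect words with polarity, growth conditions with
  synonym sets and general/specific links);
* a hand-curated benchmark around the OxyR regulon: the 21-interaction gold
  standard with growth conditions, the same interactions as an extraction run
  resolved them (including the two effect conflicts), 29 interactions of other
  TFs with conditions, 67 condition-to-gene associations lacking a TF, the
  OxyR-katG assertion table used for source attribution, and the 14 OxyR
  targets not present in the reference database;
* a three-document worked-example corpus.

The attribution corpus builder synthesizes placeholder sentence *texts* (the
benchmark table records only sentence IDs, normalized structures and evidence
labels); everything else is data carried verbatim.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .aggregation import GcAssociation, InteractionRecord
from .corpus import Document, Sentence
from .evaluation import GoldRecord, load_gold
from .extraction import SemanticStructure
from .terminology import Lexicon, load_lexicon, normalize

_DATA = resources.files("regumine") / "data"

DATA_FILES = (
    "lexicon.tsv",
    "operon_members.tsv",
    "oxyr_gold.tsv",
    "oxyr_extracted.tsv",
    "tf_gc_interactions.tsv",
    "condition_gene_associations.tsv",
    "katg_attribution.tsv",
    "novel_oxyr_targets.txt",
    "example_corpus.jsonl",
)


def data_path(name: str) -> Path:
    """Filesystem path of a shipped data file."""
    return Path(str(_DATA / name))


def load_builtin_lexicon() -> Lexicon:
    return load_lexicon(data_path("lexicon.tsv"))


def load_operon_members() -> dict[str, list[str]]:
    """Operon-to-member-gene table used for target matching in evaluation."""
    members: dict[str, list[str]] = {}
    with open(data_path("operon_members.tsv"), encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            members.setdefault(row["operon"], []).append(row["gene"])
    return members


def load_oxyr_gold(lexicon: Lexicon | None = None) -> list[GoldRecord]:
    """The 21 OxyR regulatory interactions of the reference database."""
    if lexicon is None:
        lexicon = load_builtin_lexicon()
    return load_gold(data_path("oxyr_gold.tsv"), lexicon=lexicon)


def load_oxyr_extracted(lexicon: Lexicon | None = None) -> list[InteractionRecord]:
    """The OxyR interactions as the assisted-curation run resolved them."""
    if lexicon is None:
        lexicon = load_builtin_lexicon()
    records: list[InteractionRecord] = []
    with open(data_path("oxyr_extracted.tsv"), encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            gcs = [
                (normalize(t.strip(), lexicon, lenient=True), 1)
                for t in row["gcs"].split(",")
                if t.strip()
            ]
            records.append(
                InteractionRecord(
                    tf=row["tf"],
                    target=row["target"],
                    support_positive=int(row["support_pos"]),
                    support_negative=int(row["support_neg"]),
                    support_nondirectional=int(row["support_nondir"]),
                    support_no_effect=int(row["support_noeffect"]),
                    resolved_effect=row["resolved_effect"],
                    status=row["status"],
                    gcs=gcs,
                )
            )
    return records


def load_tf_gc_interactions() -> list[dict[str, str]]:
    """29 interactions of further TFs (AraC, ArcA, Fur, ...) with conditions.

    Rows are verbatim; a combined regulator such as "IHF + SigmaS" stays one
    row here and can be split into per-TF records downstream.
    """
    with open(data_path("tf_gc_interactions.tsv"), encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def split_combined_tfs(rows: list[dict[str, str]]) -> list[dict[str, str]]:
    """Expand "TF1 + TF2" rows into one row per regulator."""
    out: list[dict[str, str]] = []
    for row in rows:
        for tf in [t.strip() for t in row["tf"].split("+")]:
            out.append({**row, "tf": tf})
    return out


def load_condition_gene_associations() -> list[GcAssociation]:
    """67 condition-effect-gene associations whose regulator is unknown."""
    out: list[GcAssociation] = []
    with open(data_path("condition_gene_associations.tsv"), encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                GcAssociation(
                    gc=row["gc"], effect=row["effect"].lower(), target=row["target"]
                )
            )
    return out


def load_novel_oxyr_targets() -> list[str]:
    """OxyR targets found in the corpus but absent from the reference database."""
    text = data_path("novel_oxyr_targets.txt").read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_example_corpus() -> list[Document]:
    from .corpus import load_corpus

    return load_corpus(data_path("example_corpus.jsonl"), format="jsonl")


# -- attribution benchmark -------------------------------------------------

_EFFECT_SYMBOL = {"+": "positive", "-": "negative", "−": "negative", "?": "nondirectional"}


@dataclass(frozen=True)
class AssertionRow:
    sentence_id: str
    structure: str
    info: str
    pmid: str


def load_katg_assertions() -> list[AssertionRow]:
    """The printed OxyR-katG assertion rows (one per sentence occurrence)."""
    out: list[AssertionRow] = []
    with open(data_path("katg_attribution.tsv"), encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(AssertionRow(**row))
    return out


def _info_to_tag(info: str) -> str:
    low = info.lower()
    if "figure" in low or "table" in low:
        return "figure_table"
    if "evidence" in low:
        return "evidence"
    if "reference linked" in low:
        return "reference_linked"
    if "reference" in low:
        return "reference"
    return "none"


def _parse_structure(
    structure: str, lexicon: Lexicon
) -> SemanticStructure:
    subject, symbol, target = structure.split()
    effect = _EFFECT_SYMBOL[symbol.strip("[]")]
    tf_names = lexicon.canonicals_of("tf")
    if subject in tf_names:
        return SemanticStructure(effect=effect, target=target, tf=subject)
    # subject is a condition term: a TF-less partial structure
    gc = normalize(subject, lexicon, lenient=True)
    return SemanticStructure(effect=effect, target=target, gc=gc)


def build_attribution_corpus(
    lexicon: Lexicon | None = None,
) -> tuple[list[Document], list[SemanticStructure]]:
    """Reconstruct the attribution benchmark as a corpus plus structures.

    One document per paper (doc_id = PMID); sentence texts are synthetic
    placeholders, but sentence IDs, evidence tags, citation links and the
    normalized structures are the benchmark's own.  A sentence printed twice
    with two structures becomes one sentence contributing two structures.
    """
    if lexicon is None:
        lexicon = load_builtin_lexicon()
    rows = load_katg_assertions()
    per_paper: dict[str, list[AssertionRow]] = {}
    for row in rows:
        per_paper.setdefault(row.pmid, []).append(row)
    documents: list[Document] = []
    structures: list[SemanticStructure] = []
    import re

    for pmid, paper_rows in per_paper.items():
        sentences: list[Sentence] = []
        seen: dict[str, Sentence] = {}
        for row in paper_rows:
            if row.sentence_id not in seen:
                cited = re.findall(r"PMID:?\s*(\d+)", row.info)
                sent = Sentence(
                    sentence_id=row.sentence_id,
                    ordinal=len(sentences) + 1,
                    text=f"[synthetic placeholder for {row.sentence_id}] "
                    f"{row.structure}.",
                    cited_pmids=cited,
                    evidence_tag=_info_to_tag(row.info),
                )
                seen[row.sentence_id] = sent
                sentences.append(sent)
            s = _parse_structure(row.structure, lexicon)
            s.doc_id = pmid
            s.sentence_id = row.sentence_id
            structures.append(s)
        documents.append(Document(doc_id=pmid, sentences=sentences))
    return documents, structures


@dataclass(frozen=True)
class AttributionStats:
    n_assertions: int
    n_sentences: int          # distinct printed assertion rows
    n_distinct_sentence_ids: int
    n_papers: int
    per_paper_sentences: dict[str, int]

    @property
    def max_per_paper(self) -> int:
        return max(self.per_paper_sentences.values())


def attribution_stats() -> AttributionStats:
    """Bookkeeping over the assertion table.

    The headline sentence count is the number of printed assertion rows (each
    row is one sentence occurrence); per-paper counts — the input to the
    mentioned-three-times heuristic — deduplicate by sentence ID, so a
    sentence printed with two structures counts once for its paper.
    """
    rows = load_katg_assertions()
    per_paper = Counter()
    seen: set[tuple[str, str]] = set()
    for row in rows:
        key = (row.pmid, row.sentence_id)
        if key not in seen:
            seen.add(key)
            per_paper[row.pmid] += 1
    return AttributionStats(
        n_assertions=len(rows),
        n_sentences=len(rows),
        n_distinct_sentence_ids=len(seen),
        n_papers=len(per_paper),
        per_paper_sentences=dict(per_paper),
    )


def write_bundle(out_dir: str | Path) -> list[Path]:
    """Copy every shipped dataset into ``out_dir`` (the fixture bundle)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in DATA_FILES:
        target = out_dir / name
        target.write_bytes(data_path(name).read_bytes())
        written.append(target)
    return written
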