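"""Mapping annotated sentences into normalized semantic structures.

Every informative sentence (one that passed the gene-AND-effect filter) is
mapped to zero or more normalized tuples in one of three forms:

* ``TF [effect] gene [GC]``  — the most complete form,
* ``TF [effect] gene``       — no growth condition stated,
* ``[effect] gene [GC]``     — the regulator is not named.

A sentence can instantiate several structures: coordinated gene lists
("activating katG, ahpCF, dps, gorA and oxyS") distribute the governing
effect over every listed target, and contrastive clauses ("... while ...")
scope effects and conditions separately.  Exclusion rules then remove or
demote structures that curators would not encode: targets absent from the
organism's gene dictionary, uninformative or underspecified conditions,
non-directional effect words (kept only for validation), explicit
negative results, and negative sigma-factor effects (necessarily indirect).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .corpus import Sentence, TermAnnotation
from .terminology import Lexicon, normalize

FORMS = ("TF_EFFECT_GENE_GC", "TF_EFFECT_GENE", "EFFECT_GENE_GC")

# exclusion reason codes
TARGET_NOT_IN_DICTIONARY = "TARGET_NOT_IN_DICTIONARY"
GC_UNINFORMATIVE = "GC_UNINFORMATIVE"
GC_UNDERSPECIFIED = "GC_UNDERSPECIFIED"
EFFECT_NONDIRECTIONAL = "EFFECT_NONDIRECTIONAL"
NO_EFFECT = "NO_EFFECT"
SIGMA_NEGATIVE = "SIGMA_NEGATIVE"
AMBIGUOUS_OPERON = "AMBIGUOUS_OPERON"


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable lists for scoping and exclusion rules, shipped with defaults.

    ``uninformative_gcs`` are dropped (the structure is demoted to the no-GC
    form); ``underspecified_gcs`` (bare terms like "pH") exclude the structure
    outright; ``sigma_factors`` are regulators whose negative effects are
    treated as indirect and excluded.
    """

    contrast_markers: tuple[str, ...] = ("while", "whereas")
    uninformative_gcs: frozenset[str] = frozenset({"normal growth", "during growth"})
    underspecified_gcs: frozenset[str] = frozenset({"pH"})
    sigma_factors: frozenset[str] = frozenset(
        {"SigmaS", "Sigma70", "Sigma32", "SigmaE", "Sigma54"}
    )
    ambiguous_operon_forms: frozenset[str] = frozenset()
    # words that may follow a gene in a coordination without being genes
    coordination_stopwords: frozenset[str] = frozenset(
        {
            "and", "or", "the", "other", "genes", "gene", "promoters",
            "promoter", "operons", "operon", "expression", "transcription",
            "levels", "both", "all", "respectively", "only",
        }
    )


DEFAULT_CONFIG = ExtractionConfig()


@dataclass
class SemanticStructure:
    """One normalized (TF, effect, target, GC) tuple with provenance."""

    effect: str
    target: str
    tf: str | None = None
    gc: str | None = None
    doc_id: str | None = None
    sentence_id: str | None = None
    validation_only: bool = False
    mutant_flag: bool = False
    target_in_lexicon: bool = True
    exclusion_reason: str | None = None
    gc_dropped: str | None = None

    @property
    def form(self) -> str | None:
        if self.tf is not None and self.gc is not None:
            return "TF_EFFECT_GENE_GC"
        if self.tf is not None:
            return "TF_EFFECT_GENE"
        if self.gc is not None:
            return "EFFECT_GENE_GC"
        return None

    @property
    def provenance(self) -> tuple[str | None, str | None]:
        return (self.doc_id, self.sentence_id)

    def key(self) -> tuple:
        return (self.tf, self.effect, self.target, self.gc)


# -- clause segmentation ---------------------------------------------------


def _clause_spans(text: str, config: ExtractionConfig) -> list[tuple[int, int]]:
    """Character spans of clauses split at contrast markers and semicolons."""
    marker = "|".join(
        [rf"\b{re.escape(m)}\b" for m in config.contrast_markers] + [";"]
    )
    spans: list[tuple[int, int]] = []
    start = 0
    for m in re.finditer(marker, text):
        spans.append((start, m.start()))
        start = m.end()
    spans.append((start, len(text)))
    return spans


# -- coordination expansion ------------------------------------------------

_CONJ_RIGHT = re.compile(r"(?:\s*,\s*(?:and\s+|or\s+)?|\s+(?:and|or)\s+)(\w[\w-]*)")
_GENE_LIKE = re.compile(r"^[a-z][A-Za-z0-9-]{2,9}$")


def _coordination_candidates(
    text: str,
    clause: tuple[int, int],
    annotations: Sequence[TermAnnotation],
    config: ExtractionConfig,
) -> list[tuple[int, str]]:
    """Unannotated gene-like tokens coordinated with annotated genes.

    Curators encounter these when a coordinated list names a gene absent from
    the dictionary (e.g. a gene from another organism); the token is carried
    forward as a candidate target so the exclusion step can record it as
    TARGET_NOT_IN_DICTIONARY rather than silently losing it.
    """
    ann_spans = {(a.start, a.end) for a in annotations}
    ann_starts = {a.start: a for a in annotations}
    candidates: list[tuple[int, str]] = []
    for ann in annotations:
        if ann.entity_class not in ("gene", "operon"):
            continue
        pos = ann.end
        while True:
            m = _CONJ_RIGHT.match(text, pos, clause[1])
            if not m:
                break
            token = m.group(1)
            tok_start = m.start(1)
            if tok_start in ann_starts:  # another dictionary hit; skip past it
                pos = ann_starts[tok_start].end
                continue
            if any(s <= tok_start < e for s, e in ann_spans):
                break
            if _GENE_LIKE.match(token) and token not in config.coordination_stopwords:
                candidates.append((tok_start, token))
                pos = m.end(1)
                continue
            break
    # dedupe by position
    seen: set[int] = set()
    out: list[tuple[int, str]] = []
    for pos, token in sorted(candidates):
        if pos not in seen:
            seen.add(pos)
            out.append((pos, token))
    return out


def distribute_conjunctions(
    effect: str, targets: Sequence[str]
) -> list[tuple[str, str]]:
    """Distribute one governing effect over a coordinated target list."""
    return [(effect, target) for target in targets]


# -- mutant cue flagging ---------------------------------------------------

_MUTANT_CUES = re.compile(r"Δ\w+|\bmutants?\b|\bdeletion of\b", re.UNICODE)


def flag_mutant_context(sentence: Sentence) -> bool:
    """True when a deletion/mutant cue co-occurs with a gene or TF mention.

    The flag travels with provenance only; mutant semantics (an effect seen in
    a deletion strain is inverted relative to the wild type) are not modeled.
    """
    if not _MUTANT_CUES.search(sentence.text):
        return False
    return bool(sentence.annotations_of("gene", "tf", "operon"))


# -- structure extraction --------------------------------------------------


def extract_structures(
    sentence: Sentence,
    lexicon: Lexicon,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> list[SemanticStructure]:
    """Map one annotated sentence to its raw semantic structures.

    Scoping: the sentence is split into clauses at contrast markers; each
    target takes the nearest effect annotation within its clause, growth
    conditions attach to all structures of their own clause, and the TF is
    the tf annotation of the clause, falling back to the sentence-level TF
    set when the clause names none (coordinated contrast clauses routinely
    elide the regulator).  Structures with neither TF nor GC match none of
    the normalized forms and are not emitted.  Exclusion rules are applied
    separately by :func:`apply_exclusions`.
    """
    text = sentence.text
    mutant = flag_mutant_context(sentence)
    sentence_tfs = _unique([a.canonical for a in sentence.annotations_of("tf")])
    structures: list[SemanticStructure] = []
    for clause in _clause_spans(text, config):
        anns = [a for a in sentence.annotations if clause[0] <= a.start < clause[1]]
        effects = [a for a in anns if a.entity_class == "effect"]
        if not effects:
            continue
        genes = [a for a in anns if a.entity_class in ("gene", "operon")]
        clause_tfs = _unique([a.canonical for a in anns if a.entity_class == "tf"])
        tfs = clause_tfs or sentence_tfs
        gcs = _unique(
            [
                normalize(a.canonical, lexicon, lenient=True)
                for a in anns
                if a.entity_class == "growth_condition"
            ]
        )
        targets: list[tuple[int, str, bool]] = [
            (a.start, a.canonical, True) for a in genes
        ]
        targets += [
            (pos, token, False)
            for pos, token in _coordination_candidates(text, clause, anns, config)
        ]
        for pos, target, in_lexicon in targets:
            effect_ann = _nearest_effect(pos, effects)
            for tf in tfs or [None]:
                for gc in gcs or [None]:
                    structures.append(
                        SemanticStructure(
                            effect=effect_ann.polarity,
                            target=target,
                            tf=tf,
                            gc=gc,
                            doc_id=sentence.doc_id,
                            sentence_id=sentence.sentence_id,
                            mutant_flag=mutant,
                            target_in_lexicon=in_lexicon,
                        )
                    )
    # a sentence asserts each distinct tuple once
    deduped: dict[tuple, SemanticStructure] = {}
    for s in structures:
        if s.form is None:
            continue
        deduped.setdefault(s.key(), s)
    return list(deduped.values())


def _nearest_effect(
    pos: int, effects: Sequence[TermAnnotation]
) -> TermAnnotation:
    def distance(eff: TermAnnotation) -> int:
        if eff.end <= pos:
            return pos - eff.end
        return eff.start - pos

    return min(effects, key=lambda e: (distance(e), e.start))


def _unique(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


# -- exclusion rules -------------------------------------------------------


def apply_exclusions(
    structures: Sequence[SemanticStructure],
    lexicon: Lexicon,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> tuple[list[SemanticStructure], list[SemanticStructure]]:
    """Partition raw structures into (kept, excluded) with reason codes.

    Rules, each applied independently:

    * TARGET_NOT_IN_DICTIONARY — the candidate target is not a known gene or
      operon of the organism; excluded.
    * AMBIGUOUS_OPERON — an unresolvable shortened operon form; excluded.
    * SIGMA_NEGATIVE — negative effect attributed to a sigma factor is
      necessarily indirect; excluded.
    * GC_UNDERSPECIFIED — the condition term is too vague to curate; excluded.
    * GC_UNINFORMATIVE — the condition is dropped and the structure demoted to
      the no-GC form; kept.
    * EFFECT_NONDIRECTIONAL — "regulated"-type effects carry no direction; the
      structure is kept but only for validating directional assertions.
    * NO_EFFECT — explicit negative results are kept as such.
    """
    valid_targets = lexicon.canonicals_of("gene", "operon")
    kept: list[SemanticStructure] = []
    excluded: list[SemanticStructure] = []
    for s in structures:
        if not s.target_in_lexicon or s.target not in valid_targets:
            excluded.append(replace(s, exclusion_reason=TARGET_NOT_IN_DICTIONARY))
            continue
        if s.target in config.ambiguous_operon_forms:
            excluded.append(replace(s, exclusion_reason=AMBIGUOUS_OPERON))
            continue
        if s.tf in config.sigma_factors and s.effect == "negative":
            excluded.append(replace(s, exclusion_reason=SIGMA_NEGATIVE))
            continue
        if s.gc is not None and s.gc in config.underspecified_gcs:
            excluded.append(replace(s, exclusion_reason=GC_UNDERSPECIFIED))
            continue
        if s.gc is not None and s.gc in config.uninformative_gcs:
            s = replace(s, gc=None, gc_dropped=s.gc)
            if s.form is None:  # GC was the only qualifier; nothing left to keep
                excluded.append(replace(s, exclusion_reason=GC_UNINFORMATIVE))
                continue
        if s.effect == "nondirectional":
            s = replace(s, validation_only=True)
        kept.append(s)
    # demotion can create duplicates of an already-kept tuple
    deduped: dict[tuple, SemanticStructure] = {}
    for s in kept:
        key = (s.doc_id, s.sentence_id) + s.key()
        deduped.setdefault(key, s)
    return list(deduped.values()), excluded


def write_structures_tsv(
    structures: Sequence[SemanticStructure], path
) -> None:
    from pathlib import Path

    header = (
        "doc_id\tsentence_id\ttf\teffect\ttarget\tgc\tform\t"
        "validation_only\tmutant_flag\texclusion_reason"
    )
    lines = [header]
    for s in structures:
        lines.append(
            "\t".join(
                [
                    s.doc_id or "",
                    s.sentence_id or "",
                    s.tf or "",
                    s.effect,
                    s.target,
                    s.gc or "",
                    s.form or "",
                    str(s.validation_only).lower(),
                    str(s.mutant_flag).lower(),
                    s.exclusion_reason or "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
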