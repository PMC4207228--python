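"""Seeded synthetic corpora with planted ground truth.

The generator emulates the shape of a curation corpus: a set of papers whose
sentences occasionally assert a planted (TF, effect, target, GC) tuple using
templates mirroring the phrasings found in the regulatory literature —
passive single-target statements, coordinated gene lists sharing one
governing effect, and contrastive clauses that elide the regulator.  The
remaining sentences are distractors carrying no extractable tuple.

Noise dials: planted terms can be rendered as non-reference synonyms
(``synonym_noise_rate``; extraction should normalize these away), as surfaces
absent from the lexicon (``unknown_synonym_rate``; these are unrecoverable by
dictionary lookup, so recall must degrade), and planted tuples can be
re-emitted with flipped polarity (``conflict_rate``; aggregation must
out-vote them).  Every stochastic decision draws from one seeded generator,
and rate decisions consume a draw whether or not they fire, so runs at
different rates with the same seed are aligned event-for-event.

The defaults emulate the scale of a single-TF curation corpus: 48 papers of
250 sentences with roughly one sentence in nine carrying a tuple.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

from .corpus import Document, Sentence
from .extraction import SemanticStructure
from .terminology import Lexicon


class SyntheticConfigError(ValueError):
    pass


DEFAULT_TUPLES: tuple[tuple[str, str, str, str], ...] = (
    ("MntR", "positive", "mntP", "manganese"),
    ("MntR", "negative", "mntS", "manganese"),
    ("OxyR", "positive", "katG", "hydrogen peroxide treatment"),
    ("OxyR", "positive", "oxyS", "oxidative stress"),
    ("OxyR", "negative", "oxyR", "oxidative stress"),
    ("FNR", "negative", "yfgF", "anaerobiosis"),
    ("Fur", "negative", "sufABCDSE", "iron treatment"),
    ("ArcA", "negative", "sodA", "anaerobiosis"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_documents: int = 48
    sentences_per_document: int = 250
    planted_tuples: tuple[tuple[str, str, str, str], ...] = DEFAULT_TUPLES
    synonym_noise_rate: float = 0.2
    unknown_synonym_rate: float = 0.0
    distractor_rate: float = 0.886
    conjunction_rate: float = 0.2
    conflict_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "synonym_noise_rate",
            "unknown_synonym_rate",
            "distractor_rate",
            "conjunction_rate",
            "conflict_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise SyntheticConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.n_documents < 0 or self.sentences_per_document < 0:
            raise SyntheticConfigError("counts must be non-negative")


@dataclass(frozen=True)
class TruthRow:
    """One planted structure, with its provenance and noise bookkeeping."""

    doc_id: str
    sentence_id: str
    tf: str
    effect: str
    target: str
    gc: str
    flipped: bool = False
    unknown_surface: bool = False


_POSITIVE_PASSIVE = ("upregulated", "induced", "activated")
_NEGATIVE_PASSIVE = ("repressed", "downregulated", "inhibited")
_POSITIVE_VERB = ("activates", "induces")
_NEGATIVE_VERB = ("represses", "inhibits")
_POSITIVE_ING = ("activating", "inducing")
_NEGATIVE_ING = ("repressing", "inhibiting")

_DISTRACTORS = (
    "The cells were grown overnight in LB medium at 37 degrees.",
    "Samples were collected at regular intervals for two hours.",
    "The culture was diluted and plated in triplicate.",
    "These observations are consistent with earlier reports.",
    "The binding site overlaps the -35 element of the promoter region.",
    "Total RNA was prepared from each culture.",
    "The strains used in this study are listed in the supplementary material.",
)


def _surface_for(
    canonical: str,
    entity_class: str,
    lexicon: Lexicon,
    rng: random.Random,
    synonym_rate: float,
    unknown_rate: float,
) -> tuple[str, bool]:
    """Render a canonical term as a surface form, possibly noisy.

    Returns (surface, unknown) where unknown marks a surface absent from the
    lexicon.  Rate draws are consumed unconditionally to keep runs at
    different rates aligned under one seed.
    """
    u_unknown = rng.random()
    u_syn = rng.random()
    if u_unknown < unknown_rate:
        return canonical + "qq", True  # guaranteed out-of-dictionary
    if u_syn < synonym_rate:
        synonyms = [
            e.surface
            for e in lexicon.entries_of(entity_class)
            if e.canonical == canonical and e.surface != canonical
        ]
        if synonyms:
            return rng.choice(synonyms), False
    return canonical, False


def generate_synthetic_corpus(
    config: SyntheticConfig, lexicon: Lexicon
) -> tuple[list[Document], list[TruthRow]]:
    """Build a corpus and the truth table of every planted structure.

    Deterministic: identical config (seed included) yields byte-identical
    output.  Raises :class:`SyntheticConfigError` when a planted tuple
    references a canonical the lexicon does not know.
    """
    tf_names = lexicon.canonicals_of("tf")
    target_names = lexicon.canonicals_of("gene", "operon")
    gc_names = lexicon.canonicals_of("growth_condition")
    for tf, effect, target, gc in config.planted_tuples:
        if tf not in tf_names:
            raise SyntheticConfigError(f"unknown TF canonical {tf!r}")
        if target not in target_names:
            raise SyntheticConfigError(f"unknown target canonical {target!r}")
        if gc not in gc_names:
            raise SyntheticConfigError(f"unknown GC canonical {gc!r}")
        if effect not in ("positive", "negative"):
            raise SyntheticConfigError(f"planted effect must be directional: {effect!r}")

    rng = random.Random(config.seed)
    documents: list[Document] = []
    truth: list[TruthRow] = []
    tuple_cycle = list(config.planted_tuples)
    for d in range(config.n_documents):
        doc_id = f"SYN{d + 1:04d}"
        sentences: list[Sentence] = []
        for i in range(config.sentences_per_document):
            sid = f"S{i + 1}"
            u_distract = rng.random()
            if u_distract < config.distractor_rate or not tuple_cycle:
                text = rng.choice(_DISTRACTORS)
                sentences.append(Sentence(sentence_id=sid, ordinal=i + 1, text=text))
                continue
            planted = rng.choice(tuple_cycle)
            text, rows = _planted_sentence(
                planted, doc_id, sid, config, lexicon, rng
            )
            truth.extend(rows)
            sentences.append(Sentence(sentence_id=sid, ordinal=i + 1, text=text))
        documents.append(Document(doc_id=doc_id, sentences=sentences))
    return documents, truth


def _planted_sentence(
    planted: tuple[str, str, str, str],
    doc_id: str,
    sid: str,
    config: SyntheticConfig,
    lexicon: Lexicon,
    rng: random.Random,
) -> tuple[str, list[TruthRow]]:
    tf, effect, target, gc = planted
    u_conflict = rng.random()
    flipped = u_conflict < config.conflict_rate
    if flipped:
        effect = "negative" if effect == "positive" else "positive"
    u_conj = rng.random()
    extra_targets: list[str] = []
    if u_conj < config.conjunction_rate:
        pool = sorted(
            t for _, _, t, _ in config.planted_tuples if t != target
        )
        if pool:
            extra_targets = rng.sample(pool, k=min(len(pool), rng.choice((1, 2))))
    targets = [target] + extra_targets

    surfaces: list[tuple[str, bool]] = [
        _surface_for(
            t, "gene", lexicon, rng, config.synonym_noise_rate,
            config.unknown_synonym_rate,
        )
        for t in targets
    ]
    gc_surface, gc_unknown = _surface_for(
        gc, "growth_condition", lexicon, rng, config.synonym_noise_rate,
        config.unknown_synonym_rate,
    )

    template = rng.randrange(3)
    target_list = _join([s for s, _ in surfaces])
    if template == 0 and len(targets) == 1:
        word = rng.choice(
            _POSITIVE_PASSIVE if effect == "positive" else _NEGATIVE_PASSIVE
        )
        text = (
            f"The {surfaces[0][0]} gene is {word} by {gc_surface} through {tf}."
        )
    elif template == 1:
        verb = rng.choice(_POSITIVE_VERB if effect == "positive" else _NEGATIVE_VERB)
        text = f"{tf} {verb} {target_list} during {gc_surface}."
    else:
        ing = rng.choice(_POSITIVE_ING if effect == "positive" else _NEGATIVE_ING)
        text = (
            f"The two binding modes allow {tf} to act at its sites, "
            f"while {ing} {target_list} only upon {gc_surface}."
        )
    rows = [
        TruthRow(
            doc_id=doc_id,
            sentence_id=sid,
            tf=tf,
            effect=effect,
            target=t,
            gc=gc,
            flipped=flipped,
            unknown_surface=unknown or gc_unknown,
        )
        for t, (_, unknown) in zip(targets, surfaces)
    ]
    return text, rows


def _join(items: Sequence[str]) -> str:
    if len(items) == 1:
        return items[0]
    return ", ".join(items[:-1]) + " and " + items[-1]


def score_against_truth(
    structures: Sequence[SemanticStructure], truth: Sequence[TruthRow]
) -> tuple[float, float]:
    """(precision, recall) of extracted tuples against the planted truth.

    Matching is at the level of (doc, sentence, TF, effect, target, GC); both
    sides are sets, so re-asserted duplicates do not inflate either score.
    An empty extraction scores precision 1.0 by convention.
    """
    extracted = {
        (s.doc_id, s.sentence_id, s.tf, s.effect, s.target, s.gc)
        for s in structures
    }
    expected = {
        (t.doc_id, t.sentence_id, t.tf, t.effect, t.target, t.gc) for t in truth
    }
    if not expected:
        raise ValueError("truth table is empty")
    tp = len(extracted & expected)
    precision = tp / len(extracted) if extracted else 1.0
    recall = tp / len(expected)
    return precision, recall


def write_truth_tsv(truth: Sequence[TruthRow], path) -> None:
    from pathlib import Path

    lines = ["doc_id\tsentence_id\ttf\teffect\ttarget\tgc\tflipped\tunknown_surface"]
    for t in truth:
        lines.append(
            "\t".join(
                [
                    t.doc_id,
                    t.sentence_id,
                    t.tf,
                    t.effect,
                    t.target,
                    t.gc,
                    str(t.flipped).lower(),
                    str(t.unknown_surface).lower(),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
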