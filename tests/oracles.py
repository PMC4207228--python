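"""Independent brute-force oracles used by property tests.

These deliberately avoid the library's matching/filtering code paths: the
gazetteer oracle scans every variant at every character position with its own
word-boundary and case logic, and the filter oracle evaluates the boolean
predicate per sentence by direct set operations.
"""

from __future__ import annotations

from regumine.corpus import Sentence
from regumine.filters import And, ClassAtom, FilterExpression, Not, Or, TermAtom
from regumine.terminology import Lexicon, LexiconEntry, generate_variants


def _is_word_char(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def brute_force_matches(
    text: str, lexicon: Lexicon
) -> list[tuple[int, int, str, str]]:
    """All dictionary hits as (start, end, canonical, entity_class), after
    longest-match-wins / leftmost-tie overlap resolution."""
    candidates: list[tuple[int, int, LexiconEntry]] = []
    for entry in lexicon.entries:
        variants = generate_variants(entry)
        for variant in variants:
            n = len(variant)
            for start in range(0, len(text) - n + 1):
                chunk = text[start : start + n]
                if entry.case_sensitive:
                    if chunk != variant:
                        continue
                elif chunk.lower() != variant.lower():
                    continue
                if start > 0 and _is_word_char(text[start - 1]):
                    continue
                end = start + n
                if end < len(text) and _is_word_char(text[end]):
                    continue
                candidates.append((start, end, entry))
    # dedupe identical spans per entry identity
    seen: set[tuple[int, int, str, str]] = set()
    unique: list[tuple[int, int, LexiconEntry]] = []
    for start, end, entry in candidates:
        key = (start, end, entry.canonical, entry.entity_class)
        if key not in seen:
            seen.add(key)
            unique.append((start, end, entry))
    unique.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    kept: list[tuple[int, int, LexiconEntry]] = []
    for start, end, entry in unique:
        if all(end <= s or e <= start for s, e, _ in kept):
            kept.append((start, end, entry))
    kept.sort(key=lambda c: c[0])
    return [(s, e, entry.canonical, entry.entity_class) for s, e, entry in kept]


def filter_predicate(expr: FilterExpression, sentence: Sentence) -> bool:
    """Direct recursive evaluation of a filter over one sentence."""
    classes = {a.entity_class for a in sentence.annotations}
    if "operon" in classes:
        classes.add("gene")
    canonicals = {a.canonical for a in sentence.annotations}
    if isinstance(expr, ClassAtom):
        return expr.entity_class in classes
    if isinstance(expr, TermAtom):
        return expr.canonical in canonicals
    if isinstance(expr, Not):
        return not filter_predicate(expr.operand, sentence)
    if isinstance(expr, And):
        return filter_predicate(expr.left, sentence) and filter_predicate(
            expr.right, sentence
        )
    if isinstance(expr, Or):
        return filter_predicate(expr.left, sentence) or filter_predicate(
            expr.right, sentence
        )
    raise TypeError(type(expr))
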