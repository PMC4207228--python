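"""Sentence filters: a small boolean condition language over annotations.

A filter selects informative sentences for curation.  The canonical filter in
regulatory-interaction curation is ``class:gene AND class:effect`` — keep the
sentences mentioning a target gene together with an effect word; in a corpus
of full papers this typically discards around nine in ten sentences.

Grammar::

    atom := class:NAME | term:CANONICAL
    expr := atom | expr AND expr | expr OR expr | NOT expr | ( expr )

with conventional precedence NOT > AND > OR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import Document, Sentence


class FilterSyntaxError(ValueError):
    def __init__(self, message: str, column: int):
        super().__init__(f"column {column}: {message}")
        self.column = column


@dataclass(frozen=True)
class FilterConfig:
    """Evaluation switches for filter atoms.

    ``genes_include_operons``: a ``class:gene`` atom is satisfied by operon
    annotations as well (targets may be transcription units).
    ``exclude_tf_genes``: surfaces whose canonical is also a TF do not satisfy
    ``class:gene`` — useful when curating only condition-bearing sentences,
    at the cost of losing autoregulation.
    """

    genes_include_operons: bool = True
    exclude_tf_genes: bool = False
    tf_canonicals: frozenset[str] = frozenset()


class FilterExpression:
    def evaluate(self, sentence: Sentence, config: FilterConfig) -> bool:
        raise NotImplementedError


@dataclass(frozen=True)
class ClassAtom(FilterExpression):
    entity_class: str

    def evaluate(self, sentence: Sentence, config: FilterConfig) -> bool:
        for ann in sentence.annotations:
            cls = ann.entity_class
            if cls == self.entity_class:
                if (
                    self.entity_class == "gene"
                    and config.exclude_tf_genes
                    and ann.canonical in config.tf_canonicals
                ):
                    continue
                return True
            if (
                self.entity_class == "gene"
                and cls == "operon"
                and config.genes_include_operons
            ):
                return True
        return False


@dataclass(frozen=True)
class TermAtom(FilterExpression):
    canonical: str

    def evaluate(self, sentence: Sentence, config: FilterConfig) -> bool:
        return any(a.canonical == self.canonical for a in sentence.annotations)


@dataclass(frozen=True)
class Not(FilterExpression):
    operand: FilterExpression

    def evaluate(self, sentence: Sentence, config: FilterConfig) -> bool:
        return not self.operand.evaluate(sentence, config)


@dataclass(frozen=True)
class And(FilterExpression):
    left: FilterExpression
    right: FilterExpression

    def evaluate(self, sentence: Sentence, config: FilterConfig) -> bool:
        return self.left.evaluate(sentence, config) and self.right.evaluate(
            sentence, config
        )


@dataclass(frozen=True)
class Or(FilterExpression):
    left: FilterExpression
    right: FilterExpression

    def evaluate(self, sentence: Sentence, config: FilterConfig) -> bool:
        return self.left.evaluate(sentence, config) or self.right.evaluate(
            sentence, config
        )


_TOKEN = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<op>AND\b|OR\b|NOT\b)"
    r"|(?P<atom>(?:class|term):[^\s()]+))"
)


@dataclass
class _Parser:
    text: str
    tokens: list[tuple[str, str, int]] = field(default_factory=list)
    pos: int = 0

    def __post_init__(self) -> None:
        i = 0
        while i < len(self.text):
            if self.text[i].isspace():
                i += 1
                continue
            m = _TOKEN.match(self.text, i)
            if not m:
                raise FilterSyntaxError(f"unexpected character {self.text[i]!r}", i + 1)
            for kind in ("lparen", "rparen", "op", "atom"):
                if m.group(kind):
                    self.tokens.append((kind, m.group(kind), m.start(kind) + 1))
                    break
            i = m.end()

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise FilterSyntaxError("unexpected end of expression", len(self.text) + 1)
        self.pos += 1
        return tok

    # precedence: OR < AND < NOT < atom/parens
    def parse(self) -> FilterExpression:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise FilterSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> FilterExpression:
        left = self.parse_and()
        while (tok := self.peek()) and tok[1] == "OR":
            self.next()
            left = Or(left, self.parse_and())
        return left

    def parse_and(self) -> FilterExpression:
        left = self.parse_not()
        while (tok := self.peek()) and tok[1] == "AND":
            self.next()
            left = And(left, self.parse_not())
        return left

    def parse_not(self) -> FilterExpression:
        tok = self.peek()
        if tok and tok[1] == "NOT":
            self.next()
            return Not(self.parse_not())
        return self.parse_primary()

    def parse_primary(self) -> FilterExpression:
        kind, value, column = self.next()
        if kind == "lparen":
            expr = self.parse_or()
            tok = self.next()
            if tok[0] != "rparen":
                raise FilterSyntaxError("expected ')'", tok[2])
            return expr
        if kind == "atom":
            prefix, _, name = value.partition(":")
            if prefix == "class":
                return ClassAtom(name)
            return TermAtom(name)
        raise FilterSyntaxError(f"unexpected token {value!r}", column)


def parse_filter(expr: str) -> FilterExpression:
    """Parse a filter expression string into an evaluable tree."""
    return _Parser(expr).parse()


def apply_filter(
    documents: Sequence[Document],
    expr: FilterExpression | str,
    config: FilterConfig | None = None,
) -> list[Sentence]:
    """Return, in corpus order, exactly the sentences satisfying ``expr``.

    Sentences must already be annotated.  The output is a subset of the
    input's sentences, so the operation is idempotent.
    """
    if isinstance(expr, str):
        expr = parse_filter(expr)
    config = config or FilterConfig()
    retained: list[Sentence] = []
    for doc in documents:
        for sentence in doc.sentences:
            if expr.evaluate(sentence, config):
                retained.append(sentence)
    return retained
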