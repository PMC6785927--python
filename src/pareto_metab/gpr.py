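"""Gene-protein-reaction (GPR) rules with quantitative semantics.

A GPR is a boolean expression over gene identifiers, e.g.
``(g1 and g2) or g3``: AND groups genes forming an enzyme complex, OR
groups isozymes.  For simulating partial knockdowns we evaluate rules on
fractional gene activities in [0, 1] with the standard quantitative
convention AND = min (a complex is limited by its scarcest subunit) and
OR = max (the best isozyme carries the reaction).  Both combinators are
overridable per call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import GprLookupError, ModelFormatError

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

# node: ("gene", id) | ("and", (nodes...)) | ("or", (nodes...))
Node = tuple


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class _Parser:
    """Recursive-descent parser: expr := term (OR term)*; term := factor (AND factor)*."""

    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ModelFormatError(f"unexpected end of GPR rule: {self.source!r}")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        if self.peek() is not None:
            raise ModelFormatError(
                f"trailing tokens in GPR rule {self.source!r}: {self.tokens[self.pos:]}"
            )
        return node

    def expr(self) -> Node:
        children = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.term())
        return children[0] if len(children) == 1 else ("or", tuple(children))

    def term(self) -> Node:
        children = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.factor())
        return children[0] if len(children) == 1 else ("and", tuple(children))

    def factor(self) -> Node:
        tok = self.next()
        if tok == "(":
            node = self.expr()
            if self.next() != ")":
                raise ModelFormatError(f"unbalanced parentheses in GPR rule {self.source!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelFormatError(f"misplaced token {tok!r} in GPR rule {self.source!r}")
        return ("gene", tok)


@dataclass(frozen=True)
class Gpr:
    """Parsed GPR rule; the empty rule evaluates to full activity (1.0)."""

    root: Node | None = None
    text: str = ""
    genes: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_string(cls, text: str | None) -> "Gpr":
        text = (text or "").strip()
        if not text:
            return cls()
        root = _Parser(_tokenize(text), text).parse()
        return cls(root=root, text=text, genes=frozenset(_collect_genes(root)))

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(
        self,
        gene_activity: Mapping[str, float],
        and_op: Callable = min,
        or_op: Callable = max,
    ) -> float:
        """Activity of the reaction given per-gene activities in [0, 1]."""
        if self.root is None:
            return 1.0
        return _eval(self.root, gene_activity, and_op, or_op)

    def __str__(self) -> str:  # round-trips through from_string
        return self.text


def _collect_genes(node: Node):
    kind = node[0]
    if kind == "gene":
        yield node[1]
    else:
        for child in node[1]:
            yield from _collect_genes(child)


def _eval(node: Node, activity: Mapping[str, float], and_op, or_op) -> float:
    kind = node[0]
    if kind == "gene":
        gene = node[1]
        if gene not in activity:
            raise GprLookupError(f"gene {gene!r} missing from activity map")
        return float(activity[gene])
    values = [_eval(child, activity, and_op, or_op) for child in node[1]]
    return and_op(values) if kind == "and" else or_op(values)
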