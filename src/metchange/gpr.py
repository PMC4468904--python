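"""Boolean gene-protein-reaction (GPR) rules.

A GPR rule ties a reaction's availability to genes: ``AND`` nodes model
enzyme complexes (every subunit required), ``OR`` nodes model isozymes
(any one gene suffices). Rules are parsed from the conventional string
form, e.g. ``"g1 and (g2 or g3)"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Union

__all__ = ["GprRule", "parse_gpr", "GprParseError"]


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


Node = Union["GprRule", str]


@dataclass(frozen=True)
class GprRule:
    """A node of a GPR expression tree.

    ``op`` is ``"and"`` or ``"or"``; children are gene ids (leaves) or
    nested rules. A bare single-gene rule is represented with op ``"or"``
    and one child.
    """

    op: str
    children: tuple[Node, ...]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            if isinstance(c, GprRule):
                out |= c.genes()
            else:
                out.add(c)
        return out

    def evaluate(self, leaf: Callable[[str], float]) -> float:
        """Fold the tree with OR -> min, AND -> max over ``leaf(gene)``.

        With detection p-values (evidence of *absence*), an isozyme set is
        as present as its most-present member (min), while a complex is as
        absent as its most-absent subunit (max).
        """
        vals = [
            c.evaluate(leaf) if isinstance(c, GprRule) else leaf(c)
            for c in self.children
        ]
        return max(vals) if self.op == "and" else min(vals)

    def evaluate_expression(self, leaf: Callable[[str], float]) -> float:
        """Fold for abundance-like values: AND -> min, OR -> sum.

        The convention used when mapping raw expression onto reactions
        (isozymes add capacity, a complex is limited by its scarcest
        subunit).
        """
        vals = [
            c.evaluate_expression(leaf) if isinstance(c, GprRule) else leaf(c)
            for c in self.children
        ]
        return min(vals) if self.op == "and" else sum(vals)

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            if isinstance(c, GprRule):
                parts.append(f"({c.to_string()})")
            else:
                parts.append(c)
        return f" {self.op} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


_KEYWORDS = {"and", "or"}


def _tokenize(text: str) -> Iterator[str]:
    token = ""
    for ch in text:
        if ch in "()" or ch.isspace():
            if token:
                yield token
                token = ""
            if ch in "()":
                yield ch
        elif ch in "&|":
            if token:
                yield token
                token = ""
            yield {"&": "and", "|": "or"}[ch]
        else:
            token += ch
    if token:
        yield token


def parse_gpr(text: str) -> GprRule | None:
    """Parse a GPR string; empty/blank input means "no gene association"."""
    tokens = list(_tokenize(text))
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def factor() -> Node:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR: {text!r}")
        if tok == "(":
            take()
            node = expr()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GprParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return take()

    def term() -> Node:
        node = factor()
        children = [node]
        while (tok := peek()) is not None and tok.lower() == "and":
            take()
            children.append(factor())
        if len(children) == 1:
            return node
        return GprRule("and", tuple(children))

    def expr() -> Node:
        node = term()
        children = [node]
        while (tok := peek()) is not None and tok.lower() == "or":
            take()
            children.append(term())
        if len(children) == 1:
            return node
        return GprRule("or", tuple(children))

    node = expr()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR: {text!r}")
    if not isinstance(node, GprRule):
        node = GprRule("or", (node,))
    return node
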