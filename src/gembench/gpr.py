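"""Gene-protein-reaction (GPR) rule parsing and evaluation.

A GPR rule is a boolean expression over gene identifiers using ``and``,
``or`` and parentheses (case-insensitive keywords, no negation).  A
reaction with rule ``(g1 and g2) or g3`` is catalysable when either the
g1/g2 complex or the g3 isozyme is available.  The empty rule is always
satisfied (no genetic requirement).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Union

__all__ = ["GprParseError", "GprNode", "parse_gpr", "evaluate_gpr", "gpr_genes"]


class GprParseError(ValueError):
    """Raised for a malformed GPR rule; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GprNode:
    """Node of a parsed GPR tree: op in {'gene','and','or'}."""

    op: str
    gene: str = ""
    children: tuple = ()

    def evaluate(self, present: Iterable[str]) -> bool:
        present = set(present)
        return _eval(self, present)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str):
    tokens = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule: str) -> Union[GprNode, None]:
    """Parse ``rule`` into a GprNode tree; ``None`` for the empty rule.

    Grammar (standard precedence, AND binds tighter than OR)::

        expr    := term ("or" term)*
        term    := factor ("and" factor)*
        factor  := gene | "(" expr ")"
    """
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def where():
        return tokens[pos][1] if pos < len(tokens) else len(rule)

    def expr():
        nonlocal pos
        node = term()
        parts = [node]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            parts.append(term())
        if len(parts) == 1:
            return parts[0]
        return GprNode("or", children=tuple(parts))

    def term():
        nonlocal pos
        node = factor()
        parts = [node]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            parts.append(factor())
        if len(parts) == 1:
            return parts[0]
        return GprNode("and", children=tuple(parts))

    def factor():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of rule", where())
        if tok == "(":
            pos += 1
            node = expr()
            if peek() != ")":
                raise GprParseError("expected ')'", where())
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r}", where())
        pos += 1
        return GprNode("gene", gene=tok)

    tree = expr()
    if pos != len(tokens):
        raise GprParseError(f"unexpected token {tokens[pos][0]!r}", where())
    return tree


def _eval(node: GprNode, present: set) -> bool:
    if node.op == "gene":
        return node.gene in present
    if node.op == "and":
        return all(_eval(c, present) for c in node.children)
    if node.op == "or":
        return any(_eval(c, present) for c in node.children)
    raise ValueError(f"unknown GPR node op {node.op!r}")


def evaluate_gpr(tree: Union[GprNode, None], present: Iterable[str]) -> bool:
    """True iff the rule is satisfiable with exactly ``present`` genes available.

    ``None`` (empty rule) is always True.
    """
    if tree is None:
        return True
    return tree.evaluate(present)


def gpr_genes(tree: Union[GprNode, None]) -> FrozenSet[str]:
    """Set of gene identifiers referenced by a parsed rule."""
    if tree is None:
        return frozenset()
    if tree.op == "gene":
        return frozenset([tree.gene])
    out = set()
    for c in tree.children:
        out |= gpr_genes(c)
    return frozenset(out)
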