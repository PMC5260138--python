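"""Gene-list bookkeeping: Venn-style membership decomposition and Boolean algebra.

Gene lists produced by the selection workflows can be decomposed into the
disjoint membership regions of up to four sets (the cells of a Venn
diagram) or combined with union / intersection / difference / symmetric
difference expressions to form new lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any, Iterable, Mapping, Sequence


@dataclass
class GeneSet:
    """A named collection of gene ids with a provenance note.

    ``table`` optionally carries per-gene values from the operation that
    produced the set (e.g. pool means and differences from a DMG
    selection).
    """

    name: str
    genes: frozenset[str]
    provenance: str = ""
    table: Any = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneSet":
        """Read a one-id-per-line gene list file (blank lines ignored)."""
        with open(path, encoding="utf-8") as fh:
            genes = frozenset(line.strip() for line in fh if line.strip())
        return cls(name=name or str(path), genes=genes, provenance=f"file:{path}")

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for g in sorted(self.genes):
                fh.write(g + "\n")


def venn_regions(sets: Sequence[GeneSet]) -> dict[str, frozenset[str]]:
    """Decompose 2–4 gene sets into their disjoint membership regions.

    Keys are bit-strings over the input order ('10' = in the first set
    only); all ``2**k - 1`` non-empty signatures are present, possibly
    mapping to empty sets.  The regions partition the union: every gene of
    the union appears in exactly one region.
    """
    k = len(sets)
    if not 2 <= k <= 4:
        raise ValueError(f"venn decomposition supports 2 to 4 sets, got {k}")
    regions: dict[str, set[str]] = {
        format(sig, f"0{k}b"): set() for sig in range(1, 2**k)
    }
    universe = set().union(*(s.genes for s in sets))
    for gene in universe:
        sig = "".join("1" if gene in s.genes else "0" for s in sets)
        regions[sig].add(gene)
    return {sig: frozenset(genes) for sig, genes in regions.items()}


class ExpressionError(ValueError):
    """A Boolean set expression could not be parsed."""


_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z_][\w.:-]*)|(?P<op>[|+&^()-]))")


def _tokenize(expression: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN.match(expression, pos)
        if m is None:
            rest = expression[pos:].lstrip()
            if not rest:
                break
            raise ExpressionError(
                f"unexpected character {rest[0]!r} at position {pos} in {expression!r}"
            )
        if m.group("name"):
            tokens.append(("name", m.group("name"), m.start("name")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for set expressions.

    Grammar (``&`` binds tighter than ``|``/``+``/``-``/``^``, which are
    left-associative at one level, so ``A | B - C`` is ``(A | B) - C``)::

        expr   := term (('|' | '+' | '-' | '^') term)*
        term   := factor ('&' factor)*
        factor := NAME | '(' expr ')'
    """

    def __init__(self, tokens, sets: Mapping[str, frozenset[str]], text: str):
        self.tokens = tokens
        self.sets = sets
        self.text = text
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expr(self) -> set[str]:
        value = self.term()
        while True:
            kind, sym, _ = self.peek()
            if kind == "op" and sym in "|+-^":
                self.next()
                rhs = self.term()
                if sym in "|+":
                    value = value | rhs
                elif sym == "-":
                    value = value - rhs
                else:
                    value = value ^ rhs
            else:
                return value

    def term(self) -> set[str]:
        value = self.factor()
        while True:
            kind, sym, _ = self.peek()
            if kind == "op" and sym == "&":
                self.next()
                value = value & self.factor()
            else:
                return value

    def factor(self) -> set[str]:
        kind, sym, pos = self.next()
        if kind == "name":
            if sym not in self.sets:
                raise ExpressionError(f"unknown set name {sym!r} at position {pos}")
            return set(self.sets[sym])
        if kind == "op" and sym == "(":
            value = self.expr()
            kind, sym, pos = self.next()
            if sym != ")":
                raise ExpressionError(f"expected ')' at position {pos}")
            return value
        raise ExpressionError(f"expected a set name or '(' at position {pos}")


def combine(sets: Iterable[GeneSet], expression: str) -> GeneSet:
    """Evaluate a Boolean expression over named gene sets.

    Supported operators: ``|`` (or ``+``) union, ``&`` intersection,
    ``-`` difference, ``^`` symmetric difference, with parentheses.  The
    result's provenance records the expression text.
    """
    by_name = {s.name: s.genes for s in sets}
    parser = _Parser(_tokenize(expression), by_name, expression)
    result = parser.expr()
    kind, sym, pos = parser.peek()
    if kind is not None:
        raise ExpressionError(f"unexpected token {sym!r} at position {pos}")
    return GeneSet(name=expression, genes=frozenset(result), provenance=expression)
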