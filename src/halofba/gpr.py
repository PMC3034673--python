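"""Gene-protein-reaction (GPR) boolean expressions.

A gene association is a boolean expression over gene locus tags, e.g.
``"Csal1876 and (Csal1877 or Csal2450)"``.  ``and`` joins subunits of a
complex, ``or`` joins isoenzymes.  A bare whitespace/comma-separated list of
tags is treated as an OR of isoenzymes.  Parsing is case-insensitive on the
operators and keeps operator precedence ``and`` > ``or``.
"""

from __future__ import annotations

import re

from halofba.errors import GPRParseError

_TOKEN = re.compile(r"\s*(\(|\)|,|[A-Za-z0-9_.\-]+)")

#: expression tree node: ("and", [children]) | ("or", [children]) | ("gene", tag)
GPRNode = tuple


def tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise GPRParseError(f"unexpected character at offset {pos}: {text[pos]!r}")
        tok = m.group(1)
        if tok != ",":
            tokens.append(tok)
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse_or(self) -> GPRNode:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_and())
        # a bare token list is an implicit OR of isoenzymes
        while self.peek() is not None and self.peek() not in (")",) and self.peek().lower() not in ("and", "or"):
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and(self) -> GPRNode:
        terms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            terms.append(self.parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom(self) -> GPRNode:
        tok = self.next()
        if tok is None:
            raise GPRParseError("unexpected end of expression")
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise GPRParseError("missing closing parenthesis")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r}")
        return ("gene", tok)


def parse_gpr(text: str) -> GPRNode | None:
    """Parse a gene-association string; ``None`` for an empty association."""
    if text is None or not text.strip():
        return None
    parser = _Parser(tokenize(text))
    node = parser.parse_or()
    if parser.peek() is not None:
        raise GPRParseError(f"trailing tokens starting at {parser.peek()!r}")
    return node


def gpr_genes(text: str) -> set[str]:
    """Every locus tag referenced by a gene-association string."""
    node = parse_gpr(text)
    out: set[str] = set()

    def walk(n):
        if n is None:
            return
        if n[0] == "gene":
            out.add(n[1])
        else:
            for child in n[1]:
                walk(child)

    walk(node)
    return out


def evaluate_gpr(text: str, present: set[str]) -> bool:
    """Evaluate a gene association against a set of present genes.

    Empty associations evaluate to True (the reaction is not gene-gated).
    """
    node = parse_gpr(text)

    def ev(n):
        if n[0] == "gene":
            return n[1] in present
        if n[0] == "and":
            return all(ev(c) for c in n[1])
        return any(ev(c) for c in n[1])

    return True if node is None else ev(node)
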