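"""Elemental formulas in Hill notation (no parentheses, integer counts)."""

from __future__ import annotations

import re
from collections import Counter

from halofba.errors import FormulaError

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse e.g. ``"C6H12O6"`` into ``{"C": 6, "H": 12, "O": 6}``.

    Raises :class:`FormulaError` on anything that is not a sequence of
    element symbols with optional integer counts.
    """
    if formula is None or not formula.strip():
        raise FormulaError("empty formula")
    text = formula.strip()
    pos = 0
    out: Counter = Counter()
    while pos < len(text):
        m = _ELEMENT.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"unparseable formula {formula!r} at offset {pos}")
        element, count = m.group(1), m.group(2)
        out[element] += int(count) if count else 1
        pos = m.end()
    return {el: n for el, n in out.items() if n != 0}


def format_formula(composition: dict[str, int]) -> str:
    """Render a composition in Hill order (C, H, then alphabetical)."""

    def key(el: str):
        return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

    parts = []
    for el in sorted(composition, key=key):
        n = composition[el]
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def formula_carbon_count(formula: str | None) -> int:
    """Number of carbon atoms, 0 when the formula is absent."""
    if formula is None or not formula.strip():
        return 0
    return parse_formula(formula).get("C", 0)
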