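"""Elemental formula parsing (enough for carbon accounting).

Formulas follow the flat Hill-style grammar used by genome-scale models:
a sequence of ``Element`` or ``Element<count>`` tokens, e.g. ``C6H12O6``
or ``C63H88CoN14O14P``.  Parenthesised groups and charges are not part
of the dialect and raise :class:`FormulaError`.
"""

from __future__ import annotations

import logging
import re
from collections import Counter

from .errors import FormulaError

_log = logging.getLogger(__name__)

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a formula into non-negative element counts."""
    formula = (formula or "").strip()
    counts: Counter[str] = Counter()
    pos = 0
    while pos < len(formula):
        match = _ELEMENT_RE.match(formula, pos)
        if match is None or match.start() != pos:
            raise FormulaError(f"malformed formula {formula!r} at position {pos}")
        element, digits = match.groups()
        counts[element] += int(digits) if digits else 1
        pos = match.end()
    return dict(counts)


def carbon_content(formula: str) -> int:
    """Carbon atoms per molecule; an empty formula counts 0 with a warning."""
    if not (formula or "").strip():
        _log.warning("empty formula treated as zero carbon atoms")
        return 0
    return parse_formula(formula).get("C", 0)
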