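"""Elemental formulas: parsing, molar mass, and balancing of lumped reactions.

Formulas are restricted to the CHONPS alphabet with nonnegative integer
counts.  Carrier metabolites (ferredoxin, heme) that contain atoms outside
this alphabet are represented by documented CHONPS pseudo-formulas; since
every carrier is strictly conserved by the reactions that use it, this has
no effect on the balance of any reaction.
"""

from __future__ import annotations

import re
from fractions import Fraction
from typing import Dict, Mapping

ELEMENTS = ("C", "H", "N", "O", "P", "S")

ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for formulas outside the CHONPS integer-count dialect."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse ``"C6H12O6"`` into ``{"C": 6, "H": 12, "O": 6}``.

    Raises :class:`FormulaError` on unknown elements, non-integer counts or
    trailing garbage.
    """
    if not isinstance(formula, str) or not formula:
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: Dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r} at {pos}")
        if not m.group(0):
            break
        elem, digits = m.group(1), m.group(2)
        if elem not in ELEMENTS:
            raise FormulaError(f"element {elem!r} outside CHONPS in {formula!r}")
        n = int(digits) if digits else 1
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at {pos}")
    return counts


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of a CHONPS formula."""
    return sum(ATOMIC_MASS[e] * n for e, n in parse_formula(formula).items())


def elemental_total(
    stoichiometry: Mapping[str, Fraction], formulas: Mapping[str, str]
) -> Dict[str, Fraction]:
    """Signed per-element sum of a reaction (products minus substrates)."""
    total: Dict[str, Fraction] = {e: Fraction(0) for e in ELEMENTS}
    for met, coeff in stoichiometry.items():
        for elem, n in parse_formula(formulas[met]).items():
            total[elem] += Fraction(coeff) * n
    return {e: v for e, v in total.items() if v != 0}


def close_reaction(
    stoichiometry: Dict[str, Fraction],
    formulas: Mapping[str, str],
    closers: Mapping[str, str],
) -> Dict[str, Fraction]:
    """Balance a partially specified lumped reaction.

    ``closers`` maps metabolite ids to the single element each one is allowed
    to close, applied in order (e.g. ``{"nh3_c": "N", "co2_c": "C",
    "h2o_c": "O", "h_c": "H"}``).  The closer's own formula may contain other
    elements, which are accounted for as its coefficient is fixed, so order
    matters: close N before C before O before H.

    Returns a new stoichiometry dict; raises :class:`FormulaError` if a
    residual remains after all closers are applied.
    """
    stoich = dict(stoichiometry)
    for met, elem in closers.items():
        residual = elemental_total(stoich, formulas)
        if residual.get(elem):
            per_unit = parse_formula(formulas[met]).get(elem, 0)
            if per_unit == 0:
                raise FormulaError(f"closer {met} carries no {elem}")
            coeff = -residual[elem] / per_unit
            stoich[met] = stoich.get(met, Fraction(0)) + coeff
            if stoich[met] == 0:
                del stoich[met]
    residual = elemental_total(stoich, formulas)
    if residual:
        raise FormulaError(f"unclosable residual {residual} in {stoichiometry}")
    return stoich
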