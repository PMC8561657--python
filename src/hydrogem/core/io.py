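"""Model serialization: a small JSON dialect with exact rational coefficients.

Layout::

    {
      "id": "...", "provenance": "...",
      "compartments": ["c", "e", "h"],
      "metabolites": [{"id", "name", "formula", "charge", "compartment"}...],
      "reactions":   [{"id", "name", "stoichiometry": {met: "num/den"},
                       "bounds": [lb, ub], "kind", "gene_association",
                       "confidence", "subsystem", "speculative"}...],
      "objective": "BIOMASS"
    }

Stoichiometric coefficients are serialized as rational strings ("-3/2") so
a write/read round trip is bit-exact.  Schema violations raise
:class:`ParseError` carrying a JSON-pointer-style location.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Union

from .model import MetabolicModel, Metabolite, Reaction

SCHEMA_VERSION = 1


class ParseError(ValueError):
    """A model file violates the schema; ``pointer`` locates the offence."""

    def __init__(self, message: str, pointer: str = "/") -> None:
        super().__init__(f"{message} (at {pointer})")
        self.pointer = pointer


def _require(obj: dict, key: str, pointer: str):
    if key not in obj:
        raise ParseError(f"missing required key {key!r}", pointer)
    return obj[key]


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "id": model.id,
        "provenance": model.provenance,
        "compartments": list(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {
                    met: str(coeff) for met, coeff in sorted(r.stoichiometry.items())
                },
                "bounds": [r.lower_bound, r.upper_bound],
                "kind": r.kind,
                "gene_association": r.gene_association,
                "confidence": r.confidence,
                "subsystem": r.subsystem,
                "speculative": r.speculative,
            }
            for r in model.reactions.values()
        ],
        "objective": model.objective_id,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    if not isinstance(data, dict):
        raise ParseError("model document must be an object", "/")
    model = MetabolicModel(
        model_id=_require(data, "id", "/"),
        provenance=data.get("provenance", ""),
    )
    mets = _require(data, "metabolites", "/")
    if not isinstance(mets, list):
        raise ParseError("'metabolites' must be a list", "/metabolites")
    for i, m in enumerate(mets):
        ptr = f"/metabolites/{i}"
        try:
            model.add_metabolite(
                Metabolite(
                    id=_require(m, "id", ptr),
                    name=m.get("name", ""),
                    formula=m.get("formula", ""),
                    charge=int(m.get("charge", 0)),
                    compartment=_require(m, "compartment", ptr),
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), ptr) from exc
    rxns = _require(data, "reactions", "/")
    if not isinstance(rxns, list):
        raise ParseError("'reactions' must be a list", "/reactions")
    for i, r in enumerate(rxns):
        ptr = f"/reactions/{i}"
        stoich_raw = _require(r, "stoichiometry", ptr)
        try:
            stoich = {met: Fraction(s) for met, s in stoich_raw.items()}
        except (ValueError, ZeroDivisionError) as exc:
            raise ParseError(f"bad coefficient: {exc}", f"{ptr}/stoichiometry")
        bounds = _require(r, "bounds", ptr)
        if (not isinstance(bounds, (list, tuple))) or len(bounds) != 2:
            raise ParseError("'bounds' must be [lb, ub]", f"{ptr}/bounds")
        try:
            model.add_reaction(
                Reaction(
                    id=_require(r, "id", ptr),
                    stoichiometry=stoich,
                    lower_bound=float(bounds[0]),
                    upper_bound=float(bounds[1]),
                    name=r.get("name", ""),
                    kind=r.get("kind", "internal"),
                    gene_association=r.get("gene_association"),
                    confidence=int(r.get("confidence", 0)),
                    subsystem=r.get("subsystem", ""),
                    speculative=bool(r.get("speculative", False)),
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), ptr) from exc
    model.objective_id = data.get("objective")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n"
    )


def read_model(path: Union[str, Path]) -> MetabolicModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", "/") from exc
    return model_from_dict(data)


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Equality under canonical ordering of metabolites and reactions."""
    if a.id != b.id or a.objective_id != b.objective_id:
        return False
    if sorted(a.metabolites) != sorted(b.metabolites):
        return False
    for mid in a.metabolites:
        if a.metabolites[mid] != b.metabolites[mid]:
            return False
    if sorted(a.reactions) != sorted(b.reactions):
        return False
    for rid in a.reactions:
        ra, rb = a.reactions[rid], b.reactions[rid]
        if (ra.stoichiometry != rb.stoichiometry
                or (ra.lower_bound, ra.upper_bound)
                != (rb.lower_bound, rb.upper_bound)
                or (ra.kind, ra.gene_association, ra.confidence,
                    ra.subsystem, ra.speculative)
                != (rb.kind, rb.gene_association, rb.confidence,
                    rb.subsystem, rb.speculative)):
            return False
    return True
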