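"""Stoichiometric data model: metabolites, reactions, and the network container.

Conventions
-----------
* three compartments: ``c`` (cytosol), ``h`` (hydrogenosome), ``e``
  (extracellular);
* BiGG-style lowercase metabolite ids with a compartment suffix
  (``pyr_c``, ``ac_h``, ``glc__D_e``);
* fluxes in mmol/gDW/h, uptake negative and secretion positive on
  exchange reactions;
* stoichiometric coefficients stored as exact :class:`fractions.Fraction`
  and converted to float only when an LP is assembled;
* all species are written in their neutral (fully protonated) form, so
  formal charges are zero throughout and charge balance reduces to
  hydrogen balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction
from numbers import Rational
from typing import Dict, Iterable, List, Optional, Tuple

from .formula import ELEMENTS, FormulaError, elemental_total, parse_formula

logger = logging.getLogger("hydrogem")

COMPARTMENTS = ("c", "h", "e")

#: reaction kinds exempt from elemental balancing (boundary pseudo-reactions)
BALANCE_EXEMPT_KINDS = frozenset({"exchange", "biomass", "maintenance", "demand"})

REACTION_KINDS = ("internal", "exchange", "biomass", "maintenance", "demand")

#: default box bound used for "unbounded" fluxes; keeps the flux polytope
#: compact for variability analysis and sampling
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Structural error in a model definition."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelError(
                f"metabolite {self.id}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )
        if self.formula:
            parse_formula(self.formula)  # raises FormulaError if invalid

    @property
    def elements(self) -> Dict[str, int]:
        return parse_formula(self.formula) if self.formula else {}


def _as_fraction(x) -> Fraction:
    if isinstance(x, float):
        return Fraction(x).limit_denominator(10**9)
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(str(x))


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, Fraction]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    kind: str = "internal"
    gene_association: Optional[str] = None
    confidence: int = 0
    subsystem: str = ""
    speculative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ModelError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not 0 <= self.confidence <= 4:
            raise ModelError(f"reaction {self.id}: confidence outside 0-4")
        self.stoichiometry = {
            m: _as_fraction(c) for m, c in self.stoichiometry.items() if c != 0
        }

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass(frozen=True)
class BalanceViolation:
    reaction_id: str
    element: str  # element symbol, or "charge"
    imbalance: Fraction

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.reaction_id}: {self.element} off by {self.imbalance}"


class MetabolicModel:
    """A compartmentalized stoichiometric network with bounds and an objective.

    The single source of truth handed to every LP stage.
    """

    def __init__(
        self,
        model_id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: Optional[str] = None,
        provenance: str = "",
    ) -> None:
        self.id = model_id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.provenance = provenance
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)
        self.objective_id = objective_id

    # -- construction -------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelError(
                    f"reaction {rxn.id} references unknown metabolite {met_id}"
                )
        if rxn.kind == "exchange":
            mets = list(rxn.stoichiometry)
            if len(mets) != 1 or self.metabolites[mets[0]].compartment != "e":
                raise ModelError(
                    f"exchange reaction {rxn.id} must touch exactly one "
                    "extracellular metabolite"
                )
        self.reactions[rxn.id] = rxn

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    # -- access -------------------------------------------------------------

    @property
    def compartments(self) -> Tuple[str, ...]:
        return tuple(sorted({m.compartment for m in self.metabolites.values()}))

    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    def set_bounds(self, rxn_id: str, lb: float, ub: float) -> None:
        rxn = self.reactions[rxn_id]
        if lb > ub:
            raise ModelError(f"{rxn_id}: lb {lb} > ub {ub}")
        rxn.lower_bound = lb
        rxn.upper_bound = ub
        if rxn.speculative and (lb, ub) != (0.0, 0.0):
            logger.info("speculative reaction %s opened to (%s, %s)", rxn_id, lb, ub)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def exchange_for(self, met_id: str) -> Optional[Reaction]:
        for r in self.exchanges():
            if met_id in r.stoichiometry:
                return r
        return None

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(self.id, provenance=self.provenance)
        m.metabolites = dict(self.metabolites)
        m.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        m.objective_id = self.objective_id
        return m

    def validate(self) -> None:
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ModelError(f"objective {self.objective_id!r} not in model")

    # -- matrices -----------------------------------------------------------

    def stoichiometric_matrix(self):
        """Dense S (metabolites x reactions) as floats, with index lists."""
        import numpy as np

        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[met], j] = float(coeff)
        return S, met_ids, rxn_ids

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, objective={self.objective_id}>"
        )


def check_balance(model: MetabolicModel) -> List[BalanceViolation]:
    """Per-element and charge audit of every non-exempt reaction.

    Boundary pseudo-reactions (exchange, biomass, maintenance, demand) are
    skipped.  Returns an empty list iff every internal reaction is balanced.
    An unparseable or missing formula on a participating metabolite raises
    :class:`~hydrogem.core.formula.FormulaError` naming the metabolite.
    """
    formulas: Dict[str, str] = {}
    for rxn in model.reactions.values():
        if rxn.kind in BALANCE_EXEMPT_KINDS:
            continue
        for met_id in rxn.stoichiometry:
            met = model.metabolites[met_id]
            if not met.formula:
                raise FormulaError(
                    f"metabolite {met.id} lacks a formula (needed to balance "
                    f"{rxn.id})"
                )
            formulas[met_id] = met.formula

    violations: List[BalanceViolation] = []
    for rxn in model.reactions.values():
        if rxn.kind in BALANCE_EXEMPT_KINDS:
            continue
        residual = elemental_total(rxn.stoichiometry, formulas)
        for elem in ELEMENTS:
            if residual.get(elem):
                violations.append(BalanceViolation(rxn.id, elem, residual[elem]))
        charge = sum(
            Fraction(c) * model.metabolites[m].charge
            for m, c in rxn.stoichiometry.items()
        )
        if charge != 0:
            violations.append(BalanceViolation(rxn.id, "charge", charge))
    return violations
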