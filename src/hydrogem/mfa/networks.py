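"""Atom-mapped networks: small test fixtures and the reduced central-carbon
network used for the labeling study.

The reduced network mirrors the organism's mapped central metabolism:
glycolysis, the non-oxidative pentose phosphate pathway run in both
directions, pyruvate formate lyase vs pyruvate:ferredoxin oxidoreductase
partitioning, and the anaplerotic PEP-carboxykinase / malic-enzyme cycle
through the hydrogenosome (with its CO2 exchange).  The malate/fumarate
pool scrambles its backbone (fumarate is symmetric), which is what makes
CO2 fixation visible to the tracer; succinate leaves from that pool.  A
constrained configuration imports pyruvate only, which resolves the
malate/pyruvate import degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple


from .atommap import AtomMapNetwork, AtomMapReaction, tracer_mid, unlabeled_mid
from .emu import EMU

# --------------------------------------------------------------------------
# toy fixtures
# --------------------------------------------------------------------------


def toy_linear() -> AtomMapNetwork:
    """A(2C) -> B(2C) -> C(2C), identity maps; label is conserved."""
    rxns = [
        AtomMapReaction("v1", (("A", "ab"),), (("B", "ab"),)),
        AtomMapReaction("v2", (("B", "ab"),), (("C", "ab"),)),
    ]
    return AtomMapNetwork(
        rxns, {"A": tracer_mid([1])}, {"A": 2, "B": 2, "C": 2}
    )


def toy_cleavage() -> AtomMapNetwork:
    """A(4C) cleaved to B(2C) + C(2C), then condensed to D(4C) with a
    reversed fragment — exercises convolution and position tracking."""
    rxns = [
        AtomMapReaction("split", (("A", "abcd"),), (("B", "ab"), ("C", "cd"))),
        AtomMapReaction("join", (("B", "ab"), ("C", "cd")),
                        (("D", "cdab"),)),
        AtomMapReaction("b_in", (("A2", "ab"),), (("B", "ab"),)),
        AtomMapReaction("b_out", (("B", "ab"),), (("BSINK", "ab"),)),
    ]
    return AtomMapNetwork(
        rxns,
        {"A": tracer_mid([1, 2]), "A2": unlabeled_mid},
        {"A": 4, "B": 2, "C": 2, "D": 4, "A2": 2, "BSINK": 2},
    )


def toy_branch() -> AtomMapNetwork:
    """A 50/50-style branch point with distinct carbon fates."""
    rxns = [
        AtomMapReaction("u", (("S", "abc"),), (("P", "abc"),)),
        AtomMapReaction("d1", (("P", "abc"),), (("X", "abc"),)),
        AtomMapReaction("d2", (("P", "abc"),), (("Y", "bc"), ("Z", "a"))),
        AtomMapReaction("back", (("Y", "ab"), ("Z", "c")), (("P", "cab"),)),
    ]
    return AtomMapNetwork(
        rxns, {"S": tracer_mid([1, 2])},
        {"S": 3, "P": 3, "X": 3, "Y": 2, "Z": 1},
    )


# --------------------------------------------------------------------------
# reduced central-carbon network
# --------------------------------------------------------------------------

_CARBONS = {
    "GLC_ext": 6, "CO2_ext": 1,
    "F6P": 6, "GAP": 3, "X5P": 5, "E4P": 4, "S7P": 7, "R5P": 5,
    "PYR": 3, "OAA": 4, "MAL": 4, "ACE": 2, "FOR": 1, "CO2": 1,
    # efflux pools (unlabeled-sink semantics: never simulated backward)
    "RNA": 5, "LAC": 3, "SUCC": 4, "CO2SINK": 1,
}

#: fumarase-mediated symmetric scrambling exchange of the malate backbone,
#: in uptake units; near-equilibrium fumarase makes this fast
SCRAMBLE_EXCHANGE = 100.0


def central_carbon_network(purity: float = 0.99) -> AtomMapNetwork:
    """The reduced atom-mapped network under a [1,2-13C]glucose tracer."""
    r = [
        AtomMapReaction("v_upt", (("GLC_ext", "abcdef"),), (("F6P", "abcdef"),)),
        # PFK + aldolase + TPI: DHAP mirror gives the 'cba' triose
        AtomMapReaction("v_emp", (("F6P", "abcdef"),),
                        (("GAP", "cba"), ("GAP", "def"))),
        # non-oxidative PPP, pentose-forming direction
        AtomMapReaction("v_tkt2_r", (("F6P", "abcdef"), ("GAP", "ghi")),
                        (("X5P", "abghi"), ("E4P", "cdef"))),
        AtomMapReaction("v_tal_r", (("F6P", "abcdef"), ("E4P", "ghij")),
                        (("S7P", "abcghij"), ("GAP", "def"))),
        AtomMapReaction("v_tkt1_r", (("S7P", "abcdefg"), ("GAP", "hij")),
                        (("X5P", "abhij"), ("R5P", "cdefg"))),
        AtomMapReaction("v_xr", (("X5P", "abcde"),), (("R5P", "abcde"),)),
        # hexose-forming (forward) direction of the same steps
        AtomMapReaction("v_tkt1_f", (("X5P", "abcde"), ("R5P", "fghij")),
                        (("S7P", "abfghij"), ("GAP", "cde"))),
        AtomMapReaction("v_tal_f", (("S7P", "abcdefg"), ("GAP", "hij")),
                        (("E4P", "defg"), ("F6P", "abchij"))),
        AtomMapReaction("v_tkt2_f", (("X5P", "abcde"), ("E4P", "fghi")),
                        (("F6P", "abfghi"), ("GAP", "cde"))),
        AtomMapReaction("v_rx", (("R5P", "abcde"),), (("X5P", "abcde"),)),
        # lower glycolysis and fermentation branch points
        AtomMapReaction("v_pyk", (("GAP", "abc"),), (("PYR", "abc"),)),
        AtomMapReaction("v_pfl", (("PYR", "abc"),),
                        (("ACE", "bc"), ("FOR", "a"))),
        AtomMapReaction("v_pfo", (("PYR", "abc"),),
                        (("ACE", "bc"), ("CO2", "a"))),
        # anaplerosis and the hydrogenosomal malic-enzyme return; the
        # malate/fumarate pool scrambles its backbone (fumarate is
        # symmetric), which is what renders CO2 fixation visible to the
        # tracer
        AtomMapReaction("v_pepck", (("PYR", "abc"), ("CO2", "d")),
                        (("OAA", "abcd"),)),
        AtomMapReaction("v_oaamal", (("OAA", "abcd"),), (("MAL", "abcd"),)),
        AtomMapReaction("v_scr", (("MAL", "abcd"),), (("MAL", "dcba"),)),
        AtomMapReaction("v_me", (("MAL", "abcd"),),
                        (("PYR", "abc"), ("CO2", "d"))),
        AtomMapReaction("v_co2in", (("CO2_ext", "a"),), (("CO2", "a"),)),
        # efflux drains (biomass-bound pools and secreted products)
        AtomMapReaction("v_rna", (("R5P", "abcde"),), (("RNA", "abcde"),)),
        AtomMapReaction("v_lac", (("PYR", "abc"),), (("LAC", "abc"),)),
        AtomMapReaction("v_succ", (("MAL", "abcd"),), (("SUCC", "abcd"),)),
        AtomMapReaction("v_co2out", (("CO2", "a"),), (("CO2SINK", "a"),)),
    ]
    inputs = {
        "GLC_ext": tracer_mid([1, 2], purity=purity),
        "CO2_ext": unlabeled_mid,
    }
    return AtomMapNetwork(r, inputs, _CARBONS)


#: default measured-fragment panel (amino-acid, glycogen-glucose and
#: RNA-ribose surrogates mapped to their precursor pools)
DEFAULT_FRAGMENTS = (
    EMU("PYR", (1, 2, 3)),   # alanine backbone
    EMU("PYR", (2, 3)),      # alanine fragment
    EMU("OAA", (1, 2, 3, 4)),  # aspartate backbone
    EMU("OAA", (1, 2)),      # aspartate fragment
    EMU("R5P", (1, 2, 3, 4, 5)),  # RNA-bound ribose
    EMU("F6P", (1, 2, 3, 4, 5, 6)),  # glycogen-bound glucose
    EMU("ACE", (1, 2)),      # acetate/ethanol C2 unit
    EMU("FOR", (1,)),        # formate
)


@dataclass
class CentralFluxParametrization:
    """Free-flux parametrization of the reduced network.

    theta = (anaplerotic PEP-carboxykinase flux, PFO share of acetyl-CoA
    formation, forward-PPP cycling flux), all in units of a fixed glucose
    uptake of 100.  Dependent fluxes follow from steady-state balances with
    fixed efflux drains (RNA pentose, succinate-bound OAA, lactate-bound
    pyruvate).
    """

    uptake: float = 100.0
    rna_drain: float = 3.0
    succ_drain: float = 2.0
    lac_drain: float = 10.0
    #: constrain the hydrogenosome to import pyruvate only: the
    #: malic-enzyme return flux is clamped to zero, which collapses the
    #: malate/pyruvate-import degeneracy and pins the anaplerotic flux to
    #: the succinate drain
    pyruvate_only_import: bool = False

    names: Tuple[str, ...] = ("v_pepck", "pfo_share", "ppp_cycle")
    lower: Tuple[float, ...] = (2.0, 0.0, 0.0)
    upper: Tuple[float, ...] = (40.0, 1.0, 15.0)

    def __post_init__(self) -> None:
        if self.pyruvate_only_import:
            self.names = ("pfo_share", "ppp_cycle")
            self.lower = (0.0, 0.0)
            self.upper = (1.0, 15.0)

    def to_fluxes(self, theta: Sequence[float]) -> Dict[str, float]:
        if self.pyruvate_only_import:
            phi, f = map(float, theta)
            v_pepck = self.succ_drain
        else:
            v_pepck, phi, f = map(float, theta)
        r, s, l = self.rna_drain, self.succ_drain, self.lac_drain
        if v_pepck < s:
            raise ValueError("anaplerotic flux below the succinate drain")
        u = r / 3.0 + f  # reverse-PPP bundle flux
        v_me = v_pepck - s
        # F6P: uptake - emp - 2u (reverse) + 2f (forward) = 0
        v_emp = self.uptake - 2.0 * u + 2.0 * f
        # GAP: 2 emp - u + f - pyk = 0
        v_pyk = 2.0 * v_emp - u + f
        ace_total = v_pyk + v_me - l - v_pepck
        if ace_total <= 0:
            raise ValueError("no acetyl-CoA formation at these parameters")
        v_pfo = phi * ace_total
        v_pfl = ace_total - v_pfo
        v_co2in = max(0.0, v_pepck - v_me - v_pfo)
        v_co2out = v_me + v_pfo + v_co2in - v_pepck
        return {
            "v_upt": self.uptake,
            "v_emp": v_emp,
            "v_tkt2_r": u, "v_tal_r": u, "v_tkt1_r": u, "v_xr": 2.0 * u,
            "v_tkt1_f": f, "v_tal_f": f, "v_tkt2_f": f, "v_rx": 2.0 * f,
            "v_pyk": v_pyk,
            "v_pfl": v_pfl, "v_pfo": v_pfo,
            "v_pepck": v_pepck, "v_oaamal": v_pepck, "v_me": v_me,
            "v_scr": SCRAMBLE_EXCHANGE,
            "v_co2in": v_co2in, "v_co2out": v_co2out,
            "v_rna": r, "v_lac": l, "v_succ": s,
        }
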