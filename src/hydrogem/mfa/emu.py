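"""Elementary-metabolite-unit (EMU) decomposition and steady-state MID
simulation.

The decomposition walks backward from the target fragments through the
atom maps, emitting for every unknown EMU the set of producing terms
(either a single source EMU or a convolution of source EMUs from a
cleavage/condensation).  Simulation then solves one linear system per EMU
size, ascending, since convolution sources are strictly smaller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .atommap import AtomMapError, AtomMapNetwork


@dataclass(frozen=True, order=True)
class EMU:
    """A metabolite fragment: ordered carbon positions (1-based)."""

    met: str
    positions: Tuple[int, ...]

    def __post_init__(self) -> None:
        if tuple(sorted(set(self.positions))) != self.positions:
            raise AtomMapError(
                f"EMU positions must be sorted and unique: {self.positions}"
            )

    @property
    def size(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:  # e.g. "pyr[2,3]"
        return f"{self.met}[{','.join(map(str, self.positions))}]"


@dataclass(frozen=True)
class EmuTerm:
    """One production term: reaction flux feeding an EMU from sources.

    ``sources`` has one entry for a transfer, several for a condensation
    (their MIDs convolve).
    """

    reaction_id: str
    sources: Tuple[EMU, ...]


@dataclass
class EmuNetwork:
    """Decomposed EMU reaction network, sufficient for the target MIDs."""

    network: AtomMapNetwork
    targets: Tuple[EMU, ...]
    #: every non-input EMU with its production terms
    production: Dict[EMU, List[EmuTerm]]

    @property
    def emus(self) -> List[EMU]:
        return sorted(self.production, key=lambda e: (e.size, e.met, e.positions))


def emu_decompose(
    network: AtomMapNetwork, target_emus: Sequence[EMU]
) -> EmuNetwork:
    """Minimal size-stratified EMU network reaching all targets."""
    production: Dict[EMU, List[EmuTerm]] = {}
    stack = list(target_emus)
    while stack:
        emu = stack.pop()
        if emu.met in network.inputs or emu in production:
            continue
        producers = network.producers(emu.met)
        if not producers:
            raise AtomMapError(
                f"{emu} has no producing reaction and is not an input"
            )
        terms: List[EmuTerm] = []
        for rxn, occurrence in producers:
            _, letters = rxn.products[occurrence]
            wanted = [letters[p - 1] for p in emu.positions]
            by_source: Dict[Tuple[str, int], List[int]] = {}
            # group the wanted carbons by substrate occurrence
            groups: Dict[int, List[int]] = {}
            for ch in wanted:
                for si, (smet, sletters) in enumerate(rxn.substrates):
                    pos = sletters.find(ch)
                    if pos >= 0:
                        groups.setdefault(si, []).append(pos + 1)
                        break
            sources = tuple(
                EMU(rxn.substrates[si][0], tuple(sorted(ps)))
                for si, ps in sorted(groups.items())
            )
            terms.append(EmuTerm(rxn.id, sources))
            for s in sources:
                if s.met not in network.inputs and s not in production:
                    stack.append(s)
        production[emu] = terms
    return EmuNetwork(network, tuple(target_emus), production)


def _convolve(mids: Sequence[np.ndarray]) -> np.ndarray:
    out = mids[0]
    for m in mids[1:]:
        out = np.convolve(out, m)
    return out


def simulate_mids(
    emu_network: EmuNetwork,
    fluxes: Mapping[str, float],
    tracer: Mapping[str, object] | None = None,
    check_balance: bool = True,
) -> Dict[EMU, np.ndarray]:
    """Steady-state MIDs of every EMU in the decomposed network.

    ``tracer`` optionally overrides input MID functions by metabolite id.
    Raises :class:`AtomMapError` when an EMU receives zero total inflow
    (singular balance), naming the EMU.
    """
    inputs = dict(emu_network.network.inputs)
    if tracer:
        inputs.update(tracer)
    if check_balance:
        emu_network.network.check_flux_balance(fluxes)

    def input_mid(emu: EMU) -> np.ndarray:
        return np.asarray(inputs[emu.met](emu.positions), dtype=float)

    solved: Dict[EMU, np.ndarray] = {}

    def mid_of(emu: EMU) -> np.ndarray:
        if emu.met in inputs:
            return input_mid(emu)
        return solved[emu]

    by_size: Dict[int, List[EMU]] = {}
    for emu in emu_network.production:
        by_size.setdefault(emu.size, []).append(emu)

    # an EMU with zero inflow is only a problem if something with positive
    # flux (or a declared target) actually needs its MID
    needed = set(emu_network.targets)
    for emu, terms in emu_network.production.items():
        for term in terms:
            if float(fluxes.get(term.reaction_id, 0.0)) > 0.0:
                needed.add(emu)
                needed.update(term.sources)

    for size in sorted(by_size):
        unknowns = sorted(by_size[size], key=lambda e: (e.met, e.positions))
        index = {e: i for i, e in enumerate(unknowns)}
        n = len(unknowns)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for emu in unknowns:
            i = index[emu]
            total_in = 0.0
            for term in emu_network.production[emu]:
                v = float(fluxes.get(term.reaction_id, 0.0))
                if v == 0.0:
                    continue
                total_in += v
                if (len(term.sources) == 1
                        and term.sources[0] in index):
                    A[i, index[term.sources[0]]] -= v
                else:
                    B[i] += v * _convolve([mid_of(s) for s in term.sources])
            if total_in <= 0.0:
                if emu in needed:
                    raise AtomMapError(
                        f"zero dilution into {emu}: no inflow at these "
                        "fluxes"
                    )
                # inert pool: give it an unlabeled placeholder MID
                A[i, i] = 1.0
                B[i, 0] = 1.0
                continue
            A[i, i] += total_in
        X = np.linalg.solve(A, B)
        for emu, i in index.items():
            solved[emu] = X[i]
    return {emu: solved[emu] for emu in emu_network.production}


def target_mids(
    emu_network: EmuNetwork, fluxes: Mapping[str, float], **kw
) -> Dict[EMU, np.ndarray]:
    """MIDs restricted to the declared targets."""
    all_mids = simulate_mids(emu_network, fluxes, **kw)
    out = {}
    for t in emu_network.targets:
        if t.met in emu_network.network.inputs:
            inputs = dict(emu_network.network.inputs)
            tr = kw.get("tracer") or {}
            inputs.update(tr)
            out[t] = np.asarray(inputs[t.met](t.positions), dtype=float)
        else:
            out[t] = all_mids[t]
    return out
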