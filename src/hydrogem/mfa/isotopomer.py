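"""Brute-force positional-isotopomer simulator.

Independent oracle for the EMU implementation: tracks the full joint
labeling state (2^C isotopomer fractions per metabolite) and solves the
steady-state balance by damped fixed-point iteration.  Exponential in
carbon count — use on networks with few carbons only.
"""

from __future__ import annotations

from itertools import product as iproduct
from typing import Dict, Mapping, Tuple

import numpy as np

from .atommap import AtomMapError, AtomMapNetwork
from .emu import EMU


def _input_isotopomers(network: AtomMapNetwork, met: str,
                       tracer: Mapping | None) -> np.ndarray:
    """Full isotopomer distribution of an input metabolite, assuming
    positional independence of the tracer definition."""
    inputs = dict(network.inputs)
    if tracer:
        inputs.update(tracer)
    n = network.carbon_counts[met]
    # per-position labeling probability from single-position MIDs
    p = np.array([inputs[met]((i + 1,))[1] for i in range(n)])
    dist = np.zeros(2**n)
    for state in iproduct((0, 1), repeat=n):
        prob = 1.0
        for bit, pi in zip(state, p):
            prob *= pi if bit else (1 - pi)
        dist[_state_index(state)] = prob
    return dist


def _state_index(state: Tuple[int, ...]) -> int:
    idx = 0
    for bit in state:
        idx = (idx << 1) | bit
    return idx


def simulate_isotopomers(
    network: AtomMapNetwork,
    fluxes: Mapping[str, float],
    tracer: Mapping | None = None,
    tol: float = 1e-14,
    max_iter: int = 200000,
) -> Dict[str, np.ndarray]:
    """Steady-state isotopomer distributions of all non-input metabolites."""
    network.check_flux_balance(fluxes)
    inputs = set(network.inputs)
    mets = sorted(
        {m for r in network.reactions.values()
         for m, _ in r.substrates + r.products} - inputs
    )
    dists: Dict[str, np.ndarray] = {}
    for met in mets:
        n = network.carbon_counts[met]
        d = np.zeros(2**n)
        d[0] = 1.0
        dists[met] = d
    fixed = {
        met: _input_isotopomers(network, met, tracer) for met in inputs
    }

    def dist_of(met: str) -> np.ndarray:
        return fixed[met] if met in fixed else dists[met]

    for _ in range(max_iter):
        delta = 0.0
        for met in mets:
            n = network.carbon_counts[met]
            total_in = 0.0
            acc = np.zeros(2**n)
            for r in network.reactions.values():
                v = float(fluxes.get(r.id, 0.0))
                if v == 0.0:
                    continue
                for pk, (pm, pletters) in enumerate(r.products):
                    if pm != met:
                        continue
                    total_in += v
                    acc += v * _product_distribution(
                        r, pk, {m: dist_of(m) for m, _ in r.substrates},
                        network.carbon_counts,
                    )
            if total_in <= 0:
                raise AtomMapError(f"zero dilution into metabolite {met}")
            new = acc / total_in
            # renormalize: condensation cycles make the probability-mass
            # direction of the raw iteration unstable, and rounding error
            # would otherwise drift the solve onto a spurious
            # mass-deficient fixed point
            total = new.sum()
            if total > 0:
                new = new / total
            delta = max(delta, float(np.abs(new - dists[met]).max()))
            dists[met] = new
        if delta < tol:
            break
    else:  # pragma: no cover - convergence failure
        raise AtomMapError("isotopomer fixed point did not converge")
    return dists


def _product_distribution(
    reaction, occurrence: int, substrate_dists: Dict[str, np.ndarray],
    carbon_counts: Mapping[str, int],
) -> np.ndarray:
    """Isotopomer distribution of one product occurrence given substrate
    joint distributions (well-mixed pools: substrates independent)."""
    pm, pletters = reaction.products[occurrence]
    n = len(pletters)
    out = np.zeros(2**n)
    # enumerate joint substrate states
    subs = list(reaction.substrates)
    sizes = [len(letters) for _, letters in subs]
    ranges = [list(iproduct((0, 1), repeat=s)) for s in sizes]
    for joint in iproduct(*ranges):
        prob = 1.0
        for (smet, _), state in zip(subs, joint):
            prob *= substrate_dists[smet][_state_index(state)]
        if prob == 0.0:
            continue
        # map substrate carbons to the product state
        state_bits = []
        for ch in pletters:
            for si, (smet, sletters) in enumerate(subs):
                pos = sletters.find(ch)
                if pos >= 0:
                    state_bits.append(joint[si][pos])
                    break
        out[_state_index(tuple(state_bits))] += prob
    return out


def isotopomer_mid(dist: np.ndarray, positions: Tuple[int, ...],
                   n_carbons: int) -> np.ndarray:
    """Marginal MID of a fragment from a full isotopomer distribution."""
    out = np.zeros(len(positions) + 1)
    for idx in range(len(dist)):
        bits = [(idx >> (n_carbons - 1 - i)) & 1 for i in range(n_carbons)]
        k = sum(bits[p - 1] for p in positions)
        out[k] += dist[idx]
    return out


def mids_via_isotopomers(
    network: AtomMapNetwork,
    fluxes: Mapping[str, float],
    targets,
    tracer: Mapping | None = None,
) -> Dict[EMU, np.ndarray]:
    """Target MIDs computed by full isotopomer enumeration (oracle path)."""
    dists = simulate_isotopomers(network, fluxes, tracer=tracer)
    inputs = dict(network.inputs)
    if tracer:
        inputs.update(tracer)
    out: Dict[EMU, np.ndarray] = {}
    for t in targets:
        if t.met in inputs:
            out[t] = np.asarray(inputs[t.met](t.positions), dtype=float)
        else:
            out[t] = isotopomer_mid(
                dists[t.met], t.positions, network.carbon_counts[t.met]
            )
    return out
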