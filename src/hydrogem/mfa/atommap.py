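"""Carbon atom-transition networks for isotope-labeling simulation.

Each reaction lists its substrates and products with carbon-index letter
strings (e.g. fructose-6-phosphate ``"abcdef"`` cleaved to two trioses
``"cba"`` and ``"def"``).  Every product carbon must trace to exactly one
substrate carbon.  Fluxes are net and nonnegative (reversible steps are
represented as separate forward/backward mapped reactions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np


class AtomMapError(ValueError):
    pass


@dataclass(frozen=True)
class AtomMapReaction:
    """One mapped reaction: ``substrates``/``products`` are tuples of
    (metabolite, letters)."""

    id: str
    substrates: Tuple[Tuple[str, str], ...]
    products: Tuple[Tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: Dict[str, Tuple[str, int]] = {}
        for met, letters in self.substrates:
            for i, ch in enumerate(letters):
                if ch in seen:
                    raise AtomMapError(
                        f"{self.id}: substrate letter {ch!r} reused"
                    )
                seen[ch] = (met, i + 1)
        n_sub = len(seen)
        n_prod = 0
        for met, letters in self.products:
            for ch in letters:
                if ch not in seen:
                    raise AtomMapError(
                        f"{self.id}: product letter {ch!r} has no substrate "
                        "origin"
                    )
                n_prod += 1
        if n_prod != n_sub:
            raise AtomMapError(
                f"{self.id}: {n_sub} substrate carbons vs {n_prod} product "
                "carbons (carbon not conserved)"
            )

    def origin(self, letter: str) -> Tuple[str, int]:
        """(substrate metabolite, 1-based carbon position) of a letter."""
        for met, letters in self.substrates:
            idx = letters.find(letter)
            if idx >= 0:
                return met, idx + 1
        raise AtomMapError(f"{self.id}: unknown letter {letter!r}")


MidFunction = Callable[[Tuple[int, ...]], np.ndarray]


class AtomMapNetwork:
    """A set of mapped reactions plus labeled-input declarations.

    ``inputs`` maps input metabolite ids to functions returning the MID of
    any subset of carbon positions (e.g. a tracer definition).
    """

    def __init__(
        self,
        reactions: Sequence[AtomMapReaction],
        inputs: Mapping[str, MidFunction],
        carbon_counts: Mapping[str, int],
    ) -> None:
        self.reactions = {r.id: r for r in reactions}
        if len(self.reactions) != len(reactions):
            raise AtomMapError("duplicate reaction ids")
        self.inputs = dict(inputs)
        self.carbon_counts = dict(carbon_counts)
        for r in reactions:
            for met, letters in r.substrates + r.products:
                n = self.carbon_counts.get(met)
                if n is None:
                    raise AtomMapError(f"{r.id}: unknown metabolite {met}")
                if len(letters) != n:
                    raise AtomMapError(
                        f"{r.id}: {met} has {n} carbons but map {letters!r}"
                    )

    def producers(self, met: str) -> List[Tuple[AtomMapReaction, int]]:
        """(reaction, product-occurrence index) pairs producing ``met``."""
        out = []
        for r in self.reactions.values():
            for k, (pm, _) in enumerate(r.products):
                if pm == met:
                    out.append((r, k))
        return out

    def check_flux_balance(
        self, fluxes: Mapping[str, float], tol: float = 1e-6
    ) -> None:
        """Verify steady state of every non-input metabolite under net
        fluxes, counting sinks as any consumption not balanced internally.

        Metabolites consumed by no reaction are treated as effluxes
        (sinks); all others must balance.
        """
        balance: Dict[str, float] = {}
        consumed: Dict[str, bool] = {}
        for r in self.reactions.values():
            v = float(fluxes.get(r.id, 0.0))
            if v < -tol:
                raise AtomMapError(f"negative net flux for {r.id}")
            for met, _ in r.substrates:
                balance[met] = balance.get(met, 0.0) - v
                consumed[met] = True
            for met, _ in r.products:
                balance[met] = balance.get(met, 0.0) + v
                consumed.setdefault(met, False)
        for met, b in balance.items():
            if met in self.inputs:
                continue
            if not consumed.get(met, False):
                if b < -tol:
                    raise AtomMapError(f"sink {met} has negative production")
                continue  # pure sink pool (efflux)
            if abs(b) > tol:
                raise AtomMapError(
                    f"metabolite {met} violates steady state by {b:.3g}"
                )


def tracer_mid(
    labeled_positions: Sequence[int], purity: float = 1.0
) -> MidFunction:
    """MID function for a positionally labeled tracer.

    Each listed position carries label with probability ``purity``; all
    other positions are unlabeled (natural abundance off).
    """
    labeled = set(labeled_positions)

    def mid(positions: Tuple[int, ...]) -> np.ndarray:
        k = len(positions)
        out = np.zeros(k + 1)
        n_lab = sum(1 for p in positions if p in labeled)
        # binomial over the labeled positions present in the fragment
        from math import comb

        for j in range(n_lab + 1):
            out[j] += comb(n_lab, j) * purity**j * (1 - purity) ** (n_lab - j)
        return out

    return mid


def unlabeled_mid(positions: Tuple[int, ...]) -> np.ndarray:
    out = np.zeros(len(positions) + 1)
    out[0] = 1.0
    return out
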