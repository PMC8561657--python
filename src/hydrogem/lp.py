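"""Linear-programming machinery over a metabolic model.

Flux balance analysis (FBA), parsimonious FBA (two-stage, with reversible
reactions split into irreversible pairs), flux variability analysis (FVA),
artificial-centering hit-and-run flux sampling on the near-optimal
polytope, and application of measured extracellular rates as exchange
bounds.

All solves go through ``scipy.optimize.linprog`` (HiGHS).  Solver
feasibility tolerance is 1e-9; solutions are validated against S.v = 0 and
the bounds at 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .core.model import MetabolicModel, ModelError

#: solver-level feasibility/optimality tolerance
SOLVER_TOL = 1e-9
#: validation tolerance on S.v = 0 and bound adherence
VALIDATION_TOL = 1e-6


class LPError(RuntimeError):
    """An LP stage failed in a way that cannot be expressed as a status."""


@dataclass
class FluxSolution:
    """Outcome of an FBA/pFBA solve.

    ``objective_value`` is the optimized flux (for a biomass objective, the
    growth rate mu in 1/h).  ``fluxes`` maps reaction id to flux in
    mmol/gDW/h.
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_id: Optional[str] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FluxRange:
    """Per-reaction flux bounds at a fixed objective fraction."""

    objective_fraction: float
    minimum: Dict[str, float]
    maximum: Dict[str, float]

    def range(self, rxn_id: str) -> Tuple[float, float]:
        return self.minimum[rxn_id], self.maximum[rxn_id]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"min_flux": self.minimum, "max_flux": self.maximum}
        ).rename_axis("reaction")


@dataclass
class FluxSample:
    """Hit-and-run flux samples: ``matrix`` is n_samples x n_reactions."""

    matrix: np.ndarray
    reaction_ids: List[str]
    seed: int
    objective_fraction: float
    thinning: int

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, rxn_id: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(rxn_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=self.reaction_ids)


@dataclass(frozen=True)
class MeasuredFlux:
    """One extracellular rate with mean, SD and observed bound interval."""

    product: str  # metabolite stem ("ac") or exchange reaction id
    mean: float
    sd: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if not self.lower_bound <= self.mean <= self.upper_bound:
            raise ModelError(
                f"measured flux {self.product}: mean {self.mean} outside "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )
        if self.sd < 0:
            raise ModelError(f"measured flux {self.product}: negative SD")


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------


def _assemble(model: MetabolicModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return S, met_ids, rxn_ids, lb, ub


def _solve(c, S, lb, ub, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    return res


def _validate(v: np.ndarray, S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> None:
    residual = np.abs(S @ v).max() if S.size else 0.0
    if residual > VALIDATION_TOL:
        raise LPError(f"steady-state residual {residual:.2e} > {VALIDATION_TOL}")
    if (v < lb - VALIDATION_TOL).any() or (v > ub + VALIDATION_TOL).any():
        raise LPError("solution violates bounds beyond tolerance")


def _objective_index(model: MetabolicModel, rxn_ids: List[str],
                     objective: Optional[str]) -> int:
    obj = objective or model.objective_id
    if obj is None:
        raise ModelError("model has no objective and none was given")
    if obj not in model.reactions:
        raise ModelError(f"objective reaction {obj!r} not in model")
    return rxn_ids.index(obj)


# --------------------------------------------------------------------------
# FBA / pFBA / FVA
# --------------------------------------------------------------------------


def fba(model: MetabolicModel, objective: Optional[str] = None,
        maximize: bool = True) -> FluxSolution:
    """Maximize (or minimize) the objective flux subject to S.v = 0 and bounds.

    Infeasibility and unboundedness are reported in ``status``, never
    silently.
    """
    S, _, rxn_ids, lb, ub = _assemble(model)
    j = _objective_index(model, rxn_ids, objective)
    c = np.zeros(len(rxn_ids))
    c[j] = -1.0 if maximize else 1.0
    res = _solve(c, S, lb, ub)
    if res.status == 2:
        return FluxSolution("infeasible", None, {}, rxn_ids[j])
    if res.status == 3:
        return FluxSolution("unbounded", None, {}, rxn_ids[j])
    if not res.success:  # pragma: no cover - solver numerical failure
        raise LPError(f"solver failure: {res.message}")
    v = res.x
    _validate(v, S, lb, ub)
    return FluxSolution(
        "optimal", float(v[j]), dict(zip(rxn_ids, map(float, v))), rxn_ids[j]
    )


def _split_problem(S, lb, ub):
    """Split each flux into forward/backward nonnegative parts.

    Returns (S2, lb2, ub2, recombine) where columns are [forward | backward]
    and ``recombine(x)`` maps back to net fluxes.
    """
    n = S.shape[1]
    S2 = np.hstack([S, -S])
    lb2 = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
    ub2 = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])

    def recombine(x: np.ndarray) -> np.ndarray:
        return x[:n] - x[n:]

    return S2, lb2, ub2, recombine


def pfba(model: MetabolicModel, objective_fraction: float = 1.0,
         objective: Optional[str] = None) -> FluxSolution:
    """Parsimonious FBA: fix the objective at ``fraction`` of its optimum,
    then minimize total absolute flux via flux splitting.

    Returns the minimal-total-flux solution; its ``objective_value`` is the
    achieved objective flux.  Infeasibility propagates from the first stage.
    """
    stage1 = fba(model, objective=objective)
    if not stage1.optimal:
        return stage1
    S, _, rxn_ids, lb, ub = _assemble(model)
    j = _objective_index(model, rxn_ids, objective)
    target = objective_fraction * stage1.objective_value
    # back off by a sliver so stage 1's vertex stays feasible at solver
    # tolerance even when fraction = 1
    target -= 1e-9 * max(1.0, abs(target))
    S2, lb2, ub2, recombine = _split_problem(S, lb, ub)
    n = len(rxn_ids)
    # objective flux >= target  (as -v_j <= -target)
    row = np.zeros(2 * n)
    row[j], row[n + j] = -1.0, 1.0
    c = np.ones(2 * n)
    res = _solve(c, S2, lb2, ub2, A_ub=row[None, :], b_ub=np.array([-target]))
    if not res.success:
        raise LPError(f"pFBA stage 2 failed: {res.message}")
    v = recombine(res.x)
    _validate(v, S, lb, ub)
    return FluxSolution(
        "optimal", float(v[j]), dict(zip(rxn_ids, map(float, v))), rxn_ids[j]
    )


def total_flux(solution: FluxSolution) -> float:
    """Sum of absolute fluxes of a solution (the pFBA stage-2 objective)."""
    return float(sum(abs(v) for v in solution.fluxes.values()))


def fva(model: MetabolicModel, objective_fraction: float = 0.9,
        reactions: Optional[Iterable[str]] = None,
        objective: Optional[str] = None) -> FluxRange:
    """Per-reaction min/max flux with the objective held at >= fraction x
    optimum (two LPs per reaction)."""
    base = fba(model, objective=objective)
    if not base.optimal:
        raise LPError(f"FVA requires an optimal base solution ({base.status})")
    S, _, rxn_ids, lb, ub = _assemble(model)
    j = _objective_index(model, rxn_ids, objective)
    target = objective_fraction * base.objective_value
    row = np.zeros(len(rxn_ids))
    row[j] = -1.0
    A_ub, b_ub = row[None, :], np.array([-target])
    wanted = list(reactions) if reactions is not None else rxn_ids
    vmin: Dict[str, float] = {}
    vmax: Dict[str, float] = {}
    for rid in wanted:
        k = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        for sign, store in ((1.0, vmin), (-1.0, vmax)):
            c[k] = sign
            res = _solve(c, S, lb, ub, A_ub=A_ub, b_ub=b_ub)
            if not res.success:
                raise LPError(f"FVA solve failed for {rid}: {res.message}")
            store[rid] = float(res.x[k])
        c[k] = 0.0
    # clamp tiny numerical inversions
    for rid in wanted:
        if vmin[rid] > vmax[rid]:
            vmin[rid] = vmax[rid] = 0.5 * (vmin[rid] + vmax[rid])
    return FluxRange(objective_fraction, vmin, vmax)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------


def _null_space(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    if S.size == 0:
        return np.eye(S.shape[1])
    u, s, vh = np.linalg.svd(S)
    rank = int((s > tol * s.max()).sum()) if s.size else 0
    return vh[rank:].T.copy()


def sample_fluxes(model: MetabolicModel, n: int = 2000,
                  objective_fraction: float = 0.9,
                  seed: int = 0, warmup: int = 1000, thinning: int = 100,
                  objective: Optional[str] = None) -> FluxSample:
    """Artificial-centering hit-and-run over the near-optimal flux polytope.

    The polytope is {v : S.v = 0, lb <= v <= ub, c.v >= fraction x optimum};
    moves are taken in null-space coordinates so the steady-state equality
    holds exactly.  Reproducible given ``seed``; every returned row satisfies
    the constraints to the validation tolerance.
    """
    base = fba(model, objective=objective)
    if not base.optimal:
        raise LPError(
            "sampling polytope is empty: base FBA is "
            f"{base.status} (binding constraint set: model bounds)"
        )
    S, _, rxn_ids, lb, ub = _assemble(model)
    j = _objective_index(model, rxn_ids, objective)
    target = objective_fraction * base.objective_value
    v0 = np.array([base.fluxes[r] for r in rxn_ids])

    # The polytope is usually not full-dimensional in the null space of S:
    # irreversibilities and dead ends pin many fluxes to a single value at
    # this objective fraction.  Identify them by FVA and fold them into the
    # equality system so the remaining directions are genuinely free.
    ranges = fva(model, objective_fraction, objective=objective)
    width = np.array([ranges.maximum[r] - ranges.minimum[r] for r in rxn_ids])
    mid = np.array([0.5 * (ranges.maximum[r] + ranges.minimum[r])
                    for r in rxn_ids])
    pinned = width < 1e-8
    S_eff = S
    if pinned.any():
        # v0 (a feasible point) already carries the pinned values; adding
        # unit rows removes those directions from the null space
        pin_rows = np.eye(len(rxn_ids))[pinned]
        S_eff = np.vstack([S, pin_rows])
    N = _null_space(S_eff)
    k = N.shape[1]
    if k == 0:
        raise LPError("flux space has no degrees of freedom to sample")

    obj_row = np.zeros(len(rxn_ids))
    obj_row[j] = -1.0

    # constraints in y-space around v0 (v = v0 + N y):
    #   N y <= ub - v0;  -N y <= v0 - lb;  -(v0 + N y)_j <= -target
    A_rows = np.vstack([N, -N, (obj_row @ N)[None, :]])
    b_vals = np.concatenate([ub - v0, v0 - lb, [-target - obj_row @ v0]])
    norms = np.linalg.norm(A_rows, axis=1)
    keep = norms > 1e-12
    A_rows, b_vals, norms = A_rows[keep], b_vals[keep], norms[keep]

    # strictly interior start: Chebyshev center of the y-polytope
    c_cheb = np.zeros(k + 1)
    c_cheb[-1] = -1.0
    res = linprog(
        c_cheb,
        A_ub=np.hstack([A_rows, norms[:, None]]),
        b_ub=b_vals,
        bounds=[(None, None)] * k + [(0.0, None)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 0:
        raise LPError(
            "sampling polytope has an empty interior at fraction "
            f"{objective_fraction} (binding constraints: objective + bounds)"
        )
    y = res.x[:k]
    radius = res.x[-1]

    eps = 1e-11

    def limits(y: np.ndarray, d: np.ndarray) -> Tuple[float, float]:
        Ad = A_rows @ d
        slack = np.maximum(b_vals - A_rows @ y, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_pos = np.where(Ad > eps, slack / Ad, np.inf)
            t_neg = np.where(Ad < -eps, -slack / np.abs(Ad), -np.inf)
        return float(t_neg.max()), float(t_pos.min())

    rng = np.random.default_rng(seed)
    center = y.copy()
    n_seen = 1
    # reservoir of previously visited points for the centering directions
    reservoir = np.empty((256, k))
    reservoir[0] = y
    n_stored = 1
    samples = np.empty((n, len(rxn_ids)))
    collected = 0
    step = 0
    stall = 0
    while collected < n:
        if step < warmup or n_seen < 3 or stall > 5:
            d = rng.standard_normal(k)
        else:
            # artificial centering: direction through a random stored point
            ref = reservoir[rng.integers(n_stored)]
            d = ref - center + 1e-6 * radius * rng.standard_normal(k)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            stall += 1
            step += 1
            continue
        d /= norm
        t_lo, t_hi = limits(y, d)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi - t_lo < 1e-12:
            stall += 1
            step += 1
            continue
        stall = 0
        # shrink slightly to stay strictly interior
        width = t_hi - t_lo
        t = rng.uniform(t_lo + 1e-9 * width, t_hi - 1e-9 * width)
        y = y + t * d
        n_seen += 1
        center += (y - center) / n_seen
        if n_stored < reservoir.shape[0]:
            reservoir[n_stored] = y
            n_stored += 1
        else:  # reservoir sampling keeps a uniform subsample of the chain
            idx = rng.integers(n_seen)
            if idx < reservoir.shape[0]:
                reservoir[idx] = y
        step += 1
        if step > warmup and (step - warmup) % thinning == 0:
            v = v0 + N @ y
            v = np.clip(v, lb, ub)
            samples[collected] = v
            collected += 1
    # validate every row
    resid = np.abs(samples @ S.T).max() if S.size else 0.0
    if resid > VALIDATION_TOL:
        raise LPError(f"sample steady-state residual {resid:.2e}")
    return FluxSample(samples, rxn_ids, seed, objective_fraction, thinning)


# --------------------------------------------------------------------------
# measured-flux constraints
# --------------------------------------------------------------------------


def _exchange_id_for(model: MetabolicModel, product: str) -> str:
    if product in model.reactions:
        return product
    for candidate in (f"EX_{product}_e", f"EX_{product}"):
        if candidate in model.reactions:
            return candidate
    raise ModelError(f"no exchange reaction found for product {product!r}")


def apply_measured_bounds(
    model: MetabolicModel, measurements: Sequence[MeasuredFlux]
) -> MetabolicModel:
    """Return a copy with each measured product's exchange bounded to its
    observed [lower, upper] interval."""
    out = model.copy()
    for m in measurements:
        rid = _exchange_id_for(out, m.product)
        out.set_bounds(rid, m.lower_bound, m.upper_bound)
    return out
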