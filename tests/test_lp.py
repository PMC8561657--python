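from fractions import Fraction
from itertools import combinations, product

import numpy as np
import pytest

from hydrogem import (
    MeasuredFlux,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_measured_bounds,
    fba,
    fva,
    pfba,
    sample_fluxes,
)
from hydrogem.datasets import measured_fluxes
from hydrogem.lp import total_flux

F = Fraction


def _toy(reactions, mets_e=(), mets_c=(), objective=None):
    m = MetabolicModel("toy")
    for mid in mets_e:
        m.add_metabolite(Metabolite(mid, formula="C", compartment="e"))
    for mid in mets_c:
        m.add_metabolite(Metabolite(mid, formula="C", compartment="c"))
    for r in reactions:
        m.add_reaction(r)
    m.objective_id = objective
    return m


def _chain_model():
    """source -> A -> B -> sink with bounds (0, 10)."""
    return _toy(
        [
            Reaction("EX_a", {"a_e": F(-1)}, -10, 0, kind="exchange"),
            Reaction("T", {"a_e": F(-1), "a_c": F(1)}, 0, 10),
            Reaction("V", {"a_c": F(-1), "b_c": F(1)}, 0, 10),
            Reaction("DM_b", {"b_c": F(-1)}, 0, 10, kind="demand"),
        ],
        mets_e=["a_e"], mets_c=["a_c", "b_c"], objective="DM_b",
    )


def _diamond_model():
    """Two parallel internal routes from A to B."""
    return _toy(
        [
            Reaction("EX_a", {"a_e": F(-1)}, -10, 0, kind="exchange"),
            Reaction("T", {"a_e": F(-1), "a_c": F(1)}, 0, 10),
            Reaction("P1", {"a_c": F(-1), "b_c": F(1)}, 0, 10),
            Reaction("P2", {"a_c": F(-1), "b_c": F(1)}, 0, 10),
            Reaction("DM_b", {"b_c": F(-1)}, 0, 10, kind="demand"),
        ],
        mets_e=["a_e"], mets_c=["a_c", "b_c"], objective="DM_b",
    )


def enumerate_vertex_optimum(model, objective_id):
    """Brute-force LP oracle: enumerate candidate basic solutions by fixing
    subsets of fluxes at their bounds and solving the equality system."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    j = rxn_ids.index(objective_id)
    rank = np.linalg.matrix_rank(S)
    best = None
    n_fix = n - rank
    for subset in combinations(range(n), n_fix):
        for choices in product(*[(lb[i], ub[i]) for i in subset]):
            # solve S v = 0 with v fixed on the subset
            A = np.vstack([S] + [np.eye(n)[i] for i in subset])
            b = np.concatenate([np.zeros(S.shape[0]), np.array(choices)])
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.abs(A @ v - b).max() > 1e-9:
                continue
            if (v < lb - 1e-9).any() or (v > ub + 1e-9).any():
                continue
            if best is None or v[j] > best:
                best = v[j]
    return best


class TestFBA:
    def test_three_reaction_chain_hits_bound(self):
        sol = fba(_chain_model())
        assert sol.objective_value == pytest.approx(10.0)
        for rid in ("T", "V", "DM_b"):
            assert sol.fluxes[rid] == pytest.approx(10.0)

    def test_infeasible_reported_in_status(self):
        m = _chain_model()
        m.set_bounds("DM_b", 5.0, 10.0)
        m.set_bounds("EX_a", 0.0, 0.0)  # no supply but forced demand
        sol = fba(m)
        assert sol.status == "infeasible"

    @pytest.mark.parametrize("builder", [_chain_model, _diamond_model])
    def test_optimum_matches_vertex_enumeration(self, builder):
        """On <= 6-reaction toys the LP optimum equals the brute-force
        vertex-enumeration optimum."""
        m = builder()
        sol = fba(m)
        oracle = enumerate_vertex_optimum(m, m.objective_id)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_core_model_optimum_matches_cobra(self, base_model):
        """Independent solver stack (cobrapy/GLPK) agrees on the optimum."""
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("cross")
        mets = {mid: cobra.Metabolite(mid) for mid in base_model.metabolites}
        pairs = []
        for rid, r in base_model.reactions.items():
            cr = cobra.Reaction(rid)
            cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
            pairs.append((cr, {mets[k]: float(v)
                               for k, v in r.stoichiometry.items()}))
        cm.add_reactions([cr for cr, _ in pairs])
        for cr, st in pairs:
            cr.add_metabolites(st)
        cm.objective = "BIOMASS"
        assert cm.optimize().objective_value == pytest.approx(
            fba(base_model).objective_value, abs=1e-6)


class TestPFBA:
    def test_futile_cycle_suppressed(self):
        m = _chain_model()
        # add a reversible 2-cycle that plain FBA may spin freely
        m.add_reaction(Reaction("C1", {"a_c": F(-1), "b_c": F(1)}, -10, 10))
        m.add_reaction(Reaction("C2", {"b_c": F(-1), "a_c": F(1)}, -10, 10))
        sol = pfba(m)
        assert sol.objective_value == pytest.approx(10.0)
        # exactly one path's worth of flux crosses a_c -> b_c: the 2-cycle
        # contributes nothing beyond (possibly) carrying the path itself
        crossing = (abs(sol.fluxes["V"]) + abs(sol.fluxes["C1"])
                    + abs(sol.fluxes["C2"]))
        assert crossing == pytest.approx(10.0, abs=1e-6)

    def test_objective_preserved_at_fraction_one(self, base_model):
        assert pfba(base_model).objective_value == pytest.approx(
            fba(base_model).objective_value, rel=1e-6)

    def test_total_flux_not_above_sampled_points(self, base_model):
        """pFBA at fraction 0.9 has minimal total |v| among feasible points
        at the same objective fraction."""
        sol = pfba(base_model, objective_fraction=0.9)
        samples = sample_fluxes(base_model, n=100, objective_fraction=0.9,
                                seed=11, warmup=200, thinning=10)
        sampled_totals = np.abs(samples.matrix).sum(axis=1)
        assert total_flux(sol) <= sampled_totals.min() + 1e-6


class TestFVA:
    def test_blocked_reaction_range_is_zero(self, model):
        model.set_bounds("LDH_L", 0.0, 0.0)
        ranges = fva(model, 0.9, reactions=["LDH_L"])
        assert ranges.range("LDH_L") == (0.0, 0.0)

    def test_biomass_range_spans_fraction_to_optimum(self, base_model):
        mu = fba(base_model).objective_value
        ranges = fva(base_model, 0.9, reactions=["BIOMASS"])
        lo, hi = ranges.range("BIOMASS")
        assert lo == pytest.approx(0.9 * mu, rel=1e-6)
        assert hi == pytest.approx(mu, rel=1e-6)

    def test_diamond_branches_each_span_full_range(self):
        ranges = fva(_diamond_model(), 1.0, reactions=["P1", "P2"])
        for rid in ("P1", "P2"):
            lo, hi = ranges.range(rid)
            assert lo == pytest.approx(0.0, abs=1e-8)
            assert hi == pytest.approx(10.0, abs=1e-8)

    def test_pfba_solution_inside_fva_intervals(self, base_model):
        fraction = 0.9
        sol = pfba(base_model, objective_fraction=fraction)
        ranges = fva(base_model, fraction)
        for rid in base_model.reactions:
            lo, hi = ranges.range(rid)
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6


class TestMeasuredBounds:
    def test_h2_row_sets_exchange_interval(self, base_model):
        constrained = apply_measured_bounds(base_model, measured_fluxes())
        rxn = constrained.reactions["EX_h2_e"]
        assert (rxn.lower_bound, rxn.upper_bound) == (0.05, 0.19)

    def test_empty_measurement_list_is_identity(self, base_model):
        out = apply_measured_bounds(base_model, [])
        from hydrogem.core.io import models_equal

        assert models_equal(out, base_model)

    def test_constraining_never_increases_optimum(self, base_model):
        mu = fba(base_model).objective_value
        constrained = apply_measured_bounds(base_model, measured_fluxes())
        sol = fba(constrained)
        assert (not sol.optimal) or sol.objective_value <= mu + 1e-9

    def test_widening_back_restores_optimum(self, base_model):
        mu = fba(base_model).objective_value
        constrained = apply_measured_bounds(base_model, measured_fluxes())
        for m in measured_fluxes():
            constrained.set_bounds(f"EX_{m.product}_e", 0.0, 1000.0)
        assert fba(constrained).objective_value == pytest.approx(mu, rel=1e-9)

    def test_measured_flux_interval_validation(self):
        with pytest.raises(Exception):
            MeasuredFlux("ac", mean=0.5, sd=0.1, lower_bound=0.6,
                         upper_bound=0.7)
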