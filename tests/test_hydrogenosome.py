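from fractions import Fraction

import numpy as np
import pytest

from hydrogem import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ScenarioConfig,
    apply_measured_bounds,
    build_default_model,
    fba,
    pfba,
    sample_fluxes,
)
from hydrogem.datasets import measured_fluxes
from hydrogem.hydrogenosome import (
    compartment_production,
    compare_scenarios,
    constraint_sensitivity,
    formate_ratio,
    mean_error_reduction,
)

F = Fraction


class TestScenarioGrowth:
    def test_bifurcating_hydrogenase_boosts_growth_16_percent(
            self, base_model, bifurcating_model):
        mu_base = fba(base_model).objective_value
        mu_bif = fba(bifurcating_model).objective_value
        gain = 100.0 * (mu_bif / mu_base - 1.0)
        assert 13.0 <= gain <= 19.0

    def test_identical_configs_give_identical_growth(self, base_model):
        other = build_default_model(ScenarioConfig())
        assert fba(other).objective_value == pytest.approx(
            fba(base_model).objective_value, rel=1e-9)

    def test_bifurcating_growth_at_least_base(self, base_model):
        both = build_default_model(ScenarioConfig(hydrogenase_mode="both"))
        assert fba(both).objective_value >= \
            fba(base_model).objective_value - 1e-9

    def test_toy_redox_audit_atp_per_glucose_3_vs_4(self, base_model,
                                                    bifurcating_model):
        """Max-ATP audit: with an ATP-linked phosphofructokinase the
        ethanol-balanced route yields 3 ATP/glucose and the bifurcating
        route 4 (hand stoichiometric audit of the two routes)."""
        for m, expected in ((base_model, 3.0), (bifurcating_model, 4.0)):
            atp = m.copy()
            atp.set_bounds("BIOMASS", 0.0, 0.0)
            atp.set_bounds("ATPM", 0.0, 1000.0)
            # disable the PPi-coupled bypass to isolate textbook glycolysis
            atp.set_bounds("PFK_ppi", 0.0, 0.0)
            atp.add_reaction(Reaction(
                "PFK_atp",
                {"f6p_c": F(-1), "atp_c": F(-1), "fdp_c": F(1),
                 "adp_c": F(1)},
            ))
            sol = fba(atp, objective="DM_atp_c")
            assert sol.objective_value / 1.5 == pytest.approx(expected,
                                                              abs=1e-6)


class TestHydrogenCoupling:
    def test_no_h2_without_pfo_in_base_scenario(self, base_model):
        """With the hydrogen dehydrogenase forward-only and a
        ferredoxin-coupled hydrogenase, PFO is the only route to H2."""
        m = base_model.copy()
        m.set_bounds("PFO_h", 0.0, 0.0)
        sol = fba(m, objective="EX_h2_e")
        assert sol.optimal and sol.objective_value == pytest.approx(0.0,
                                                                    abs=1e-9)

    def test_h2_possible_with_pfo(self, base_model):
        sol = fba(base_model, objective="EX_h2_e")
        assert sol.objective_value > 0.1


class TestCompartmentProduction:
    def _tiny(self):
        m = MetabolicModel("tiny")
        m.add_metabolite(Metabolite("a_e", formula="C", compartment="e"))
        m.add_metabolite(Metabolite("x_c", formula="C", compartment="c"))
        m.add_reaction(Reaction("EX_a", {"a_e": F(-1)}, -2, 0,
                                kind="exchange"))
        m.add_reaction(Reaction("MAKE", {"a_e": F(-1), "x_c": F(1)}, 0, 2))
        m.add_reaction(Reaction("DM", {"x_c": F(-1)}, 0, 2, kind="demand"))
        m.objective_id = "DM"
        return m

    @staticmethod
    def _sample_from_solution(model, solution):
        from hydrogem.lp import FluxSample

        rxn_ids = model.reaction_ids()
        row = np.array([[solution.fluxes[r] for r in rxn_ids]])
        return FluxSample(row, rxn_ids, seed=0, objective_fraction=1.0,
                          thinning=1)

    def test_single_producer_counts_coefficient_times_flux(self):
        m = self._tiny()
        sample = self._sample_from_solution(m, fba(m))
        assert compartment_production(sample, m, "x", "c") == pytest.approx(
            2.0, abs=1e-9)

    def test_reversible_reaction_running_backward_produces_other_side(self):
        m = self._tiny()
        # a reversible conversion forced backward becomes a producer of x_c
        m.add_metabolite(Metabolite("y_c", formula="C", compartment="c"))
        m.add_reaction(Reaction("REV", {"x_c": F(-1), "y_c": F(1)}, -1, -1))
        m.add_reaction(Reaction("YIN", {"y_c": F(1)}, 1, 1, kind="demand"))
        m.set_bounds("DM", 0, 3)
        sol = fba(m)
        sample = self._sample_from_solution(m, sol)
        # REV at flux -1 contributes +1 to x_c production
        prod = compartment_production(sample, m, "x", "c")
        assert prod == pytest.approx(sol.fluxes["MAKE"] + 1.0, abs=1e-9)

    def test_nad_production_shifts_to_hydrogenosome_under_bifurcation(
            self, base_model, bifurcating_model):
        results = compare_scenarios(
            build_default_model,
            {"base": ScenarioConfig(),
             "bif": ScenarioConfig(hydrogenase_mode="bifurcating")},
            n=300, seed=3,
        )
        base, bif = results
        assert bif.compartment_production[("nad", "h")] > \
            base.compartment_production[("nad", "h")] + 0.5
        # and the hydrogenosome overtakes none of the cytosolic share in
        # the base case
        assert base.compartment_production[("nad", "h")] < 0.1


class TestFormateRatio:
    def test_ratio_exactly_one_without_pfo(self, base_model):
        """Every acetyl-CoA co-produces one formate when PFL is the only
        route, so the secreted ratio is exactly 1 in any feasible
        solution."""
        m = base_model.copy()
        m.set_bounds("PFO_h", 0.0, 0.0)
        for seed in (1, 2):
            sample = sample_fluxes(m, n=50, seed=seed, warmup=200,
                                   thinning=10)
            stats = formate_ratio(sample)
            assert stats["min"] == pytest.approx(1.0, abs=1e-6)
            assert stats["max"] == pytest.approx(1.0, abs=1e-6)

    def test_pfo_flux_lowers_ratio_by_its_share(self, base_model):
        """With PFO flux f and PFL flux F the ratio is F/(F+f) < 1."""
        m = base_model.copy()
        m.set_bounds("PFO_h", 0.4, 0.4)
        sol = pfba(m)
        f_pfl = sol.fluxes["PFL"] + sol.fluxes["PFL_h"]
        expected = f_pfl / (f_pfl + 0.4)
        assert formate_ratio(sol)["ratio"] == pytest.approx(expected,
                                                            abs=1e-6)

    def test_h2_constraint_narrows_ratio_distribution(self, base_model):
        wide = formate_ratio(sample_fluxes(base_model, n=400, seed=5))
        h2 = [m for m in measured_fluxes() if m.product == "h2"]
        constrained_model = apply_measured_bounds(base_model, h2)
        narrow = formate_ratio(sample_fluxes(constrained_model, n=400,
                                             seed=6))
        assert narrow["max"] - narrow["min"] < wide["max"] - wide["min"]


class TestProtonModule:
    def test_atp_synthase_flux_stays_small(self, proton_model):
        """The hydrogenosomal ATP synthase supports only a small share of
        the glucose flux (mean over near-optimal samples)."""
        sample = sample_fluxes(proton_model, n=300, seed=8)
        glucose = -sample.column("EX_glc__D_e").mean()
        atps = sample.column("ATPS_h").mean()
        assert atps <= 0.05 * glucose


class TestConstraintSensitivity:
    def test_single_constraint_tightens_own_prediction(self, base_model):
        sens = constraint_sensitivity(base_model, measured_fluxes(),
                                      n=300, seed=4)
        assert sens.loc["ac", "ac"] < sens.loc["ac", "unconstrained"]

    def test_all_constraints_pin_errors_inside_interval_widths(
            self, base_model):
        """With all five products constrained at once, every constrained
        variable's error stays within its own measured-interval width and
        the overall mean error drops below the unconstrained value (the
        all-constrained polytope is nested in each single-constrained
        one)."""
        from hydrogem.hydrogenosome import SENSITIVITY_PRODUCTS

        meas = [m for m in measured_fluxes()
                if m.product in SENSITIVITY_PRODUCTS]
        unconstrained = sample_fluxes(base_model, n=300, seed=9)
        constrained_all = apply_measured_bounds(base_model, meas)
        sample = sample_fluxes(constrained_all, n=300, seed=9)
        errs_all, errs_un = [], []
        for m in meas:
            pred = sample.column(f"EX_{m.product}_e").mean()
            err = abs(pred - m.mean) / m.mean
            width = (m.upper_bound - m.lower_bound) / m.mean
            assert err <= width + 1e-9
            errs_all.append(err)
            pred_un = unconstrained.column(f"EX_{m.product}_e").mean()
            errs_un.append(abs(pred_un - m.mean) / m.mean)
        assert np.mean(errs_all) < np.mean(errs_un)

    def test_acetate_most_informative_carbon_constraint(self, base_model):
        """Among the measured carbon products, the acetate constraint
        yields the largest drop in mean prediction error."""
        sens = constraint_sensitivity(base_model, measured_fluxes(),
                                      n=2000, seed=1)
        reduction = mean_error_reduction(sens)
        carbon = ["ac", "etoh", "for", "lac__L"]
        assert reduction["ac"] == max(reduction[c] for c in carbon)
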