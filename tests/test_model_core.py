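from fractions import Fraction

import pytest

from hydrogem import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ScenarioConfig,
    build_default_model,
    check_balance,
    fba,
    set_sole_carbon_source,
)
from hydrogem.core.build import CARBON_SOURCE_EXCHANGES, build_core_model
from hydrogem.core.formula import FormulaError, parse_formula
from hydrogem.core.model import ModelError


class TestTypes:
    def test_metabolite_compartment_validation(self):
        with pytest.raises(ModelError):
            Metabolite("x_m", compartment="m")

    def test_reaction_bound_order(self):
        with pytest.raises(ModelError):
            Reaction("r", {}, lower_bound=1.0, upper_bound=0.0)

    def test_exchange_must_touch_one_extracellular_metabolite(self):
        m = MetabolicModel("t")
        m.add_metabolite(Metabolite("a_c", formula="C", compartment="c"))
        with pytest.raises(ModelError):
            m.add_reaction(
                Reaction("EX_a", {"a_c": Fraction(-1)}, kind="exchange"))

    def test_unknown_stoichiometry_key_rejected(self):
        m = MetabolicModel("t")
        with pytest.raises(ModelError):
            m.add_reaction(Reaction("r", {"ghost_c": Fraction(1)}))

    def test_scenario_config_validates_mode(self):
        with pytest.raises(ModelError):
            ScenarioConfig(hydrogenase_mode="magic")


class TestBalance:
    def test_core_model_fully_balanced(self, base_model):
        assert check_balance(base_model) == []

    def test_corrupted_reaction_reports_element_imbalance(self, model):
        # remove one water from enolase: 2pg -> pep (+ H2O dropped)
        rxn = model.reactions["ENO"]
        del rxn.stoichiometry["h2o_c"]
        violations = check_balance(model)
        by_elem = {(v.reaction_id, v.element): v.imbalance for v in violations}
        assert by_elem[("ENO", "O")] == -1
        assert by_elem[("ENO", "H")] == -2

    def test_exchange_reactions_exempt(self, model):
        # exchanges are massively "unbalanced" by construction yet silent
        assert all(v.reaction_id != "EX_glc__D_e"
                   for v in check_balance(model))

    def test_missing_formula_raises_naming_metabolite(self):
        m = MetabolicModel("t")
        m.add_metabolite(Metabolite("a_c", compartment="c"))
        m.add_metabolite(Metabolite("b_c", formula="C", compartment="c"))
        m.add_reaction(
            Reaction("r", {"a_c": Fraction(-1), "b_c": Fraction(1)}))
        with pytest.raises(FormulaError, match="a_c"):
            check_balance(m)


class TestScenarios:
    def test_base_scenario_reaction_set(self, base_model):
        r = base_model.reactions
        assert r["PFL_h"].upper_bound > 0
        assert r["PFO_h"].upper_bound > 0
        assert r["HYD_fd"].upper_bound > 0
        assert r["ASCT_h"].upper_bound > 0
        assert r["SUCOAS_h"].upper_bound > 0
        # hydrogen dehydrogenase is forward-only
        assert r["HYDD_h"].lower_bound == 0.0
        # speculative reactions carry zero flux in the base case
        for rid in ("HYD_bif", "CPLX12_h", "ATPS_h"):
            assert (r[rid].lower_bound, r[rid].upper_bound) == (0.0, 0.0)
            assert r[rid].speculative

    def test_bifurcating_replaces_ferredoxin_hydrogenase(self, bifurcating_model):
        r = bifurcating_model.reactions
        assert (r["HYD_fd"].lower_bound, r["HYD_fd"].upper_bound) == (0, 0)
        assert r["HYD_bif"].upper_bound > 0

    def test_reversible_hydrogen_dehydrogenase_flag(self):
        m = build_default_model(
            ScenarioConfig(hydrogen_dehydrogenase_reversible=True))
        assert m.reactions["HYDD_h"].lower_bound < 0

    def test_deleting_closed_speculative_reactions_preserves_optimum(
            self, base_model):
        mu = fba(base_model).objective_value
        pruned = base_model.copy()
        for rid in [r.id for r in pruned.reactions.values() if r.speculative]:
            pruned.remove_reaction(rid)
        assert fba(pruned).objective_value == pytest.approx(mu, abs=1e-9)


class TestSoleCarbonSource:
    def test_glucose_bound(self, base_model):
        m = set_sole_carbon_source(base_model, "glucose", 1.5)
        assert m.reactions["EX_glc__D_e"].lower_bound == -1.5
        # all other sugar uptakes closed
        assert m.reactions["EX_fru_e"].lower_bound == 0.0
        assert m.reactions["EX_cellb_e"].lower_bound == 0.0

    def test_cellobiose_scaled_to_glucose_carbon_equivalents(self, base_model):
        m = set_sole_carbon_source(base_model, "cellobiose", 1.5)
        assert m.reactions["EX_cellb_e"].lower_bound == pytest.approx(-0.75)

    def test_unknown_substrate_raises(self, base_model):
        with pytest.raises(ModelError):
            set_sole_carbon_source(base_model, "unknownose", 1.0)

    def test_vitamin_exchanges_untouched(self, base_model):
        m = set_sole_carbon_source(base_model, "xylose", 1.5)
        assert m.reactions["EX_btn_e"].lower_bound < 0


class TestInvariants:
    def test_base_model_supports_growth_at_measured_uptake(self, base_model):
        sol = fba(base_model)
        assert sol.optimal and sol.objective_value > 1e-3

    def test_all_carbon_closed_means_no_growth(self, base_model):
        m = base_model.copy()
        for rxn in m.exchanges():
            (met,) = rxn.stoichiometry
            if parse_formula(m.metabolites[met].formula).get("C", 0):
                m.set_bounds(rxn.id, 0.0, rxn.upper_bound)
        sol = fba(m)
        assert (not sol.optimal) or sol.objective_value < 1e-9

    def test_carbon_closure_of_optimal_solution(self, base_model):
        """Carbon uptake equals secreted carbon plus biomass carbon."""
        from hydrogem.lp import pfba

        sol = pfba(base_model)
        carbon_in = carbon_out = 0.0
        for rxn in base_model.exchanges():
            (met,) = rxn.stoichiometry
            n_c = parse_formula(base_model.metabolites[met].formula).get("C", 0)
            if not n_c:
                continue
            flux = sol.fluxes[rxn.id]
            if flux < 0:
                carbon_in += -flux * n_c
            else:
                carbon_out += flux * n_c
        biomass_carbon = _biomass_carbon(base_model) * sol.objective_value
        assert carbon_in == pytest.approx(carbon_out + biomass_carbon,
                                          abs=1e-6)

    def test_every_battery_substrate_has_an_exchange(self, base_model):
        for exchange_id in CARBON_SOURCE_EXCHANGES.values():
            assert exchange_id in base_model.reactions


def _biomass_carbon(model) -> float:
    """mmol carbon drained per unit biomass flux (independent audit)."""
    total = 0.0
    rxn = model.reactions["BIOMASS"]
    for met_id, coeff in rxn.stoichiometry.items():
        n_c = parse_formula(model.metabolites[met_id].formula).get("C", 0)
        total += -float(coeff) * n_c
    return total
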