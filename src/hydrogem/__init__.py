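"""hydrogem: constraint-based analysis of anaerobic gut-fungal metabolism.

A core-scale stoichiometric model of *Neocallimastix lanati* with an
explicit hydrogenosome, plus the analysis machinery around it: FBA/pFBA,
flux variability analysis, hit-and-run flux sampling, maintenance-energy
(GAM/NGAM) regression, substrate-utilization validation, hydrogenosome
scenario analysis, and a reduced EMU-based 13C labeling simulator/fitter.
"""

from .biomass import (
    BiomassComposition,
    MonomerDistribution,
    attach_maintenance,
    build_biomass_reaction,
    table2_composition,
)
from .core.build import (
    ScenarioConfig,
    apply_scenario,
    build_core_model,
    set_sole_carbon_source,
)
from .core.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    check_balance,
)
from .lp import (
    FluxRange,
    FluxSample,
    FluxSolution,
    MeasuredFlux,
    apply_measured_bounds,
    fba,
    fva,
    pfba,
    sample_fluxes,
)
from .maintenance import (
    GrowthExperiment,
    MaintenanceFit,
    compute_specific_fluxes,
    fit_maintenance,
    max_atp_yield,
)
from .synth import GeneratorSpec, generate_flux_measurements, generate_growth_experiments, generate_mids
from .validation import (
    ConfusionMatrix,
    UtilizationTest,
    predict_carbon_growth,
    predict_vitamin_essentiality,
    run_battery,
    score_predictions,
)

__version__ = "0.1.0"


def build_default_model(config: ScenarioConfig | None = None,
                        gam: float = 75.98, ngam: float = 2.27):
    """Base-case model with the measured-composition biomass and maintenance.

    Convenience wrapper: compiles the biomass reaction from the measured
    macromolecular composition with the fitted GAM/NGAM, builds the core
    network under ``config`` and attaches the NGAM floor.
    """
    comp = table2_composition(gam=gam, ngam=ngam)
    biomass = build_biomass_reaction(comp)
    model = build_core_model(config or ScenarioConfig(), biomass)
    attach_maintenance(model, comp)
    return model
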