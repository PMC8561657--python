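"""Scenario analyses of hydrogenosomal energy metabolism.

Hydrogenase-mode comparison (ferredoxin vs bifurcating vs proton-pumping
module), compartment-wise gross production of NAD+ and ATP over flux
samples, formate:(acetate+ethanol) ratio distributions, H2 flux ranges,
and the sensitivity of prediction error to individual measured-flux
constraints.

"Production" follows gross semantics: for each reaction term the
contribution ``coefficient x flux`` counts when positive (a reversible
reaction running backward produces the other side), with no netting
against consumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .core.build import ScenarioConfig
from .core.model import MetabolicModel
from .lp import FluxSample, FluxSolution, MeasuredFlux, apply_measured_bounds, fba, sample_fluxes


@dataclass
class ScenarioResult:
    """One scenario's growth rate, sampled production summary and H2 range."""

    label: str
    growth_rate: float
    #: (metabolite stem, compartment) -> mean gross production flux
    compartment_production: Dict[Tuple[str, str], float]
    h2_flux_range: Tuple[float, float]
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metabolite": met, "compartment": comp, "mean_production": v}
            for (met, comp), v in self.compartment_production.items()
        ]
        df = pd.DataFrame(rows)
        df["scenario"] = self.label
        return df


def compartment_production(
    sample: FluxSample,
    model: MetabolicModel,
    metabolite: str,
    compartment: str,
) -> float:
    """Mean gross production flux of ``metabolite`` in ``compartment``.

    Per sample, sums ``coefficient x flux`` over all reaction terms that
    produce the metabolite (positive contributions only); returns the mean
    over samples.
    """
    met_id = f"{metabolite}_{compartment}"
    if met_id not in model.metabolites:
        raise KeyError(f"no metabolite {met_id} in model")
    contributions = np.zeros(sample.n_samples)
    for rid, rxn in model.reactions.items():
        coeff = rxn.stoichiometry.get(met_id)
        if coeff is None or rid not in sample.reaction_ids:
            continue
        term = float(coeff) * sample.column(rid)
        contributions += np.maximum(term, 0.0)
    return float(contributions.mean())


def formate_ratio(solution_or_sample) -> Dict[str, float]:
    """Molar ratio of secreted formate to acetate + ethanol.

    Accepts a :class:`FluxSolution` (single ratio) or a
    :class:`FluxSample` (distribution summary).  When PFL is the only
    acetyl-CoA source the ratio is exactly 1; PFO flux pushes it below 1.
    """
    if isinstance(solution_or_sample, FluxSolution):
        f = solution_or_sample["EX_for_e"]
        denom = solution_or_sample["EX_ac_e"] + solution_or_sample["EX_etoh_e"]
        ratio = f / denom if denom else float("nan")
        return {"ratio": ratio}
    sample: FluxSample = solution_or_sample
    f = sample.column("EX_for_e")
    denom = sample.column("EX_ac_e") + sample.column("EX_etoh_e")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(denom > 0, f / denom, np.nan)
    ratios = ratios[np.isfinite(ratios)]
    return {
        "mean": float(np.mean(ratios)),
        "median": float(np.median(ratios)),
        "min": float(np.min(ratios)),
        "max": float(np.max(ratios)),
        "q05": float(np.percentile(ratios, 5)),
        "q95": float(np.percentile(ratios, 95)),
    }


#: default production summary targets of the scenario comparison
_PRODUCTION_TARGETS = (("nad", "c"), ("nad", "h"), ("atp", "c"), ("atp", "h"))


def compare_scenarios(
    model_builder: Callable[[ScenarioConfig], MetabolicModel],
    configs: Mapping[str, ScenarioConfig],
    n: int = 2000,
    objective_fraction: float = 0.9,
    seed: int = 0,
    targets: Sequence[Tuple[str, str]] = _PRODUCTION_TARGETS,
) -> List[ScenarioResult]:
    """Rebuild, solve and sample the model under each named configuration.

    Each scenario gets a deterministic sub-seed derived from ``seed`` and
    its position, so scenario results are independent of one another.
    """
    results: List[ScenarioResult] = []
    for i, (label, config) in enumerate(configs.items()):
        model = model_builder(config)
        sol = fba(model)
        if not sol.optimal:
            raise RuntimeError(f"scenario {label}: FBA {sol.status}")
        sample = sample_fluxes(
            model, n=n, objective_fraction=objective_fraction,
            seed=(seed * 1009 + i) % (2**31),
        )
        production = {
            (met, comp): compartment_production(sample, model, met, comp)
            for met, comp in targets
        }
        h2 = sample.column("EX_h2_e")
        results.append(
            ScenarioResult(
                label=label,
                growth_rate=sol.objective_value,
                compartment_production=production,
                h2_flux_range=(float(h2.min()), float(h2.max())),
                n_samples=n,
            )
        )
    return results


#: the five measured fermentation products of the sensitivity analysis
SENSITIVITY_PRODUCTS = ("ac", "etoh", "for", "h2", "lac__L")


def constraint_sensitivity(
    model: MetabolicModel,
    measurements: Sequence[MeasuredFlux],
    n: int = 2000,
    objective_fraction: float = 0.9,
    seed: int = 0,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Absolute relative prediction error under single-product constraints.

    For each measured product, only that product's exchange is bounded to
    its measured interval; the constrained model is sampled at the given
    objective fraction and the aggregated predicted secretion of every
    measured product is compared with its measured mean:
    ``|predicted - mean| / mean``.

    Returns a DataFrame indexed by predicted product with one column per
    constrained product (plus ``unconstrained``).
    """
    agg = {"mean": np.mean, "median": np.median}[aggregator]
    by_product = {
        m.product: m for m in measurements
        if m.product in SENSITIVITY_PRODUCTS
    }
    table: Dict[str, Dict[str, float]] = {}

    def _errors(constrained_label: str, constrained_model, sub_seed: int):
        sample = sample_fluxes(
            constrained_model, n=n, objective_fraction=objective_fraction,
            seed=sub_seed,
        )
        col: Dict[str, float] = {}
        for prod, meas in by_product.items():
            pred = float(agg(sample.column(f"EX_{prod}_e")))
            col[prod] = abs(pred - meas.mean) / meas.mean
        table[constrained_label] = col

    _errors("unconstrained", model, seed % (2**31))
    for i, prod in enumerate(by_product):
        constrained = apply_measured_bounds(model, [by_product[prod]])
        _errors(prod, constrained, (seed * 7919 + i + 1) % (2**31))
    df = pd.DataFrame(table)
    df.index.name = "predicted_product"
    return df


def mean_error_reduction(sensitivity: pd.DataFrame) -> pd.Series:
    """Drop in mean absolute relative error vs the unconstrained model,
    per single-product constraint (largest = most informative)."""
    base = sensitivity["unconstrained"].mean()
    reductions = {
        col: base - sensitivity[col].mean()
        for col in sensitivity.columns
        if col != "unconstrained"
    }
    return pd.Series(reductions).sort_values(ascending=False)
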