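"""Synthetic datasets for exercising every pipeline stage without downloads.

Three generators:

* cellobiose-gradient growth experiments (for maintenance fitting), built
  as the exact inverse of the fitting procedure: for each substrate level a
  growth rate follows a saturating (Monod-like) curve, the implied
  maintenance ATP budget is converted into a redox-consistent mixed-acid
  fermentation profile on the model's route stoichiometry, and the profile
  is turned back into concentration/dry-mass time series with
  multiplicative lognormal noise on the measured concentrations;
* measured-flux tables with the structure of the printed secretion-rate
  table (replicate draws from a truncated normal; bounds are the observed
  replicate range);
* steady-state mass-isotopomer distributions under a [1,2-13C]glucose
  tracer with additive, renormalized Gaussian noise.

Identical generator specifications produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .core.model import MetabolicModel, ModelError
from .lp import MeasuredFlux
from .maintenance import MM_CELLOBIOSE, GrowthExperiment

#: products whose liquid-phase concentrations are "measured"
LIQUID_PRODUCTS = ("succ", "lac__L", "etoh", "for", "ac")


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic growth experiments."""

    seed: int = 0
    noise_cv: float = 0.05
    n_replicates: int = 3
    substrate_levels: Tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    #: ground truth maintenance parameters (the fitted values)
    gam: float = 75.98
    ngam: float = 2.27
    #: Monod-like growth-rate curve mu(L) = mu_max * L / (K + L); the
    #: defaults put the 5 g/L culture at the observed exponential-phase
    #: growth rate (~0.044 /h)
    mu_max: float = 0.07
    monod_k: float = 3.0
    #: culture geometry
    volume: float = 0.01  # L
    initial_dry_mass: float = 5e-4  # g
    sampling_interval: float = 24.0  # h

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ModelError("noise_cv must be nonnegative")
        if len(set(self.substrate_levels)) != len(self.substrate_levels):
            raise ModelError("substrate levels must be distinct")
        if any(l <= 0 for l in self.substrate_levels):
            raise ModelError("substrate levels must be positive")

    def growth_rate(self, level: float) -> float:
        return self.mu_max * level / (self.monod_k + level)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _replicate_mean_factor(rng: np.random.Generator, cv: float, n: int) -> float:
    """Mean of n replicate lognormal measurement factors (triplicate tubes
    are measured independently and averaged before the fit)."""
    if cv == 0:
        return 1.0
    return float(np.mean(_lognormal_factor(rng, cv, size=n)))


#: relative route activities of the synthetic cultures (lactate, ethanol,
#: succinate, acetate-via-PFO), mirroring the measured mixed-acid product
#: proportions of exponential-phase cultures
_ROUTE_SHAPE = {"lactate": 0.87, "ethanol": 0.66, "succinate": 0.03,
                "pfo": 0.10}


def _fermentation_profile(
    model: MetabolicModel, atp_budget: float
) -> Dict[str, float]:
    """Redox- and carbon-consistent mixed-acid fermentation profile
    delivering a fixed maintenance ATP flux at zero growth.

    Constructed analytically on the model's route stoichiometry (PPi-linked
    glycolysis yields 1.5 ATP + 1 NADH per pyruvate; the hydrogenosomal
    acetate route adds 1 ATP; ethanol disposes 2 NADH per pyruvate, lactate
    1, the reductive succinate branch 1 net): the route mix keeps the
    measured product proportions, the PFL acetate route closes the redox
    balance, and the whole profile is scaled to the ATP budget.  The fit
    procedure's max-ATP solve reproduces the budget exactly on noiseless
    output (audited by tests against the LP).
    """
    l = _ROUTE_SHAPE["lactate"]
    e = _ROUTE_SHAPE["ethanol"]
    s = _ROUTE_SHAPE["succinate"]
    a_o = _ROUTE_SHAPE["pfo"]
    a_f = e + s - a_o  # acetate via PFL closes the NADH balance
    if a_f < 0:
        raise ModelError("route shape is redox-infeasible (PFO too large)")
    pyr = l + e + a_f + a_o
    atp_unit = 1.5 * pyr + (a_f + a_o) + 1.5 * s
    k = atp_budget / atp_unit
    glc = (pyr + s) / 2.0
    return {
        "lac__L": l * k,
        "etoh": e * k,
        "for": (e + a_f) * k,
        "ac": (a_f + a_o) * k,
        "succ": s * k,
        "h2": a_o * k,
        "cellb": -glc * k / 2.0,
    }


def generate_growth_experiments(
    model: MetabolicModel, spec: GeneratorSpec
) -> List[GrowthExperiment]:
    """Synthetic cellobiose-gradient cultures (one per substrate level),
    sampled twice 24 h apart, consistent with the ground-truth GAM/NGAM."""
    rng = np.random.default_rng(spec.seed)
    experiments: List[GrowthExperiment] = []
    for level in spec.substrate_levels:
        mu = spec.growth_rate(level)
        atp_budget = spec.gam * mu + spec.ngam
        profile = _fermentation_profile(model, atp_budget)

        t0, t1 = 0.0, spec.sampling_interval
        m0 = spec.initial_dry_mass
        m1 = m0 * float(np.exp(mu * (t1 - t0)))
        dmass = m1 - m0
        denom = (t1 - t0) * dmass

        # multiplicative lognormal noise on the measured concentrations;
        # each level is a triplicate set, so the noise of the averaged
        # measurement is the mean of n_replicates factors
        conc: Dict[str, Tuple[float, float]] = {}
        for stem in LIQUID_PRODUCTS:
            c1 = profile[stem] * denom / spec.volume  # mM accumulated
            f1 = _replicate_mean_factor(rng, spec.noise_cv, spec.n_replicates)
            conc[stem] = (0.0, float(c1 * f1))
        c_cellb0 = level / MM_CELLOBIOSE * 1000.0  # g/L -> mM
        c_cellb1 = c_cellb0 + profile["cellb"] * denom / spec.volume
        if c_cellb1 < 0:
            raise ModelError(
                f"substrate level {level} g/L exhausted before the second "
                "sampling; increase the level or shrink the inoculum"
            )
        conc["cellb"] = (
            float(c_cellb0
                  * _replicate_mean_factor(rng, spec.noise_cv,
                                           spec.n_replicates)),
            float(c_cellb1
                  * _replicate_mean_factor(rng, spec.noise_cv,
                                           spec.n_replicates)),
        )
        h2_1 = profile["h2"] * denom
        headspace = (
            0.0,
            float(h2_1 * _replicate_mean_factor(rng, spec.noise_cv,
                                                spec.n_replicates)),
        )
        # dry masses and the pressure-derived growth rate are carried as
        # given: the growth rate comes from a curve fit over many pressure
        # readings and the masses are extrapolated through it
        mu_obs = mu
        masses = (m0, m1)
        experiments.append(
            GrowthExperiment(
                substrate_level=level,
                timepoints=(t0, t1),
                metabolite_concentrations=conc,
                headspace_h2=headspace,
                dry_mass=masses,
                growth_rate=mu_obs,
            )
        )
    return experiments


def generate_flux_measurements(
    means: Mapping[str, float],
    sds: Mapping[str, float],
    spec: GeneratorSpec,
) -> List[MeasuredFlux]:
    """Replicate secretion rates drawn from truncated normals.

    ``lower_bound``/``upper_bound`` are the min/max of the replicate draws,
    mirroring the observed-range semantics of the printed flux table.
    """
    from scipy import stats

    rng = np.random.default_rng(spec.seed)
    out: List[MeasuredFlux] = []
    for product, mean in means.items():
        sd = sds[product]
        if sd == 0:
            out.append(MeasuredFlux(product, mean, 0.0, mean, mean))
            continue
        a = (0.0 - mean) / sd  # truncate at zero: rates are nonnegative
        draws = stats.truncnorm.rvs(
            a, np.inf, loc=mean, scale=sd, size=spec.n_replicates,
            random_state=rng,
        )
        out.append(
            MeasuredFlux(
                product,
                float(np.mean(draws)),
                float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0,
                float(np.min(draws)),
                float(np.max(draws)),
            )
        )
    return out


def generate_mids(
    emu_network,
    fluxes: Mapping[str, float],
    tracer: Optional[Mapping] = None,
    spec: Optional[GeneratorSpec] = None,
):
    """Simulated steady-state MIDs with additive renormalized noise.

    Returns a dict ``emu -> (mid_vector, se_vector)`` averaged over
    ``spec.n_replicates`` noisy replicates.
    """
    from .mfa.emu import simulate_mids

    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    clean = simulate_mids(emu_network, fluxes, tracer=tracer)
    noisy: Dict = {}
    #: absolute noise floor on a mass channel, mol fraction
    floor = 5e-4
    for emu, mid in clean.items():
        reps = []
        for _ in range(spec.n_replicates):
            x = np.asarray(mid, dtype=float)
            if spec.noise_cv > 0:
                sd = spec.noise_cv * x + floor
                x = x + rng.normal(0.0, 1.0, size=x.shape) * sd
                x = np.clip(x, 0.0, None)
                total = x.sum()
                x = x / total if total > 0 else np.asarray(mid, dtype=float)
            reps.append(x)
        reps = np.array(reps)
        mean = reps.mean(axis=0)
        se = (reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
              if len(reps) > 1 else spec.noise_cv * mean + floor)
        se = np.maximum(se, floor)
        noisy[emu] = (mean, se)
    return noisy
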