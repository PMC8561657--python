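import numpy as np
import pytest

from hydrogem import GeneratorSpec, generate_flux_measurements, generate_growth_experiments
from hydrogem.core.model import ModelError
from hydrogem.datasets import measured_flux_frame
from hydrogem.mfa import central_carbon_network, emu_decompose
from hydrogem.mfa.emu import target_mids
from hydrogem.mfa.networks import DEFAULT_FRAGMENTS, CentralFluxParametrization
from hydrogem.synth import generate_mids


class TestSpec:
    def test_levels_must_be_distinct_and_positive(self):
        with pytest.raises(ModelError):
            GeneratorSpec(substrate_levels=(1.0, 1.0))
        with pytest.raises(ModelError):
            GeneratorSpec(substrate_levels=(0.0, 1.0))

    def test_growth_rate_monotone_in_level(self):
        spec = GeneratorSpec()
        mus = [spec.growth_rate(l) for l in spec.substrate_levels]
        assert all(b > a for a, b in zip(mus, mus[1:]))


class TestGrowthExperiments:
    def test_deterministic_given_spec(self, base_model):
        a = generate_growth_experiments(base_model, GeneratorSpec(seed=5))
        b = generate_growth_experiments(base_model, GeneratorSpec(seed=5))
        assert repr(a) == repr(b)

    def test_outputs_physically_sensible(self, base_model):
        for e in generate_growth_experiments(base_model,
                                             GeneratorSpec(seed=2)):
            assert e.dry_mass[1] > e.dry_mass[0] > 0
            assert e.growth_rate > 0
            assert all(c1 >= 0 for _, c1 in
                       e.metabolite_concentrations.values())
            t0, t1 = e.timepoints
            assert t1 - t0 == pytest.approx(24.0)

    def test_substrate_never_exhausted(self, base_model):
        for e in generate_growth_experiments(base_model,
                                             GeneratorSpec(seed=3)):
            c0, c1 = e.metabolite_concentrations["cellb"]
            assert 0 < c1 < c0


class TestFluxMeasurements:
    def test_zero_sd_collapses_bounds_to_mean(self):
        out = generate_flux_measurements({"ac": 0.56}, {"ac": 0.0},
                                         GeneratorSpec(seed=1))
        (m,) = out
        assert m.lower_bound == m.mean == m.upper_bound == 0.56

    def test_all_outputs_nonnegative(self):
        # succinate's small mean/sd ratio would go negative untruncated
        out = generate_flux_measurements(
            {"succ": 0.03}, {"succ": 0.06},
            GeneratorSpec(seed=0, n_replicates=200))
        (m,) = out
        assert m.lower_bound >= 0.0

    def test_generated_intervals_overlap_printed_ranges(self):
        """Feeding the printed means/SDs back through the generator yields
        intervals overlapping the printed [lb, ub] for all six products in
        nearly every seed."""
        df = measured_flux_frame()
        means = dict(zip(df["metabolite"], df["mean"]))
        sds = dict(zip(df["metabolite"], df["sd"]))
        printed = {row["metabolite"]: (row["lower_bound"], row["upper_bound"])
                   for _, row in df.iterrows()}
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            out = generate_flux_measurements(means, sds,
                                             GeneratorSpec(seed=seed))
            ok = all(
                m.lower_bound <= printed[p][1] and
                m.upper_bound >= printed[p][0]
                for m, p in zip(out, means)
            )
            hits += ok
        assert hits / n_seeds >= 0.95


@pytest.fixture(scope="module")
def emu_setup():
    par = CentralFluxParametrization()
    emu_net = emu_decompose(central_carbon_network(),
                            list(DEFAULT_FRAGMENTS))
    fluxes = par.to_fluxes((12.0, 0.2, 6.0))
    return emu_net, fluxes


class TestMids:
    def test_zero_noise_equals_simulation(self, emu_setup):
        emu_net, fluxes = emu_setup
        out = generate_mids(emu_net, fluxes,
                            spec=GeneratorSpec(seed=1, noise_cv=0.0))
        clean = target_mids(emu_net, fluxes)
        for t, (mid, se) in out.items():
            if t in clean:
                assert np.allclose(mid, clean[t])

    def test_reproducible_given_seed(self, emu_setup):
        emu_net, fluxes = emu_setup
        a = generate_mids(emu_net, fluxes, spec=GeneratorSpec(seed=7))
        b = generate_mids(emu_net, fluxes, spec=GeneratorSpec(seed=7))
        for t in a:
            assert np.array_equal(a[t][0], b[t][0])
            assert np.array_equal(a[t][1], b[t][1])

    def test_noisy_mids_remain_normalized(self, emu_setup):
        emu_net, fluxes = emu_setup
        out = generate_mids(emu_net, fluxes,
                            spec=GeneratorSpec(seed=2, noise_cv=0.05))
        for mid, se in out.values():
            assert mid.sum() == pytest.approx(1.0, abs=1e-9)
            assert (mid >= 0).all() and (se > 0).all()
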