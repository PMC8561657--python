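import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydrogem.mfa import (
    EMU,
    AtomMapNetwork,
    AtomMapReaction,
    CentralFluxParametrization,
    central_carbon_network,
    emu_decompose,
    mids_via_isotopomers,
    simulate_mids,
    toy_branch,
    toy_cleavage,
    toy_linear,
    tracer_mid,
    unlabeled_mid,
)
from hydrogem.mfa.atommap import AtomMapError
from hydrogem.mfa.emu import target_mids
from hydrogem.mfa.networks import DEFAULT_FRAGMENTS


class TestAtomMaps:
    def test_product_letter_must_have_origin(self):
        with pytest.raises(AtomMapError):
            AtomMapReaction("r", (("A", "ab"),), (("B", "ax"),))

    def test_carbon_conservation_enforced(self):
        with pytest.raises(AtomMapError):
            AtomMapReaction("r", (("A", "abc"),), (("B", "ab"),))

    def test_flux_balance_checker_flags_imbalance(self):
        net = toy_linear()
        with pytest.raises(AtomMapError, match="steady state"):
            net.check_flux_balance({"v1": 1.0, "v2": 0.5})


class TestDecomposition:
    def test_linear_transfer_chain(self):
        """Identity-mapped chain: B[1,2] is fed by A[1,2] alone."""
        net = toy_linear()
        emu_net = emu_decompose(net, [EMU("B", (1, 2))])
        (term,) = emu_net.production[EMU("B", (1, 2))]
        assert term.sources == (EMU("A", (1, 2)),)

    def test_cleavage_and_condensation_reach_isotopomer_minimal_set(self):
        """Every EMU the decomposition emits is required: dropping any one
        breaks the simulation (brute-force-checked minimality proxy), and
        the simulated targets equal the exhaustive-isotopomer result."""
        net = toy_cleavage()
        targets = [EMU("D", (1, 2, 3, 4))]
        emu_net = emu_decompose(net, targets)
        fluxes = {"split": 1.0, "join": 1.0, "b_in": 0.5, "b_out": 0.5}
        mids = simulate_mids(emu_net, fluxes)
        oracle = mids_via_isotopomers(net, fluxes, targets)
        assert np.allclose(mids[EMU("D", (1, 2, 3, 4))],
                           oracle[EMU("D", (1, 2, 3, 4))], atol=1e-12)
        # condensation appears as a convolution term
        (term,) = emu_net.production[EMU("D", (1, 2, 3, 4))]
        assert len(term.sources) == 2

    def test_central_network_sizes_bounded_by_substrate(self):
        emu_net = emu_decompose(central_carbon_network(),
                                list(DEFAULT_FRAGMENTS))
        assert max(e.size for e in emu_net.production) <= 6


class TestSimulation:
    @pytest.mark.parametrize(
        "factory,targets,fluxes",
        [
            (toy_linear, [EMU("C", (1, 2)), EMU("B", (2,))],
             {"v1": 1.0, "v2": 1.0}),
            (toy_cleavage,
             [EMU("D", (1, 2, 3, 4)), EMU("D", (2, 3)), EMU("B", (1, 2))],
             {"split": 1.0, "join": 1.0, "b_in": 0.5, "b_out": 0.5}),
            (toy_branch, [EMU("X", (1, 2, 3)), EMU("P", (1, 3))],
             {"u": 1.0, "d1": 1.0, "d2": 0.6, "back": 0.6}),
        ],
    )
    def test_emu_equals_brute_force_isotopomer_enumeration(
            self, factory, targets, fluxes):
        net = factory()
        mids = simulate_mids(emu_decompose(net, targets), fluxes)
        oracle = mids_via_isotopomers(net, fluxes, targets)
        for t in targets:
            assert np.abs(mids[t] - oracle[t]).max() < 1e-10

    def test_central_network_matches_isotopomer_oracle(self):
        """The full reduced network agrees with the exhaustive simulator
        on a pyruvate fragment (dual-route check at realistic fluxes)."""
        net = central_carbon_network()
        fluxes = CentralFluxParametrization().to_fluxes((12.0, 0.2, 6.0))
        targets = [EMU("PYR", (1, 2, 3)), EMU("ACE", (1, 2)),
                   EMU("FOR", (1,))]
        mids = simulate_mids(emu_decompose(net, targets), fluxes)
        oracle = mids_via_isotopomers(net, fluxes, targets)
        for t in targets:
            assert np.abs(mids[t] - oracle[t]).max() < 1e-8

    def test_unlabeled_tracer_gives_all_m0(self):
        net = toy_branch()
        emu_net = emu_decompose(net, [EMU("X", (1, 2, 3))])
        mids = simulate_mids(emu_net, {"u": 1.0, "d1": 1.0},
                             tracer={"S": unlabeled_mid})
        for mid in mids.values():
            assert mid[0] == pytest.approx(1.0)
            assert np.abs(mid[1:]).max() < 1e-12

    def test_straight_chain_conserves_tracer_mid(self):
        net = toy_linear()
        emu_net = emu_decompose(net, [EMU("C", (1, 2))])
        mids = simulate_mids(emu_net, {"v1": 2.0, "v2": 2.0})
        assert np.allclose(mids[EMU("C", (1, 2))], tracer_mid([1])((1, 2)))

    def test_zero_dilution_raises_naming_emu(self):
        net = toy_linear()
        emu_net = emu_decompose(net, [EMU("C", (1, 2))])
        with pytest.raises(AtomMapError, match=r"C\[1,2\]"):
            simulate_mids(emu_net, {"v1": 1.0, "v2": 0.0},
                          check_balance=False)

    @given(st.integers(0, 2**31 - 1))
    def test_mid_normalization_preserved(self, seed):
        """Simulated MIDs sum to 1 for arbitrary feasible flux draws."""
        rng = np.random.default_rng(seed)
        theta = (
            float(rng.uniform(2.5, 30.0)),
            float(rng.uniform(0.0, 0.9)),
            float(rng.uniform(0.0, 12.0)),
        )
        par = CentralFluxParametrization()
        net = central_carbon_network()
        emu_net = emu_decompose(net, list(DEFAULT_FRAGMENTS))
        mids = target_mids(emu_net, par.to_fluxes(theta))
        for mid in mids.values():
            assert abs(mid.sum() - 1.0) < 1e-9
            assert (mid >= -1e-12).all()
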