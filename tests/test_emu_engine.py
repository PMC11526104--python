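import itertools

import numpy as np
import pytest

from tcellflux.emu_engine import (
    EMU,
    EMUSimulationError,
    TracerSpec,
    brute_force_isotopomer_mids,
    emu_decompose,
    simulate_mids,
    system_to_dot,
)
from tcellflux.network_model import FluxState, parse_model
from tcellflux.synthetic_data import PRESETS

from conftest import (
    chain_flux,
    condensation_flux,
    cycle_flux,
    two_carbon_tracer,
)


def oracle_vs_emu(model, flux, tracer, targets):
    """Max componentwise deviation between the two simulation routes."""
    system = emu_decompose(model, targets)
    emu_mids = simulate_mids(system, flux, tracer)
    bf = brute_force_isotopomer_mids(model, flux, tracer)
    return max(
        np.abs(emu_mids[e] - bf[e.metabolite]).max() for e in targets
    )


class TestTracerSpec:
    def test_default_is_75pct_u13c_glucose(self):
        t = TracerSpec()
        assert t.metabolite == "GLC.x"
        assert dict(t.components) == {"111111": 0.75, "000000": 0.25}

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            TracerSpec(components=(("111111", 0.5), ("000000", 0.4)))

    def test_purity_bounds(self):
        with pytest.raises(ValueError, match="purity"):
            TracerSpec(purity=0.0)

    def test_emu_mid_pure_tracer(self):
        t = TracerSpec(components=(("111111", 1.0),), purity=1.0)
        assert np.allclose(t.emu_mid((1, 2, 3)), [0, 0, 0, 1])

    def test_emu_mid_purity_binomial(self):
        t = TracerSpec(components=(("11", 1.0),), purity=0.9)
        np.testing.assert_allclose(t.emu_mid((1, 2)), [0.01, 0.18, 0.81])


class TestDecomposition:
    def test_chain_single_level(self, chain_model):
        system = emu_decompose(chain_model, [EMU("C.c", (1, 2))])
        unknowns = [e for lv in system.levels for e in lv]
        assert EMU("C.c", (1, 2)) in unknowns
        assert EMU("B.c", (1, 2)) in unknowns
        assert len(system.levels) == 1  # only size-2 EMUs needed

    def test_condensation_pulls_convolution_inputs(self, condensation_model):
        target = EMU("C.c", (1, 2, 3, 4))
        system = emu_decompose(condensation_model, [target])
        prods = system.producers[target]
        assert any(len(er.sources) == 2 for er in prods)
        sizes = sorted(lv[0].size for lv in system.levels)
        assert sizes == sorted(set(sizes))

    def test_emu_count_below_isotopomer_count(self, builtin_model, fragment_library):
        targets = sorted(
            {EMU(f.metabolite, f.atoms) for f in fragment_library.values()}
        )
        system = emu_decompose(builtin_model, targets)
        total_isotopomers = sum(
            2 ** m.n_carbons
            for m in builtin_model.metabolites.values()
            if m.balanced
        )
        assert system.n_unknowns < total_isotopomers

    def test_unknown_target_rejected(self, chain_model):
        with pytest.raises(EMUSimulationError, match="unknown metabolite"):
            emu_decompose(chain_model, [EMU("Z.c", (1,))])

    def test_dot_export(self, cycle_model):
        system = emu_decompose(cycle_model, [EMU("P.obs", (1, 2))])
        dot = system_to_dot(system)
        assert dot.startswith("digraph")
        assert "mix" in dot


class TestSimulation:
    def test_unlabeled_tracer_gives_all_m0(self, cycle_model):
        tracer = two_carbon_tracer(frac_labeled=0.0, purity=1.0)
        targets = [EMU("P.obs", (1, 2)), EMU("M.m", (1, 2, 3))]
        system = emu_decompose(cycle_model, targets)
        mids = simulate_mids(system, cycle_flux(), tracer)
        for e in targets:
            assert np.allclose(mids[e], np.eye(e.size + 1)[0], atol=1e-12)

    def test_pure_tracer_linear_chain_fully_labeled(self, chain_model):
        tracer = two_carbon_tracer(frac_labeled=1.0, purity=1.0)
        target = EMU("C.c", (1, 2))
        system = emu_decompose(chain_model, [target])
        mids = simulate_mids(system, chain_flux(), tracer)
        np.testing.assert_allclose(mids[target], [0, 0, 1], atol=1e-12)

    def test_pure_tracer_glycolysis_pyruvate_m3(self, builtin_model):
        tracer = TracerSpec(components=(("111111", 1.0),), purity=1.0)
        state = FluxState(
            dict(PRESETS["WT-like"]["net"]),
            dict(PRESETS["WT-like"]["exchange"]),
            dict(PRESETS["WT-like"]["mixing"]),
        )
        # remove dilution so every pyruvate carbon derives from glucose
        state.net["pyrx"] = 0.0
        state.net["ldh"] += 10.0
        state.exchange["pyrx"] = 0.0
        target = EMU("PYR.c", (1, 2, 3))
        system = emu_decompose(builtin_model, [target])
        mids = simulate_mids(system, state, tracer)
        np.testing.assert_allclose(mids[target], [0, 0, 0, 1], atol=1e-9)

    def test_mid_normalization_random_fluxes(self, cycle_model):
        rng = np.random.default_rng(123)
        tracer = two_carbon_tracer()
        targets = [
            EMU("P.obs", (1, 2)),
            EMU("M.m", (1, 2, 3)),
            EMU("G.m", (1, 2)),
            EMU("C1.m", (1,)),
        ]
        system = emu_decompose(cycle_model, targets)
        for _ in range(100):
            flux = cycle_flux(
                upt=rng.uniform(0.1, 50),
                co2d=rng.uniform(0.01, 20),
                exch=rng.uniform(0, 30),
                mix=rng.uniform(0, 1),
            )
            mids = simulate_mids(system, flux, tracer)
            for e in targets:
                mid = mids[e]
                assert abs(mid.sum() - 1.0) <= 1e-10
                assert (mid >= -1e-12).all()

    def test_mixing_endpoints(self, cycle_model):
        tracer = two_carbon_tracer()
        obs = EMU("P.obs", (1, 2))
        pc, pm = EMU("P.c", (1, 2)), EMU("P.m", (1, 2))
        system = emu_decompose(cycle_model, [obs, pc, pm])
        at1 = simulate_mids(system, cycle_flux(mix=1.0), tracer)
        np.testing.assert_array_equal(at1[obs], at1[pc])
        at0 = simulate_mids(system, cycle_flux(mix=0.0), tracer)
        np.testing.assert_array_equal(at0[obs], at0[pm])

    def test_co2_dilution_monotonicity(self, cycle_model):
        """More unlabeled CO2 inflow never increases labeled mass of the
        carboxylation product M."""
        tracer = two_carbon_tracer()
        target = EMU("M.m", (1, 2, 3))
        system = emu_decompose(cycle_model, [target])
        labeled_mass = []
        for co2d in [0.01, 0.1, 1.0, 5.0, 20.0, 100.0]:
            mids = simulate_mids(system, cycle_flux(co2d=co2d), tracer)
            labeled_mass.append(1.0 - mids[target][0])
        assert all(a >= b - 1e-12 for a, b in zip(labeled_mass, labeled_mass[1:]))

    def test_convolution_property(self, condensation_model):
        """Condensation product MID equals the convolution of its part MIDs
        when each part has a single producing pathway."""
        tracer = two_carbon_tracer()
        c = EMU("C.c", (1, 2, 3, 4))
        b = EMU("B.c", (1, 2))
        system = emu_decompose(condensation_model, [c, b])
        mids = simulate_mids(system, condensation_flux(), tracer)
        np.testing.assert_allclose(
            mids[c], np.convolve(mids[b], mids[b]), atol=1e-12
        )

    def test_missing_mixing_fraction_raises(self, cycle_model):
        tracer = two_carbon_tracer()
        system = emu_decompose(cycle_model, [EMU("P.obs", (1, 2))])
        flux = cycle_flux()
        flux.mixing = {}
        with pytest.raises(EMUSimulationError, match="mixing fraction"):
            simulate_mids(system, flux, tracer)


class TestBruteForceOracle:
    def test_single_pool_equals_tracer(self, chain_model):
        tracer = two_carbon_tracer(frac_labeled=0.6, purity=1.0)
        bf = brute_force_isotopomer_mids(chain_model, chain_flux(), tracer)
        np.testing.assert_allclose(bf["B.c"], [0.4, 0, 0.6], atol=1e-12)

    def test_self_condensation_binomial(self, condensation_model):
        """50% labeled B condensing with itself: enumerate all 16 C
        isotopomers by hand and compare."""
        tracer = two_carbon_tracer(frac_labeled=0.5, purity=1.0)
        bf = brute_force_isotopomer_mids(
            condensation_model, condensation_flux(), tracer
        )
        # hand-coded enumeration: each 2-carbon unit is 00 or 11 w.p. 1/2
        expected = np.zeros(5)
        for u1, u2 in itertools.product([0, 1], repeat=2):
            expected[2 * u1 + 2 * u2] += 0.25
        np.testing.assert_allclose(bf["C.c"], expected, atol=1e-12)
        np.testing.assert_allclose(bf["C.c"][[0, 2, 4]], [0.25, 0.5, 0.25])

    def test_size_guard(self, builtin_model):
        spec = PRESETS["WT-like"]
        state = FluxState(dict(spec["net"]), dict(spec["exchange"]), dict(spec["mixing"]))
        with pytest.raises(EMUSimulationError, match="too large"):
            brute_force_isotopomer_mids(
                builtin_model, state, TracerSpec(), size_guard=16
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_cycle_model(self, cycle_model, seed):
        rng = np.random.default_rng(seed)
        flux = cycle_flux(
            upt=rng.uniform(0.5, 20),
            co2d=rng.uniform(0.05, 10),
            exch=rng.uniform(0, 10),
            mix=rng.uniform(0, 1),
        )
        tracer = two_carbon_tracer(purity=rng.uniform(0.9, 1.0))
        targets = [
            EMU("P.obs", (1, 2)),
            EMU("M.m", (1, 2, 3)),
            EMU("G.m", (1, 2)),
            EMU("C1.m", (1,)),
        ]
        assert oracle_vs_emu(cycle_model, flux, tracer, targets) <= 1e-10

    def test_oracle_equivalence_builtin_model(
        self, builtin_model, fragment_library
    ):
        spec = PRESETS["WT-like"]
        state = FluxState(
            dict(spec["net"]), dict(spec["exchange"]), dict(spec["mixing"])
        )
        targets = sorted(
            {EMU(f.metabolite, f.atoms) for f in fragment_library.values()}
        )
        assert oracle_vs_emu(builtin_model, state, TracerSpec(), targets) <= 1e-10
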