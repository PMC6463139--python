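"""Assembled ODE system: inducer response, degradation, conservation,
toggle locality and the decoy-cancellation structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualosc.odes import active_fractions, assemble_odes, degradation_flux
from dualosc.params import CircuitConfig, InducerCondition, ParameterSet
from dualosc.stability import jacobian_at

from conftest import make_circuit


def random_state(system, rng, scale=20.0):
    y = rng.uniform(0.1, scale, system.n)
    # spread promoter occupancy over microstates, respecting copy numbers
    for sl, total in system.conserved_blocks:
        block = rng.uniform(0.0, 1.0, sl.stop - sl.start)
        y[sl] = total * block / block.sum()
    return y


class TestActiveFractions:
    def test_no_iptg_gives_fully_active_laci(self, params):
        _, f_l = active_fractions(InducerCondition(0.5, 0.0), params)
        assert f_l == 1.0

    def test_laci_half_effect_at_half_saturation(self, params):
        _, f_l = active_fractions(
            InducerCondition(0.5, params.iptg_laci_k_half), params
        )
        assert f_l == pytest.approx(0.5)

    def test_zero_arabinose_floor_is_iptg_independent(self, params):
        """IPTG inhibits only the arabinose-dependent part of the AraC
        response, so the basal floor does not move with IPTG."""
        f0, _ = active_fractions(InducerCondition(0.0, 0.0), params)
        f1, _ = active_fractions(InducerCondition(0.0, 30.0), params)
        assert f0 == pytest.approx(params.ara_basal)
        assert f1 == pytest.approx(params.ara_basal)

    def test_monotonicity_and_bounds(self, params):
        aras = np.geomspace(0.001, 10, 25)
        fs = [active_fractions(InducerCondition(a, 0.1), params)[0]
              for a in aras]
        assert np.all(np.diff(fs) > 0)
        assert all(0.0 <= f <= 1.0 for f in fs)
        # IPTG weakly inhibits AraC activation
        hi, _ = active_fractions(InducerCondition(1.0, 0.0), params)
        lo, _ = active_fractions(InducerCondition(1.0, 30.0), params)
        assert lo < hi

    def test_negative_inducer_rejected(self, params):
        with pytest.raises(ValueError):
            InducerCondition(-1.0, 0.0)


class TestDegradationFlux:
    def test_single_species_reduces_to_michaelis_menten(self, params):
        flux = degradation_flux((7.0, 0.0, 0.0), params, sharing_on=True)
        expected = params.v_max * 7.0 / (params.k_m + 7.0)
        assert flux[0] == pytest.approx(expected)
        assert flux[1] == flux[2] == 0.0

    def test_reporter_load_slows_regulator_degradation(self, params):
        base = degradation_flux((50.0, 30.0, 100.0), params, True)
        loaded = degradation_flux((50.0, 30.0, 200.0), params, True)
        assert loaded[0] < base[0]
        assert loaded[1] < base[1]

    def test_sharing_off_decouples_gfp(self, params):
        base = degradation_flux((50.0, 30.0, 100.0), params, False)
        loaded = degradation_flux((50.0, 30.0, 200.0), params, False)
        assert loaded[0] == base[0] and loaded[1] == base[1]
        assert loaded[2] > base[2]

    @given(
        a=st.floats(0, 1e4), l=st.floats(0, 1e4), g=st.floats(0, 1e4)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_total_shared_flux_bounded_by_vmax(self, a, l, g):
        p = ParameterSet()
        total = degradation_flux((a, l, g), p, True).sum()
        assert total <= p.v_max * (1 + 1e-12)
        expected = p.v_max * (a + l + g) / (p.k_m + a + l + g)
        assert total == pytest.approx(expected)


class TestAssembledSystem:
    def test_reporter_none_drops_reporter_states(self, params,
                                                 reference_condition):
        system = assemble_odes(make_circuit("none"), params,
                               reference_condition)
        assert "gfp" not in system.state_names
        assert not any("reporter" in n or "decoy" in n
                       for n in system.state_names)

    def test_dimension_mismatch_rejected(self, params, reference_condition):
        system = assemble_odes(make_circuit("lac"), params,
                               reference_condition)
        with pytest.raises(ValueError, match="dimension"):
            system.rhs(0.0, np.ones(system.n + 3))

    @pytest.mark.parametrize("kind", ["none", "lac_ara", "lac", "lac_decoy"])
    def test_promoter_copy_conservation_of_rhs(self, kind, params,
                                               reference_condition, rng):
        """The RHS conserves the summed occupancy of every promoter class."""
        system = assemble_odes(make_circuit(kind), params,
                               reference_condition)
        for _ in range(5):
            dy = system.rhs(0.0, random_state(system, rng))
            for sl, _total in system.conserved_blocks:
                assert abs(dy[sl].sum()) < 1e-10

    def test_pure_decay_when_production_and_protease_off(self, params,
                                                         reference_condition):
        """With production, protease and DNA binding all off, only dilution
        remains and proteins decay as exp(-lambda t)."""
        p = params.replace(k_tx_active=0.0, k_tx_basal=0.0, b_d1=0.0,
                           b_d2=0.0, v_max=0.0, ka_on=0.0, kr_on=0.0)
        system = assemble_odes(make_circuit("lac_ara"), p,
                               reference_condition)
        y = system.initial_state(a=100.0, l=50.0)
        dy = system.rhs(0.0, y)
        assert dy[system.i_a] == pytest.approx(-p.dilution * 100.0)
        assert dy[system.i_l] == pytest.approx(-p.dilution * 50.0)

    def test_analytic_jacobian_matches_finite_differences(self, params,
                                                          reference_condition,
                                                          rng):
        for kind in ("lac_ara", "lac_decoy"):
            system = assemble_odes(make_circuit(kind), params,
                                   reference_condition)
            y = random_state(system, rng)
            J = system.jacobian(0.0, y)
            Jfd = jacobian_at(system, y, method="fd")
            assert np.allclose(J, Jfd, rtol=1e-5, atol=1e-5)

    def test_toggles_are_no_ops_without_reporter(self, params,
                                                 reference_condition, rng):
        """With no downstream gene the competition toggles cannot act."""
        systems = [
            assemble_odes(make_circuit("none", retro=r, share=s), params,
                          reference_condition)
            for r in (True, False) for s in (True, False)
        ]
        y = random_state(systems[0], rng)
        ref = systems[0].rhs(0.0, y)
        for system in systems[1:]:
            assert np.array_equal(system.rhs(0.0, y), ref)

    def test_toggle_locality(self, params, reference_condition, rng):
        """Flipping retroactivity changes only free-pool sequestration terms;
        flipping protease sharing changes only the free-pool degradation
        rows.  Promoter-occupancy dynamics never move."""
        y = None
        base = assemble_odes(make_circuit("lac_ara"), params,
                             reference_condition)
        y = random_state(base, rng)
        no_retro = assemble_odes(
            make_circuit("lac_ara", retro=False), params, reference_condition
        )
        no_share = assemble_odes(
            make_circuit("lac_ara", share=False), params, reference_condition
        )
        f0 = base.rhs(0.0, y)
        f_r = no_retro.rhs(0.0, y)
        f_s = no_share.rhs(0.0, y)
        pools = [base.i_a, base.i_l, base.i_g]
        occ = np.ones(base.n, dtype=bool)
        occ[pools] = False
        # occupancy + mRNA rows identical in all variants
        assert np.array_equal(f0[occ], f_r[occ])
        assert np.array_equal(f0[occ], f_s[occ])
        # retroactivity toggle: only a and l rows move, not gfp
        assert not np.array_equal(f0[[base.i_a, base.i_l]],
                                  f_r[[base.i_a, base.i_l]])
        assert f0[base.i_g] == f_r[base.i_g]
        # sharing toggle: all three pool rows may move but nothing else
        assert not np.array_equal(f0[pools], f_s[pools])

    def test_decoy_equalises_free_pool_dynamics_without_sharing(
        self, params, reference_condition, rng
    ):
        """With protease sharing off, the lac/ara-reporter circuit and the
        lac-reporter+decoy circuit expose the same total census of AraC and
        LacI binding sites, so the free regulatory pools obey identical
        dynamics (the AraC-site and LacI-operator kinetics factorise)."""
        sys_a = assemble_odes(make_circuit("lac_ara", share=False), params,
                              reference_condition)
        sys_d = assemble_odes(make_circuit("lac_decoy", share=False), params,
                              reference_condition)
        rep_a = next(c for c in sys_a.classes if c.name == "reporter")
        rep_d = next(c for c in sys_d.classes if c.name == "reporter")
        dec_d = next(c for c in sys_d.classes if c.name == "decoy")

        y_a = random_state(sys_a, rng)
        # map the lac/ara-reporter occupancy to (lac reporter, decoy)
        # marginals: sum over the AraC axis / the LacI axis respectively
        y_d = np.zeros(sys_d.n)
        y_d[sys_d.i_a] = y_a[sys_a.i_a]
        y_d[sys_d.i_l] = y_a[sys_a.i_l]
        y_d[sys_d.i_g] = y_a[sys_a.i_g]
        for gene, im in sys_d.i_m.items():
            y_d[im] = y_a[sys_a.i_m[gene]]
        for c_d, c_a in zip(sys_d.classes[:2], sys_a.classes[:2]):
            y_d[c_d.sl] = y_a[c_a.sl]
        occ_a = y_a[rep_a.sl].reshape(2, 5)          # (AraC state, lac pattern)
        y_d[rep_d.sl] = occ_a.sum(axis=0)            # lac-pattern marginal
        y_d[dec_d.sl] = occ_a.sum(axis=1)            # AraC-site marginal

        f_a = sys_a.rhs(0.0, y_a)
        f_d = sys_d.rhs(0.0, y_d)
        for ia, id_ in ((sys_a.i_a, sys_d.i_a), (sys_a.i_l, sys_d.i_l)):
            assert f_a[ia] == pytest.approx(f_d[id_], rel=1e-12, abs=1e-12)
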