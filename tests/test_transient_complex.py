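"""Mass-action transient-complex model: structure, conservation, fluxes."""

from dataclasses import replace

import numpy as np
import pytest

from chankin import transient_complex as tc
from chankin.binding_equilibrium import free_ligand_quadratic
from chankin.channeling import MichaelisParams
from chankin.errors import InvalidInputError, UndefinedFractionError


@pytest.fixture(scope="module")
def constants(acceptor_mm):
    return tc.RateConstants.from_calibration(0.8, acceptor_mm)


class TestScheme:
    def test_structure(self, constants):
        net = tc.build_scheme(constants)
        assert net.stoichiometry.shape == (9, 10)
        assert net.species == tc.SPECIES

    def test_pool_conservation_is_structural(self, constants):
        # each conserved pool's indicator vector annihilates the stoichiometry
        net = tc.build_scheme(constants)
        idx = {s: i for i, s in enumerate(tc.SPECIES)}
        pools = {
            "L": ["L", "LN_c", "LN_d", "LGN"],
            "G": ["G", "GN", "LGN"],
            "N": ["N", "GN", "LN_c", "LN_d", "LGN", "P_c", "P_d"],
        }
        for members in pools.values():
            vec = np.zeros(len(tc.SPECIES))
            vec[[idx[m] for m in members]] = 1.0
            np.testing.assert_allclose(vec @ net.stoichiometry, 0.0, atol=1e-14)

    def test_disabling_complex_silences_its_reactions(self, constants):
        net = tc.build_scheme(constants.without_channeling())
        state = tc.initial_state(1.0, 10.0, 5.0, gn_bound=2.0).concentrations
        rates = net.rates(state)
        # complex association/dissociation and hand-over carry zero flux
        assert rates[4] == rates[5] == rates[6] == 0.0

    def test_kd_accessor(self, constants):
        assert constants.kd_gn == pytest.approx(0.8)

    def test_negative_constant_rejected(self):
        with pytest.raises(InvalidInputError):
            tc.RateConstants(1, 1, 1, 1, 1, 1, -1, 1)


class TestSimulate:
    def test_all_rates_zero_state_constant(self):
        constants = tc.RateConstants(0, 0, 0, 0, 0, 0, 0, 0)
        init = tc.initial_state(0.5, 100.0, 40.0)
        traj = tc.simulate(tc.build_scheme(constants), init, 10.0, t_eval=[0.0, 10.0])
        np.testing.assert_allclose(traj.states[-1], init.concentrations, atol=1e-12)

    def test_mass_conservation_along_trajectory(self, constants):
        init = tc.initial_state(0.01, 240.0, 40.0)
        traj = tc.simulate(tc.build_scheme(constants), init, 0.5)
        ref = np.array(init.totals)
        for i in range(len(traj.times)):
            np.testing.assert_allclose(traj.state(i).totals, ref, rtol=1e-6)

    def test_equilibrium_free_nadh_matches_closed_form(self, constants):
        # binding-only relaxation with no acceptor: the exact quadratic is the oracle
        eq = tc.equilibrate(constants, tc.initial_state(0.0, 240.0, 40.0))
        expected = free_ligand_quadratic(240.0, 40.0, constants.kd_gn)
        assert eq.N == pytest.approx(expected, rel=1e-6)

    def test_equilibrium_is_path_independent(self, constants):
        # same totals, NADH started free vs mostly pre-bound
        a = tc.equilibrate(constants, tc.initial_state(0.01, 240.0, 40.0))
        b = tc.equilibrate(constants, tc.initial_state(0.01, 240.0, 40.0, gn_bound=39.0))
        np.testing.assert_allclose(a.concentrations, b.concentrations, rtol=1e-6,
                                   atol=1e-12)

    def test_detailed_balance_at_equilibrium(self, constants):
        eq = tc.equilibrate(constants, tc.initial_state(0.01, 240.0, 40.0))
        assert eq.G * eq.N / eq.GN == pytest.approx(constants.kd_gn, rel=1e-6)
        assert eq.L * eq.N / eq.LN == pytest.approx(
            constants.koff_ln / constants.kon_ln, rel=1e-6
        )
        assert eq.L * eq.GN / eq.LGN == pytest.approx(
            constants.koff_cx / constants.kon_cx, rel=1e-6
        )

    def test_negative_initial_state_rejected(self, constants):
        state = tc.initial_state(0.01, 240.0, 40.0)
        state.concentrations[0] = -1.0
        with pytest.raises(InvalidInputError):
            tc.simulate(tc.build_scheme(constants), state, 1.0)


class TestSteadyRate:
    def test_null_model_reproduces_free_diffusion_prediction(
        self, constants, acceptor_mm
    ):
        v = tc.steady_rate(constants.without_channeling(), 0.01, 240.0, 40.0)
        free = free_ligand_quadratic(240.0, 40.0, constants.kd_gn)
        assert v == pytest.approx(acceptor_mm.rate(free), rel=0.02)

    def test_zero_nadh_zero_rate(self, constants):
        assert tc.steady_rate(constants, 0.01, 240.0, 0.0) == 0.0

    def test_specific_activity_independent_of_acceptor_level(self, constants):
        v1 = tc.steady_rate(constants, 0.01, 240.0, 40.0)
        v2 = tc.steady_rate(constants, 0.02, 240.0, 40.0)
        assert v2 == pytest.approx(v1, rel=0.01)

    def test_channeling_raises_measured_over_calculated(self, constants, acceptor_mm):
        v = tc.steady_rate(constants, 0.01, 240.0, 40.0)
        free = free_ligand_quadratic(240.0, 40.0, constants.kd_gn)
        assert v / acceptor_mm.rate(free) > 1.2

    def test_ratio_grows_as_nadh_drops(self, constants, acceptor_mm):
        ratios = []
        for nadh in (40.0, 20.0, 10.0):
            v = tc.steady_rate(constants, 0.01, 200.0, nadh)
            free = free_ligand_quadratic(200.0, nadh, constants.kd_gn)
            ratios.append(v / acceptor_mm.rate(free))
        assert ratios[0] < ratios[1] < ratios[2]


class TestFluxPartition:
    def test_no_complex_path_no_channeled_product(self, constants):
        traj = tc._run_to_conversion(
            constants.without_channeling(), 0.01, 240.0, 40.0, 0.02
        )
        assert tc.flux_partition(traj).channeled_fraction == 0.0

    def test_no_free_capture_all_channeled(self, constants):
        traj = tc._run_to_conversion(
            replace(constants, kon_ln=0.0), 0.01, 240.0, 40.0, 0.02
        )
        assert tc.flux_partition(traj).channeled_fraction == 1.0

    def test_fractions_sum_to_one(self, constants):
        traj = tc._run_to_conversion(constants, 0.01, 240.0, 40.0, 0.02)
        fp = tc.flux_partition(traj)
        total = fp.channeled_product + fp.diffusive_product
        assert fp.channeled_fraction == pytest.approx(fp.channeled_product / total,
                                                      abs=1e-9)

    def test_no_product_undefined(self, constants):
        net = tc.build_scheme(constants.binding_only())
        traj = tc.simulate(net, tc.initial_state(0.01, 240.0, 40.0), 0.01)
        with pytest.raises(UndefinedFractionError):
            tc.flux_partition(traj)


class TestOffrateSweep:
    def test_single_point_grid_matches_flux_partition(self, constants):
        out = tc.offrate_sweep(
            constants, [constants.koff_gn], [constants.koff_cx],
            ldh_sites=0.01, gapdh_sites=240.0, nadh_total=40.0,
        )
        traj = tc._run_to_conversion(constants, 0.01, 240.0, 40.0, 0.05)
        assert out.shape == (1, 1)
        assert out[0, 0] == pytest.approx(
            tc.flux_partition(traj).channeled_fraction, rel=1e-6
        )

    def test_offrate_overlap_fixed_affinity(self, constants):
        # at fixed donor Kd, faster NADH release overlaps the complex
        # lifetime more often: channeled fraction rises monotonically
        grid = np.geomspace(constants.koff_gn / 3, constants.koff_gn * 30, 5)
        out = tc.offrate_sweep(
            constants, grid, [constants.koff_cx],
            ldh_sites=0.01, gapdh_sites=240.0, nadh_total=40.0,
        ).ravel()
        assert np.all(np.diff(out) > 0)

    def test_shortlived_complex_cannot_channel(self, constants):
        out = tc.offrate_sweep(
            constants, [constants.koff_gn],
            [constants.koff_cx, constants.koff_cx * 1e4],
            ldh_sites=0.01, gapdh_sites=240.0, nadh_total=40.0,
        ).ravel()
        assert out[1] < out[0] * 0.05  # koff_cx → ∞ limit kills hand-over


class TestTurnoverComparison:
    def test_channeled_never_exceeds_diffusive(self, constants):
        rng = np.random.default_rng(23)
        for _ in range(20):
            scale = 10.0 ** rng.uniform(-1, 1, size=4)
            trial = replace(
                constants,
                koff_gn=constants.koff_gn * scale[0],
                k_transfer=constants.koff_gn * scale[0],
                koff_cx=constants.koff_cx * scale[1],
                kon_cx=constants.kon_cx * scale[2],
                koff_ln=constants.koff_ln * scale[3],
            )
            rep = tc.channeled_turnover_comparison(
                trial, ldh_sites=0.01, gapdh_sites=240.0, nadh_total=40.0
            )
            assert rep.channeled_turnover <= rep.diffusive_turnover + 1e-9

    def test_instantaneous_handover_converges_to_diffusive(self, constants):
        fast = replace(constants, k_transfer=constants.kcat * 1e6)
        rep = tc.channeled_turnover_comparison(
            fast, ldh_sites=0.01, gapdh_sites=240.0, nadh_total=40.0
        )
        assert rep.channeled_turnover == pytest.approx(rep.diffusive_turnover, rel=0.01)

    def test_dead_end_complex_has_zero_channeled_turnover(self, constants):
        dead = replace(constants, k_transfer=0.0)
        rep = tc.channeled_turnover_comparison(
            dead, ldh_sites=0.01, gapdh_sites=240.0, nadh_total=40.0
        )
        assert rep.channeled_turnover == 0.0
        assert rep.channeled_fraction == 0.0


class TestUnitConversions:
    def test_kcat_vmax_roundtrip(self):
        kcat = tc.kcat_from_vmax(140.0)
        assert kcat == pytest.approx(4900.0)
        assert tc.specific_activity(kcat * 0.01, 0.01) == pytest.approx(140.0)
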