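import dataclasses

import numpy as np
import pytest

from srlumen import (
    EffluxModel,
    InfluxModel,
    SimulationConfig,
    build_axial_grid,
    build_axisymmetric_mesh,
    initial_condition,
    solve,
    well_mixed_limit,
)
from srlumen.oracle_validation import analytic_rod_solution


class TestInitialCondition:
    def test_with_calsequestrin_total_is_buffer_equilibrium(self, params, disc_1d):
        field = initial_condition(params, True, disc_1d)
        assert np.allclose(field.total, 8.2723, atol=5e-5)
        # derived free view recovers the resting free concentration
        assert np.allclose(field.free, 3.6, atol=5e-5)

    def test_without_calsequestrin_total_equals_free(self, params, disc_1d):
        field = initial_condition(params, False, disc_1d)
        assert np.allclose(field.total, 3.6)
        assert field.free is field.total


class TestEquilibriumAndConservation:
    @pytest.mark.parametrize("casq", [False, True])
    def test_zero_flux_field_constant_in_time(self, params, geom, casq):
        disc = build_axial_grid(geom, 4e-8)
        cfg = SimulationConfig(duration=0.02, n_output_points=50, efflux_mode="constant", casq_enabled=casq)
        tiny = EffluxModel(mode="constant", J0=-1e-300, reference_free_ca=params.ca_free_initial)
        field, _ = solve(cfg, params, geom, disc, tiny, InfluxModel(enabled=False))
        assert np.abs(field.total - field.total[0]).max() < 1e-10

    def test_mass_balance_against_integrated_boundary_fluxes(self, run_20ms_casq):
        _, fluxes = run_20ms_casq
        assert fluxes.mass_balance_error() < 1e-6

    def test_mass_balance_with_serca(self, params, geom, disc_1d, decaying_efflux):
        cfg = SimulationConfig(duration=0.02, casq_enabled=True, serca_enabled=True)
        _, fluxes = solve(cfg, params, geom, disc_1d, decaying_efflux,
                          InfluxModel(enabled=True, J_in=params.J_serca_influx))
        assert fluxes.mass_balance_error() < 1e-6

    def test_field_values_stay_physical(self, run_20ms_casq):
        field, _ = run_20ms_casq
        assert field.total.min() >= 0
        assert np.all(field.free <= field.total + 1e-12)


class TestAgainstAnalyticSeries:
    def test_constant_coefficient_rod_matches_fourier_series(self, params, geom, constant_efflux, no_influx):
        # casq off, constant efflux: D* is the constant free diffusivity
        disc = build_axial_grid(geom, 5e-9)
        cfg = SimulationConfig(duration=0.02, n_output_points=100, efflux_mode="constant", casq_enabled=False)
        field, _ = solve(cfg, params, geom, disc, constant_efflux, no_influx)
        exact = analytic_rod_solution(
            params.D_ca_free, params.J_efflux_0, params.ca_free_initial,
            geom.axial_length, disc.node_x, field.times,
        )
        rel_err = np.abs(field.total - exact).max() / params.ca_free_initial
        assert rel_err < 1e-4


class TestGridAndDimensionConsistency:
    def test_grid_convergence_of_csr_free(self, params, geom, decaying_efflux, no_influx):
        cfg = SimulationConfig(duration=0.02, n_output_points=200, casq_enabled=True)
        vals = []
        for spacing in (1e-8, 5e-9):
            disc = build_axial_grid(geom, spacing)
            field, _ = solve(cfg, params, geom, disc, decaying_efflux, no_influx)
            vals.append(field.free_at(disc.csr_node)[-1])
        assert abs(vals[1] - vals[0]) / vals[0] < 1e-4

    def test_1d_and_2d_axial_profiles_agree(self, params, geom, decaying_efflux, no_influx):
        # no radial forcing: the axisymmetric solution is exactly axial
        cfg1 = SimulationConfig(duration=0.02, n_output_points=100, casq_enabled=True)
        cfg2 = dataclasses.replace(cfg1, discretization_mode="axisymmetric_2d")
        disc1 = build_axial_grid(geom, 1e-8)
        disc2 = build_axisymmetric_mesh(geom, 1e-8)
        f1, _ = solve(cfg1, params, geom, disc1, decaying_efflux, no_influx)
        f2, _ = solve(cfg2, params, geom, disc2, decaying_efflux, no_influx)
        nr, nz = disc2.shape
        axial2 = f2.total.reshape(-1, nr, nz)[:, 0, :]
        assert np.abs(f1.total - axial2).max() / f1.total[0, 0] < 1e-6

    def test_operator_forms_agree_for_constant_coefficient(self, params, geom, constant_efflux, no_influx):
        # with casq off D* is uniform, so both operator forms are identical
        disc = build_axial_grid(geom, 2e-8)
        base = dict(duration=0.005, n_output_points=50, efflux_mode="constant", casq_enabled=False)
        f_cons, _ = solve(SimulationConfig(**base), params, geom, disc, constant_efflux, no_influx)
        f_non, _ = solve(
            SimulationConfig(operator_form="nonconservative", **base),
            params, geom, disc, constant_efflux, no_influx,
        )
        assert np.abs(f_cons.total - f_non.total).max() / 3.6 < 1e-7


class TestPhysicalFindings:
    def test_calsequestrin_slows_both_declines(self, run_20ms_nocasq, run_20ms_casq):
        """Buffering reduces the 20-ms percent declines of efflux and CSR free Ca."""
        from srlumen.observables import percent_decline

        (f_off, fl_off), (f_on, fl_on) = run_20ms_nocasq, run_20ms_casq
        for f, fl in ((f_off, fl_off), (f_on, fl_on)):
            assert np.all(np.diff(np.abs(fl.efflux_density_F2)) <= 0)
        d_eff_off = percent_decline(fl_off.times, np.abs(fl_off.efflux_density_F2))
        d_eff_on = percent_decline(fl_on.times, np.abs(fl_on.efflux_density_F2))
        d_csr_off = percent_decline(f_off.times, f_off.free_at(f_off.disc.csr_node))
        d_csr_on = percent_decline(f_on.times, f_on.free_at(f_on.disc.csr_node))
        assert d_eff_on < d_eff_off
        assert d_csr_on < d_csr_off

    def test_long_window_flattens_axial_gradient(self, params, geom, disc_1d, decaying_efflux, no_influx):
        """At 2 s the LSR-CSR difference has fallen below its 20-ms-window peak."""
        cfg = SimulationConfig(duration=2.0, n_output_points=500, casq_enabled=False)
        field, _ = solve(cfg, params, geom, disc_1d, decaying_efflux, no_influx)
        diff = field.free_at(disc_1d.lsr_node) - field.free_at(disc_1d.csr_node)
        early_peak = diff[field.times <= 0.02].max()
        assert diff[-1] <= early_peak
        # late-time profile near-uniform relative to its mean depletion
        late_spread = field.free[-1].max() - field.free[-1].min()
        depletion = field.free[0, 0] - field.free[-1].mean()
        assert late_spread / depletion < 0.01


class TestWellMixedLimit:
    def test_constant_efflux_is_exactly_linear(self, params, geom, constant_efflux, no_influx):
        cfg = SimulationConfig(duration=0.02, n_output_points=50, efflux_mode="constant", casq_enabled=False)
        t, c = well_mixed_limit(cfg, params, constant_efflux, no_influx, geom)
        expected = params.ca_free_initial - abs(params.J_efflux_0) * t / geom.axial_length
        assert np.allclose(c, expected, rtol=1e-8)

    def test_decaying_efflux_is_exponential(self, params, geom, decaying_efflux, no_influx):
        cfg = SimulationConfig(duration=2.0, n_output_points=50, casq_enabled=False)
        t, c = well_mixed_limit(cfg, params, decaying_efflux, no_influx, geom)
        rate = abs(params.J_efflux_0) / (geom.axial_length * params.ca_free_initial)
        assert np.allclose(c, params.ca_free_initial * np.exp(-rate * t), rtol=1e-7)


class TestErrorHandling:
    def test_mismatched_geometry_rejected(self, params, geom, decaying_efflux, no_influx):
        from srlumen import SRElementGeometry

        other = SRElementGeometry(radius=2e-8)
        disc = build_axial_grid(other, 1e-8)
        with pytest.raises(ValueError, match="different geometry"):
            solve(SimulationConfig(), params, geom, disc, decaying_efflux, no_influx)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_output_points=1)
        with pytest.raises(ValueError):
            SimulationConfig(operator_form="upwind")
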