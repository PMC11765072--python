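"""Explicit finite-difference cooling solver and its analytic oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest

import oleoprint as op
from oleoprint.errors import StabilityError


class TestStabilityCheck:
    def test_reference_config_passes(self, packaged_scenario):
        rep = op.stability_check(packaged_scenario.configs[5.0])
        assert rep.passed
        assert rep.r < 0.1

    def test_hundredfold_dt_fails(self, packaged_scenario):
        cfg = replace(packaged_scenario.configs[5.0], dt_s=1.0)
        rep = op.stability_check(cfg)
        assert not rep.passed
        assert rep.r == pytest.approx(
            100 * op.stability_check(packaged_scenario.configs[5.0]).r, rel=1e-12
        )

    def test_vanishing_diffusivity_passes(self, small_sim_config):
        cfg = replace(
            small_sim_config,
            material=op.MaterialThermalProps(1e-12, 880.0, 2400.0),
        )
        rep = op.stability_check(cfg)
        assert rep.r < 1e-10 and rep.passed

    def test_solver_refuses_unstable_dt(self, small_sim_config):
        cfg = replace(small_sim_config, dt_s=100.0)
        with pytest.raises(StabilityError):
            op.solve_layer(cfg)


class TestStepField:
    def test_equilibrium_is_fixed_point(self, small_sim_config):
        cfg = replace(
            small_sim_config,
            boundaries=op.BoundaryConditions(50.0, 50.0, 2.0, 50.0),
        )
        g = cfg.geometry
        f = op.ThermalField(np.full((g.Nx, g.Ny, g.Nz), 50.0))
        for _ in range(20):
            f = op.step_field(f, cfg)
        assert np.all(f.temperatures_C == 50.0)

    def test_insulated_equilibrated_base_stays_constant(self, small_sim_config):
        cfg = replace(
            small_sim_config,
            boundaries=op.BoundaryConditions(79.7, 22.1, 0.0, 79.7),
        )
        g = cfg.geometry
        f = op.ThermalField(np.full((g.Nx, g.Ny, g.Nz), 79.7))
        for _ in range(20):
            f = op.step_field(f, cfg)
        assert np.all(f.temperatures_C == 79.7)

    def test_cooling_step_respects_bounds_and_never_heats(self, small_sim_config):
        g = small_sim_config.geometry
        f0 = op.ThermalField(np.full((g.Nx, g.Ny, g.Nz), 79.7))
        f1 = op.step_field(f0, small_sim_config)
        t0, t1 = f0.temperatures_C.copy(), f1.temperatures_C
        t0[:, :, 0] = 8.5  # base plane is Dirichlet from the start
        assert np.all(t1 <= t0 + 1e-12)
        assert np.all(t1 >= 8.5) and np.all(t1 <= 79.7)
        # nodes whose stencil sees a colder neighbour strictly decrease
        assert np.all(t1[:, :, 1] < 79.7)          # base-adjacent
        assert np.all(t1[0, :, 1:] < 79.7)         # Robin side
        assert np.all(t1[:, :, -1] < 79.7)         # Robin top
        # after many steps the whole slab is strictly below T0
        hist = op.solve_layer(small_sim_config, duration_s=2.0)
        assert np.all(hist.final_field.temperatures_C[:, :, 1:] < 79.7)


class TestSolveLayer:
    def test_zero_duration_returns_initial_state(self, small_sim_config):
        hist = op.solve_layer(small_sim_config, duration_s=0.0)
        assert len(hist.times_s) == 1 and hist.times_s[0] == 0.0
        assert hist.final_t_upper_C == pytest.approx(79.7, abs=1e-12)
        assert np.all(hist.final_field.temperatures_C[:, :, 1:] == 79.7)
        assert np.all(hist.final_field.temperatures_C[:, :, 0] == 8.5)

    def test_final_time_matches_duration(self, small_sim_config):
        hist = op.solve_layer(small_sim_config, duration_s=3.456)
        assert abs(hist.times_s[-1] - 3.456) <= small_sim_config.dt_s

    def test_centerline_matches_fourier_series_oracle(self):
        # lateral/top convection off -> exact 1D slab problem
        mat = op.MaterialThermalProps(0.16, 880.0, 2400.0)
        alpha = mat.diffusivity_m2_s
        Lz, t_end = 0.001, 5.0
        geo = op.LayerGeometry(0.01, 0.01, Lz, Nx=5, Ny=5, Nz=20)
        dz = geo.spacings_m[2]
        dt = t_end / math.ceil(t_end / (0.2 * dz**2 / alpha))
        cfg = op.PrintSimConfig(
            geometry=geo,
            material=mat,
            boundaries=op.BoundaryConditions(8.5, 22.1, 0.0, 79.7),
            layer_duration_s=t_end,
            n_layers=1,
            dt_s=dt,
            output_stride_s=t_end,
        )
        hist = op.solve_layer(cfg)
        z = np.linspace(0.0, Lz, geo.Nz)
        exact = op.analytic_slab_solution(z, t_end, Lz, alpha, 8.5, 79.7, n_terms=200)
        center = hist.final_field.temperatures_C[2, 2, :]
        assert np.abs(center - exact).max() < 0.5

    def test_energy_balance_closes(self, small_sim_config):
        hist = op.solve_layer(small_sim_config)
        assert hist.energy.residual_rel < 0.01
        # cooling run: enthalpy falls, base extracts heat
        assert hist.energy.enthalpy_change_J < 0
        assert hist.energy.base_in_J < 0

    def test_mean_temperature_monotone_under_cooling(self, small_sim_config):
        g = small_sim_config.geometry
        f = op.ThermalField(np.full((g.Nx, g.Ny, g.Nz), 79.7))
        means = []
        for _ in range(100):
            f = op.step_field(f, small_sim_config)
            means.append(f.temperatures_C[:, :, 1:].mean())
        assert np.all(np.diff(means) <= 1e-12)


class TestSimulatePrint:
    def test_single_layer_reduces_to_solve_layer(self, small_sim_config):
        cfg = replace(small_sim_config, n_layers=1)
        [hist] = op.simulate_print(cfg)
        ref = op.solve_layer(cfg, layer_index=1)
        np.testing.assert_array_equal(
            hist.final_field.temperatures_C, ref.final_field.temperatures_C
        )
        np.testing.assert_array_equal(hist.t_upper_C, ref.t_upper_C)

    def test_base_handoff_is_bit_exact(self, small_sim_config):
        hists = op.simulate_print(small_sim_config)
        assert len(hists) == small_sim_config.n_layers
        assert hists[0].base_temperature_C == 8.5
        for prev, nxt in zip(hists, hists[1:]):
            assert nxt.base_temperature_C == prev.final_t_upper_C

    def test_discrete_maximum_principle_tracked(self, small_sim_config):
        for h in op.simulate_print(small_sim_config):
            lo = min(8.5, 22.1, 79.7, h.base_temperature_C)
            hi = max(8.5, 22.1, 79.7, h.base_temperature_C)
            assert h.observed_min_C >= lo - 1e-9
            assert h.observed_max_C <= hi + 1e-9


class TestAnalyticSlabSolution:
    def test_initial_condition_recovered(self):
        val = op.analytic_slab_solution(0.0007, 0.0, 0.001, 7.58e-8, 8.5, 79.7,
                                        n_terms=20000)
        assert val == pytest.approx(79.7, abs=0.05)

    def test_long_time_limit_is_base_temperature(self):
        val = op.analytic_slab_solution(0.001, 1e5, 0.001, 7.58e-8, 8.5, 79.7)
        assert val == pytest.approx(8.5, abs=1e-9)

    def test_series_converged_at_50_terms_for_t_ge_1s(self):
        for z in (0.0, 0.0005, 0.001):
            a = op.analytic_slab_solution(z, 1.0, 0.001, 7.58e-8, 8.5, 79.7, n_terms=50)
            b = op.analytic_slab_solution(z, 1.0, 0.001, 7.58e-8, 8.5, 79.7, n_terms=100)
            assert abs(a - b) < 1e-6
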