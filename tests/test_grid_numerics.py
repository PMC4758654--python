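"""Discrete operators and steppers: oracles, conservation, stability, symmetry."""

import numpy as np
import pytest

from angiofield import (
    FieldState,
    Grid,
    ModelParameters,
    StepDiagnostics,
    adapt_dt,
    laplacian,
    step_capillary,
    step_nutrient,
    step_taf,
    step_tumor,
    tumor_free_energy,
)
from angiofield.grid_numerics import DT_MAX, NumericsError, TOL_DOWN, TOL_UP

from conftest import smooth_random_field

P = ModelParameters()


def make_state(grid, phi=0.0, sigma=0.45, c=-1.0, f=0.0):
    shape = grid.shape
    return FieldState(phi=np.full(shape, float(phi)),
                      sigma=np.full(shape, float(sigma)),
                      c=np.full(shape, float(c)),
                      f=np.full(shape, float(f)))


class TestLaplacian:
    def test_constant_field_maps_to_zero(self, small_grid):
        arr = np.full(small_grid.shape, 3.7)
        np.testing.assert_allclose(laplacian(arr, small_grid), 0.0, atol=1e-12)

    def test_exact_for_quadratic_in_interior(self, small_grid):
        X, _ = small_grid.meshgrid()
        lap = laplacian(X ** 2, small_grid)
        np.testing.assert_allclose(lap[5:-5, 5:-5], 2.0, rtol=1e-10)

    def test_single_spike_stencil_value(self, small_grid):
        arr = np.zeros(small_grid.shape)
        arr[20, 30] = 1.0
        expected = -(2.0 / small_grid.dx ** 2 + 2.0 / small_grid.dy ** 2)
        assert laplacian(arr, small_grid)[20, 30] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            laplacian(np.zeros((3, 3)), small_grid)

    def test_spectral_solve_inverts_stencil(self, small_grid, rng):
        # (I - a*Lap) u = rhs solved in DCT space must satisfy the 5-point
        # mirror-boundary stencil identity exactly
        from angiofield.grid_numerics import get_operators
        ops = get_operators(small_grid)
        rhs = smooth_random_field(small_grid, rng, 0.0, 1.0)
        u = ops.solve_diffusion(rhs, 0.7)
        np.testing.assert_allclose(u - 0.7 * laplacian(u, small_grid), rhs,
                                   atol=1e-10)


class TestTumorStep:
    @pytest.mark.parametrize("phi0", [0.0, 1.0])
    def test_uniform_bulk_states_unchanged(self, small_grid, phi0):
        st = make_state(small_grid, phi=phi0, sigma=0.2)
        phi_new = step_tumor(st, 0.5, P, small_grid)
        np.testing.assert_allclose(phi_new, phi0, atol=1e-12)

    def test_interface_retreats_when_nutrient_low(self, small_grid):
        # 1D front, sigma below the hypoxic-viable threshold everywhere:
        # the host phase is energetically preferred and the tumor shrinks
        X, _ = small_grid.meshgrid()
        st = make_state(small_grid, sigma=0.2)
        st.phi = 0.5 * (1.0 + np.tanh((400.0 - X) / (2 * np.sqrt(2) * P.lambda_phi)))
        before = st.phi.sum()
        for _ in range(20):
            st.phi = step_tumor(st, 0.2, P, small_grid)
        assert st.phi.sum() < before

    def test_interface_advances_when_nutrient_high(self, small_grid):
        X, _ = small_grid.meshgrid()
        st = make_state(small_grid, sigma=0.8)
        st.phi = 0.5 * (1.0 + np.tanh((400.0 - X) / (2 * np.sqrt(2) * P.lambda_phi)))
        before = st.phi.sum()
        for _ in range(20):
            st.phi = step_tumor(st, 0.2, P, small_grid)
        assert st.phi.sum() > before

    def test_front_speed_matches_fine_explicit_oracle(self):
        # independent oracle: fine-grid fully explicit 1D integration of the
        # tilted Allen-Cahn equation; the traveling-wave speed must agree
        grid = Grid(nx=256, ny=4, width=2000.0, height=40.0)
        m_sigma = 0.2
        st = make_state(grid, sigma=m_sigma)
        X, _ = grid.meshgrid()
        st.phi = 0.5 * (1.0 + np.tanh((600.0 - X) / (2 * np.sqrt(2) * P.lambda_phi)))

        def front_pos(phi_line, xs):
            i = int(np.argmax(phi_line < 0.5))
            return xs[i - 1] + (xs[i] - xs[i - 1]) * (phi_line[i - 1] - 0.5) / (
                phi_line[i - 1] - phi_line[i])

        xs = grid.x_centers()
        p0 = front_pos(st.phi[2], xs)
        T = 12.0
        n_steps = 240
        for _ in range(n_steps):
            st.phi = step_tumor(st, T / n_steps, P, grid)
        v_imex = (front_pos(st.phi[2], xs) - p0) / T

        # explicit reference on a 4x finer 1D grid
        n = 1024
        dx = 2000.0 / n
        x = (np.arange(n) + 0.5) * dx
        phi = 0.5 * (1.0 + np.tanh((600.0 - x) / (2 * np.sqrt(2) * P.lambda_phi)))
        from angiofield import mu_phi
        p0_ref = front_pos(phi, x)
        dt = 0.2 * dx * dx / (P.M_phi * P.lambda_phi ** 2)
        steps = int(T / dt)
        for _ in range(steps):
            lap = np.empty_like(phi)
            lap[1:-1] = (phi[2:] - 2 * phi[1:-1] + phi[:-2]) / dx ** 2
            lap[0] = (phi[1] - phi[0]) / dx ** 2
            lap[-1] = (phi[-2] - phi[-1]) / dx ** 2
            phi = phi + dt * P.M_phi * (P.lambda_phi ** 2 * lap
                                        - mu_phi(phi, m_sigma, P))
        v_ref = (front_pos(phi, x) - p0_ref) / T
        assert v_imex == pytest.approx(v_ref, rel=0.15)

    def test_frozen_sigma_energy_decay(self, small_grid, rng):
        st = make_state(small_grid)
        st.phi = smooth_random_field(small_grid, rng, 0.0, 1.0)
        st.sigma = smooth_random_field(small_grid, rng, 0.1, 0.9)
        energies = [tumor_free_energy(st.phi, st.sigma, small_grid, P)]
        for _ in range(120):
            st.phi = step_tumor(st, 0.5, P, small_grid)
            energies.append(tumor_free_energy(st.phi, st.sigma, small_grid, P))
        diffs = np.diff(energies)
        assert (diffs <= 1e-9 * max(1.0, abs(energies[0]))).all()


class TestNutrientStep:
    def test_pointwise_exponential_decay_oracle(self, small_grid):
        # phi=0, c=-1 uniform: sigma decays by host uptake only,
        # sigma(dt) = sigma0 * exp(-V_uH * H(1) * dt)
        sigma0 = 0.45
        st = make_state(small_grid, sigma=sigma0)
        for dt in (0.1, 1.0, 5.0):
            from angiofield import smoothed_heaviside_H
            expected = sigma0 * np.exp(-P.V_uH * float(smoothed_heaviside_H(1.0, P)) * dt)
            got = step_nutrient(st, dt, 1.0, P, small_grid)
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_saturated_capillary_only_loses_by_uptake(self, small_grid):
        st = make_state(small_grid, sigma=1.0, c=1.0)
        out = step_nutrient(st, 1.0, 1.0, P, small_grid)
        assert (out <= 1.0 + 1e-12).all()
        assert out.max() < 1.0  # production (1-sigma) vanished, uptake remains

    def test_steady_state_decay_length(self):
        # 1D balance D sigma'' = V_uH sigma gives decay length sqrt(D/V_uH)
        grid = Grid(nx=400, ny=4, width=1200.0, height=12.0)
        st = make_state(grid, sigma=0.45)
        X, _ = grid.meshgrid()
        strip = X < 25.0
        st.c = np.where(strip, 1.0, -1.0)
        for _ in range(3000):
            st.sigma = step_nutrient(st, 5.0, 1.0, P, grid)
        ell = np.sqrt(P.D_sigma / P.V_uH)
        assert ell == pytest.approx(223.6, abs=0.1)
        xs = grid.x_centers()
        sel = (xs > 100) & (xs < 500)
        profile = st.sigma[2, sel]
        fitted = np.polyfit(xs[sel], np.log(profile), 1)
        assert -1.0 / fitted[0] == pytest.approx(ell, rel=0.03)

    def test_range_preserved_from_admissible_data(self, small_grid, rng):
        st = make_state(small_grid)
        st.sigma = smooth_random_field(small_grid, rng, 0.0, 1.0)
        st.phi = smooth_random_field(small_grid, rng, 0.0, 1.0)
        st.c = smooth_random_field(small_grid, rng, -1.0, 1.0)
        for _ in range(50):
            st.sigma = step_nutrient(st, 2.0, 0.7, P, small_grid)
            assert st.sigma.min() >= -1e-9 and st.sigma.max() <= 1.0 + 1e-9

    def test_invalid_S_rejected(self, small_grid):
        st = make_state(small_grid)
        with pytest.raises(ValueError):
            step_nutrient(st, 0.1, 0.0, P, small_grid)


class TestCapillaryStep:
    def test_uniform_bulk_states_unchanged(self, small_grid):
        for c0, f0 in ((1.0, 0.0), (-1.0, 0.7)):
            st = make_state(small_grid, c=c0, f=f0)
            c_new = step_capillary(st, 0.5, P, small_grid)
            np.testing.assert_allclose(c_new, c0, atol=5e-9)

    def test_mass_conserved_without_proliferation(self, small_grid, rng):
        st = make_state(small_grid, f=0.0)  # B_p(0) = 0
        st.c = smooth_random_field(small_grid, rng, -1.0, 1.0)
        total0 = st.c.sum()
        for _ in range(100):
            st.c = step_capillary(st, 0.5, P, small_grid)
        drift = abs(st.c.sum() - total0) / (small_grid.nx * small_grid.ny)
        assert drift < 1e-8

    def test_proliferation_grows_capillary_mass(self, small_grid):
        st = make_state(small_grid, c=-1.0, f=0.5)
        X, Y = small_grid.meshgrid()
        st.c = np.where(Y < 100.0, 1.0, -1.0).astype(float)
        total0 = st.c.sum()
        for _ in range(10):
            st.c = step_capillary(st, 0.2, P, small_grid)
        assert st.c.sum() > total0


class TestTafStep:
    def test_no_source_stays_zero(self, small_grid):
        st = make_state(small_grid, phi=0.0, f=0.0)
        out = step_taf(st, 1.0, P, small_grid)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_small_step_linearization(self, small_grid):
        # uniform phi=1, sigma=0.3 (peak secretion), no capillaries:
        # f grows like G_amp * dt initially
        st = make_state(small_grid, phi=1.0, sigma=0.3, f=0.0)
        dt = 1e-3
        out = step_taf(st, dt, P, small_grid)
        np.testing.assert_allclose(out, P.G_amp * dt, rtol=1e-3)

    def test_saturated_field_has_no_source(self, small_grid):
        st = make_state(small_grid, phi=1.0, sigma=0.3, f=1.0)
        out = step_taf(st, 1.0, P, small_grid)
        assert (out <= 1.0 + 1e-12).all()
        np.testing.assert_allclose(out, 1.0, atol=1e-12)  # no capillary uptake


class TestMirrorSymmetry:
    def test_deterministic_steppers_preserve_axis_symmetry(self, rng):
        grid = Grid(nx=64, ny=48)
        st = make_state(grid)
        half = smooth_random_field(Grid(nx=32, ny=48), rng, 0.0, 1.0)
        st.phi = np.concatenate([half, half[:, ::-1]], axis=1)
        st.sigma = 0.2 + 0.6 * st.phi[:, ::-1] * st.phi
        st.sigma = np.minimum(st.sigma, 1.0)
        st.c = 2.0 * np.concatenate([half, half[:, ::-1]], axis=1) - 1.0
        st.f = 0.5 * st.phi
        for _ in range(5):
            st.sigma = step_nutrient(st, 1.0, 1.0, P, grid)
            st.phi = step_tumor(st, 1.0, P, grid)
            st.f = step_taf(st, 1.0, P, grid)
            st.c = step_capillary(st, 1.0, P, grid)
        for arr in (st.phi, st.sigma, st.c, st.f):
            np.testing.assert_allclose(arr, arr[:, ::-1], atol=1e-10)


class TestAdaptDt:
    def test_quiet_step_grows(self):
        assert adapt_dt(1.0, StepDiagnostics(max_change=1e-4), P) == pytest.approx(1.2)

    def test_growth_capped_at_maximum(self):
        assert adapt_dt(DT_MAX, StepDiagnostics(max_change=1e-4), P) == DT_MAX

    def test_failure_halves(self):
        assert adapt_dt(1.0, StepDiagnostics(max_change=0.0, solver_failed=True),
                        P) == pytest.approx(0.5)

    def test_large_change_halves(self):
        assert adapt_dt(1.0, StepDiagnostics(max_change=2 * TOL_UP), P) == pytest.approx(0.5)

    def test_moderate_change_keeps_dt(self):
        mid = 0.5 * (TOL_UP + TOL_DOWN)
        assert adapt_dt(1.0, StepDiagnostics(max_change=mid), P) == pytest.approx(1.0)

    def test_tec_displacement_cap(self):
        dt = adapt_dt(DT_MAX, StepDiagnostics(max_change=1e-4, max_tec_speed=P.chi), P)
        assert dt <= P.R / (2 * P.chi) + 1e-12

    def test_underflow_raises(self):
        with pytest.raises(NumericsError):
            adapt_dt(1e-4, StepDiagnostics(max_change=1.0), P)


class TestGridConvergence:
    def test_day_one_tumor_area_stable_under_refinement(self):
        # halving the spacing changes the early-time tumor area by < 2 %
        from angiofield import ScenarioConfig, run_scenario
        areas = {}
        for nx, ny in ((64, 48), (128, 96)):
            cfg = ScenarioConfig(mode="avascular", nx=nx, ny=ny,
                                 t_end_days=1.0, output_every_days=1.0)
            areas[nx] = run_scenario(cfg).records[-1].A_t
        assert abs(areas[128] - areas[64]) / areas[128] < 0.02
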