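"""Finite-volume solver: grid, invariants, analytic and brute-force oracles."""

import math

import numpy as np
import pytest

from oxydrop.model import DimensionlessParams
from oxydrop.observables import core_trace
from oxydrop.solver import (
    FieldState,
    Trajectory,
    advance,
    build_grid,
    initial_state,
    simulate,
    steady_disc_oracle,
)
from oxydrop.workflows import plateau_annulus_width


class TestGrid:
    def test_uniform_spacing_and_faces(self):
        g = build_grid(1.0, 100)
        assert g.h == pytest.approx(0.01)
        assert g.faces[0] == 0.0 and g.faces[-1] == pytest.approx(1.0)
        assert np.all(np.diff(g.faces) > 0)

    def test_volumes_sum_to_disc_area(self):
        g = build_grid(3.7, 257)
        assert g.volumes().sum() == pytest.approx(math.pi * 3.7**2, rel=1e-12)

    def test_reference_spacing(self):
        g = build_grid(9.3, 1024)
        assert g.h == pytest.approx(9.3 / 1024, rel=1e-12)
        assert g.h == pytest.approx(9.082e-3, rel=1e-3)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            build_grid(1.0, 8)


class TestInitialState:
    def test_uniform_saturated(self):
        g = build_grid(2.0, 64)
        s = initial_state(g)
        assert np.all(s.c_oxy == 1.0) and np.all(s.c_cell == 1.0) and s.t == 0.0
        # dimensionless cell and O2 content both equal the disc area
        assert float(np.sum(s.c_cell * g.volumes())) == pytest.approx(math.pi * 4.0, rel=1e-12)


class TestAdvanceBasics:
    def test_uniform_state_is_fixed_point_without_uptake(self):
        p = DimensionlessParams.from_ratios(2.0, 1.0, chi_tilde=0.0)
        g = build_grid(2.0, 64)
        traj = simulate(p, g, t_max=2.0, cadence=1.0, uptake="none", steady_tol=0.0)
        assert np.allclose(traj.c_oxy[-1], 1.0, atol=1e-12)
        assert np.allclose(traj.c_cell[-1], 1.0, atol=1e-12)

    def test_robin_relaxation_toward_saturation(self):
        p = DimensionlessParams.from_ratios(2.0, 1.0)
        g = build_grid(2.0, 64)
        s0 = initial_state(g)
        s0.c_oxy[:] = 0.5
        traj = simulate(
            p, g, t_max=8.0, cadence=0.5, initial=s0, uptake="none",
            evolve_cells=False, steady_tol=0.0,
        )
        # monotone recovery toward saturation everywhere, never above 1
        assert np.all(np.diff(traj.c_oxy, axis=0) >= -1e-12)
        assert traj.c_oxy[-1].min() > 0.99
        assert traj.c_oxy.max() <= 1.0 + 1e-9

    def test_advance_steps_a_state(self):
        p = DimensionlessParams.from_ratios(2.0, 1.0)
        g = build_grid(2.0, 64)
        s1 = advance(initial_state(g), p, g, 0.25)
        assert s1.t == pytest.approx(0.25)
        assert s1.c_oxy.min() < 1.0  # uptake has begun


class TestSteadyDiscOracle:
    def test_reference_values(self):
        g = build_grid(2.0, 64)
        prof = steady_disc_oracle(1.0, 1.0, g)
        assert prof[-1] == pytest.approx(1.0 - 1.0 * (4 - g.centers[-1] ** 2) / 4)
        # center value c_edge - Q R^2/4 = 0 for R=2, Q=1, c_edge=1
        assert steady_disc_oracle(1.0, 1.0, g)[0] == pytest.approx(
            1.0 - (4 - g.centers[0] ** 2) / 4
        )
        assert np.allclose(steady_disc_oracle(0.0, 0.7, g), 0.7)

    def test_solver_matches_disc_poisson_solution(self):
        """Constant sink, frozen cells, absorbing rim: the steady profile
        must match c(r) = 1 - Q (R^2 - r^2)/4 to 1e-3 relative error."""
        Q = 0.5
        p = DimensionlessParams.from_ratios(2.0, 0.0)  # Dirichlet limit
        g = build_grid(2.0, 512)
        traj = simulate(
            p, g, t_max=30.0, cadence=5.0, uptake=Q, evolve_cells=False,
            dt_max=2e-4, steady_tol=1e-10,
        )
        expected = steady_disc_oracle(Q, 1.0, g)
        err = np.max(np.abs(traj.c_oxy[-1] - expected)) / np.max(np.abs(expected))
        assert err < 1e-3


class TestExplicitEulerOracle:
    def test_production_solver_matches_brute_force(self):
        """A plain explicit-Euler integrator of the same finite-volume system
        (tiny fixed dt) reproduces the production IMEX fields at t=1."""
        N, Rt, kt_inv = 64, 2.0, 1.0
        p = DimensionlessParams.from_ratios(Rt, kt_inv)
        g = build_grid(Rt, N)
        traj = simulate(p, g, t_max=1.0, cadence=1.0, dt_max=5e-5, steady_tol=0.0)

        # --- independent brute force ---
        h = g.h
        rc, rf = g.centers, g.faces
        k_eff = 1.0 / (kt_inv + 0.5 * h)
        oxy = np.ones(N)
        cell = np.ones(N)
        dt = 1e-5
        n_steps = int(round(1.0 / dt))
        for _ in range(n_steps):
            s = 0.5 * (1 + np.tanh((oxy - p.c_crit_tilde) / p.delta_tilde))
            f = oxy / (p.K_chi_tilde + oxy)
            oxy_f = 0.5 * (oxy[:-1] + oxy[1:])
            s_f = 0.5 * (1 + np.tanh((oxy_f - p.c_crit_tilde) / p.delta_tilde))
            # oxygen: diffusion + Robin influx - switched MM uptake
            flux = np.zeros(N + 1)
            flux[1:N] = rf[1:N] * (oxy[1:] - oxy[:-1]) / h
            flux[N] = rf[N] * k_eff * (1.0 - oxy[-1])
            div = (flux[1:] - flux[:-1]) / (rc * h)
            uptake = s * cell * oxy / (p.K_tilde + oxy)
            # cells: switched diffusion + upwinded aerotactic advection
            dflux = np.zeros(N + 1)
            dflux[1:N] = rf[1:N] * p.Dcell_tilde * s_f * (cell[1:] - cell[:-1]) / h
            v = p.chi_tilde * s_f * (f[1:] - f[:-1]) / h
            adv = np.zeros(N + 1)
            up = np.where(v > 0, cell[:-1], cell[1:])
            adv[1:N] = rf[1:N] * v * up
            cell = cell + dt * (dflux[1:] - dflux[:-1] - (adv[1:] - adv[:-1])) / (rc * h)
            oxy = oxy + dt * (div - uptake)
        rel_l2 = np.linalg.norm(traj.c_oxy[-1] - oxy) / np.linalg.norm(oxy)
        rel_l2_cell = np.linalg.norm(traj.c_cell[-1] - cell) / np.linalg.norm(cell)
        assert rel_l2 < 1e-3
        assert rel_l2_cell < 1e-3


class TestInvariants:
    def test_oxygen_bounds(self, transient_traj, permanent_traj):
        for traj in (transient_traj, permanent_traj):
            assert traj.c_oxy.min() >= 0.0
            assert traj.c_oxy.max() <= 1.0 + 1e-9

    def test_cell_positivity(self, transient_traj):
        assert transient_traj.c_cell.min() >= -1e-12

    def test_cell_conservation_ledger(self, transient_traj, permanent_traj):
        for traj in (transient_traj, permanent_traj):
            assert traj.diagnostics["mass_rel_drift"] < 1e-8

    def test_timestamps_strictly_increasing(self, transient_traj):
        assert np.all(np.diff(transient_traj.times) > 0)

    def test_grid_convergence_of_annulus_width(self, permanent_traj):
        """The annulus width at core formation for (9.3, 0.7) changes by <2%
        when N doubles from 512 to 1024.  (The later slow interface creep
        converges only first-order; see the methods note.)"""
        p = permanent_traj.params
        traj2 = simulate(p, build_grid(9.3, 1024), t_max=30.0, cadence=0.5)
        w1 = core_trace(permanent_traj).ell_init
        w2 = core_trace(traj2).ell_init
        assert abs(w2 - w1) / w1 < 0.02


class TestEnhancedMotilityVariant:
    def test_doubled_motility_erodes_faster(self, transient_traj):
        """Enhancing both motility parameters accelerates core erosion."""
        p2 = transient_traj.params.with_(Dcell_tilde=0.05, chi_tilde=0.6)
        g = transient_traj.grid
        traj2 = simulate(p2, g, t_max=260.0, cadence=2.0, stop_on_vanish=True)
        tv_base = core_trace(transient_traj).t_vanish
        tv_2x = core_trace(traj2).t_vanish
        assert tv_2x < tv_base


class TestTrajectoryIO:
    def test_hdf5_round_trip(self, tmp_path, transient_traj):
        path = tmp_path / "traj.h5"
        transient_traj.save(path)
        back = Trajectory.load(path)
        assert np.array_equal(back.times, transient_traj.times)
        assert np.array_equal(back.c_oxy, transient_traj.c_oxy)
        assert np.array_equal(back.c_cell, transient_traj.c_cell)
        assert back.params.R_tilde == transient_traj.params.R_tilde
        assert back.diagnostics["status"] == transient_traj.diagnostics["status"]


class TestValidation:
    def test_grid_params_radius_mismatch(self):
        p = DimensionlessParams.from_ratios(2.0, 1.0)
        with pytest.raises(ValueError):
            simulate(p, build_grid(3.0, 64), t_max=1.0)

    def test_bad_initial_fields(self):
        p = DimensionlessParams.from_ratios(2.0, 1.0)
        g = build_grid(2.0, 64)
        bad = FieldState(t=0.0, c_oxy=np.full(64, 2.0), c_cell=np.ones(64))
        with pytest.raises(ValueError):
            simulate(p, g, t_max=1.0, initial=bad)

    def test_nonpositive_t_max(self):
        p = DimensionlessParams.from_ratios(2.0, 1.0)
        with pytest.raises(ValueError):
            simulate(p, build_grid(2.0, 64), t_max=0.0)
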