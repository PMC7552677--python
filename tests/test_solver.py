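import math

import numpy as np
import pytest

from bmhvflow import CaseSpec, PhysicalProperties
from bmhvflow.errors import DomainError, SolverError
from bmhvflow.solver import (BoundaryConditions, FlowField, ProjectionSolver,
                             SolverConfig, TurbulenceState, advance, cfl,
                             komega_equilibrium_omega, komega_update,
                             run_case, zero_field,
                             KOMEGA_ALPHA, KOMEGA_BETA)
from bmhvflow.verification import (poiseuille_benchmark, straight_channel_mask,
                                   womersley_benchmark)


@pytest.fixture(scope="module")
def channel():
    return straight_channel_mask(nx=24, ny_fluid=16, spacing=1.0 / 16)


@pytest.fixture(scope="module")
def unit_props():
    return PhysicalProperties(density=1.0, dynamic_viscosity=0.01)


class TestCfl:
    def test_zero_field_is_zero(self, channel):
        assert cfl(zero_field(channel), SolverConfig(), channel.spacing_m) == 0.0

    def test_arithmetic(self, channel):
        fld = zero_field(channel)
        fld.u[:, :] = 1.0
        c = cfl(fld, SolverConfig(dt=5e-4), 1e-3)
        assert c == pytest.approx(0.5)
        assert cfl(fld, SolverConfig(dt=1e-3), 1e-3) == pytest.approx(2 * c)


class TestProjectionStep:
    def test_zero_inflow_fixed_point(self, channel, unit_props):
        cfg = SolverConfig(dt=1e-3)
        solver = ProjectionSolver(channel, unit_props, cfg)
        fld = zero_field(channel)
        for _ in range(5):
            fld = solver.step(fld, 1e-3, 0.0)
        assert np.all(fld.u == 0.0) and np.all(fld.v == 0.0)

    def test_divergence_free_after_projection(self, channel, unit_props):
        cfg = SolverConfig(dt=1e-3)
        solver = ProjectionSolver(channel, unit_props, cfg)
        fld = zero_field(channel)
        inlet = np.where(channel.fluid[0, :], 1.0, 0.0)
        for _ in range(20):
            dt = solver.stable_dt(fld, 1.0)
            fld = solver.step(fld, dt, inlet)
            div = (np.diff(fld.u, axis=0) + np.diff(fld.v, axis=1)) / channel.spacing_m
            assert np.abs(div[channel.fluid]).max() < 1e-9

    def test_kinetic_energy_decays_without_inflow(self, channel, unit_props):
        rng = np.random.default_rng(7)
        cfg = SolverConfig(dt=1e-3)
        solver = ProjectionSolver(channel, unit_props, cfg)
        fld = zero_field(channel)
        fld.u[solver.u_active] = 0.1 * rng.standard_normal(int(solver.u_active.sum()))
        fld.v[solver.v_active] = 0.1 * rng.standard_normal(int(solver.v_active.sum()))
        fld = solver.step(fld, 1e-4, 0.0)  # project the random field first
        ke = [float((fld.u ** 2).sum() + (fld.v ** 2).sum())]
        for _ in range(30):
            dt = solver.stable_dt(fld, 0.0)
            fld = solver.step(fld, dt, 0.0)
            ke.append(float((fld.u ** 2).sum() + (fld.v ** 2).sum()))
        assert all(b <= a * (1 + 1e-12) for a, b in zip(ke, ke[1:]))

    def test_advance_raises_on_cfl_violation(self, channel, unit_props):
        fld = zero_field(channel)
        fld.u[:, :] = 100.0
        cfg = SolverConfig(dt=1e-2)
        with pytest.raises(SolverError, match="CFL"):
            advance(fld, channel, None, BoundaryConditions(0.0), cfg, unit_props)


class TestAnalyticBenchmarks:
    def test_poiseuille_centerline_mean_ratio(self):
        r = poiseuille_benchmark(ny_fluid=32, t_end=0.25)
        assert r.centerline_mean_ratio == pytest.approx(1.5, rel=0.02)

    def test_grid_convergence_order_at_least_one(self):
        e_coarse = poiseuille_benchmark(ny_fluid=8, nx=16, t_end=0.25).rel_error
        e_fine = poiseuille_benchmark(ny_fluid=16, nx=16, t_end=0.25).rel_error
        order = math.log2(e_coarse / e_fine)
        assert order >= 1.0

    def test_womersley_profile_maintained(self):
        r = womersley_benchmark(alpha=5.0, ny_fluid=24, n_periods=1.25)
        assert r.rel_error < 0.05
        assert r.max_divergence <= r.divergence_tolerance


class TestKOmega:
    def test_update_requires_turbulent_mode(self, open_box_mask):
        fld = zero_field(open_box_mask)
        turb = TurbulenceState.quiescent(open_box_mask.shape)
        with pytest.raises(DomainError):
            komega_update(fld, turb, open_box_mask, SolverConfig())

    def test_laminar_case_run_has_no_eddy_viscosity(self):
        # laminar mode carries no turbulence state at all: nu_t is identically 0
        case = CaseSpec(27.0, 0.0, 3.0)
        cfg = SolverConfig(n_cycles=1, sample_interval_s=0.05)
        run = run_case(case, config=cfg)
        assert run.nu_t_snapshots is None

    def test_no_shear_means_no_production(self, open_box_mask):
        cfg = SolverConfig(turbulence_mode="k_omega", nu_t_max_ratio=1e12)
        props = PhysicalProperties(density=1.0, dynamic_viscosity=1e-6)
        fld = zero_field(open_box_mask)
        fld.u[:, :] = 2.0  # uniform flow: no strain anywhere
        turb = TurbulenceState(k=np.full(open_box_mask.shape, 1.0),
                               omega_t=np.full(open_box_mask.shape, 50.0),
                               nu_t=np.full(open_box_mask.shape, 0.02))
        ks = [1.0]
        for _ in range(40):
            turb = komega_update(fld, turb, open_box_mask, cfg, props, dt=1e-3)
            ks.append(float(turb.k[8, 8]))
        assert all(b < a for a, b in zip(ks, ks[1:]))

    def test_constant_shear_equilibrium_balance(self, open_box_mask):
        cfg = SolverConfig(turbulence_mode="k_omega", nu_t_max_ratio=1e12)
        props = PhysicalProperties(density=1.0, dynamic_viscosity=1e-6)
        gamma = 100.0
        y = (np.arange(open_box_mask.shape[1]) + 0.5) * open_box_mask.spacing_m
        nx, ny = open_box_mask.shape
        fld = FlowField(np.tile(gamma * y, (nx + 1, 1)), np.zeros((nx, ny + 1)),
                        np.zeros((nx, ny)), 0.0)
        turb = TurbulenceState(k=np.full((nx, ny), 1e-6),
                               omega_t=np.full((nx, ny), 100.0),
                               nu_t=np.full((nx, ny), 1e-8))
        for _ in range(800):
            turb = komega_update(fld, turb, open_box_mask, cfg, props, dt=5e-4)
        c = (nx // 2, ny // 2)
        assert turb.omega_t[c] == pytest.approx(komega_equilibrium_omega(gamma),
                                                rel=0.01)
        assert turb.nu_t[c] * gamma / turb.k[c] == pytest.approx(
            math.sqrt(KOMEGA_BETA / KOMEGA_ALPHA), rel=0.01)

    def test_negative_k_floored_and_counted(self, open_box_mask):
        cfg = SolverConfig(turbulence_mode="k_omega")
        props = PhysicalProperties(density=1.0, dynamic_viscosity=1e-6)
        fld = zero_field(open_box_mask)
        turb = TurbulenceState(k=np.full(open_box_mask.shape, 1e-3),
                               omega_t=np.full(open_box_mask.shape, 1e4),
                               nu_t=np.zeros(open_box_mask.shape))
        # dissipation term overshoots with this large explicit step
        turb = komega_update(fld, turb, open_box_mask, cfg, props, dt=0.1)
        assert np.all(turb.k >= 0.0)
        assert turb.floor_events > 0


class TestRunCase:
    def test_mass_conservation_and_divergence(self):
        case = CaseSpec(27.0, 0.0, 3.0)
        cfg = SolverConfig(n_cycles=1, sample_interval_s=0.02)
        run = run_case(case, config=cfg)
        assert run.mass_balance_rel < 0.01
        assert run.max_divergence <= run.divergence_tolerance
        assert len(run.snapshots) > 10

    def test_periodicity_reached_by_fifth_cycle(self):
        case = CaseSpec(27.0, 0.0, 3.0)
        cfg = SolverConfig(n_cycles=5, sample_interval_s=0.02)
        run = run_case(case, config=cfg)
        assert run.periodicity_metric < 0.05
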