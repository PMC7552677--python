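"""Analytic solver benchmarks: plane Poiseuille and oscillatory channel flow.

These run the projection solver on a plain straight channel against closed
forms: the steady parabolic profile (centerline/mean ratio 3/2) and the
oscillatory plane-channel (Womersley) solution.  Unit-scale fluids are used
so the benchmarks are fast and resolution is counted in cells, not mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Region, SolidMask
from .inflow import womersley_profile
from .solver import FlowField, ProjectionSolver, SolverConfig, zero_field
from .study_grid import PhysicalProperties


def straight_channel_mask(nx: int, ny_fluid: int, spacing: float) -> SolidMask:
    """Unobstructed channel: ``ny_fluid`` open rows between solid wall rows.

    ``spacing`` is in the benchmark's own length unit; the mask stores it as
    mm-with-unit-scale so that ``spacing_m = spacing`` (the solver only ever
    uses the metric spacing).
    """
    ny = ny_fluid + 2
    solid = np.zeros((nx, ny), dtype=bool)
    solid[:, 0] = True
    solid[:, -1] = True
    region = np.where(solid, np.int8(Region.SOLID), np.int8(Region.AORTA))
    return SolidMask(solid=solid, region=region, spacing_mm=spacing * 1e3,
                     valve_plane_x_mm=0.0, valve_band=(0, 1),
                     lvot_diameter_mm=float(ny_fluid) * spacing * 1e3)


@dataclass
class BenchmarkResult:
    centerline_mean_ratio: float | None
    rel_error: float
    max_divergence: float
    divergence_tolerance: float
    n_cells: int


def poiseuille_benchmark(ny_fluid: int = 64, nx: int = 32,
                         t_end: float = 0.3, u_max: float = 1.0,
                         nu: float = 1.0) -> BenchmarkResult:
    """Run a parabolic inflow to steady state and compare with the closed form.

    Returns the centerline/mean velocity ratio at the mid-channel column
    (analytically 3/2) and the relative L2 profile error.
    """
    H = 1.0
    h = H / ny_fluid
    mask = straight_channel_mask(nx, ny_fluid, h)
    props = PhysicalProperties(density=1.0, dynamic_viscosity=nu)
    config = SolverConfig(dt=1.0, n_cycles=1, cfl_limit=0.8)
    solver = ProjectionSolver(mask, props, config)

    y = (np.arange(ny_fluid + 2) + 0.5) * h - h  # cell-center y, walls outside
    exact = u_max * (1.0 - ((y - H / 2.0) / (H / 2.0)) ** 2)
    inlet = np.where(mask.fluid[0, :], np.maximum(exact, 0.0), 0.0)

    fld = zero_field(mask)
    t = 0.0
    while t < t_end:
        dt = min(solver.stable_dt(fld, u_max), t_end - t)
        fld = solver.step(fld, dt, inlet)
        t = fld.t

    mid = nx // 2
    profile = 0.5 * (fld.u[mid, :] + fld.u[mid + 1, :])
    open_rows = mask.fluid[mid, :]
    prof = profile[open_rows]
    ratio = float(prof.max() / prof.mean())
    err = float(np.linalg.norm(prof - exact[open_rows])
                / np.linalg.norm(exact[open_rows]))
    tol = config.poisson_tolerance * u_max / h
    return BenchmarkResult(centerline_mean_ratio=ratio, rel_error=err,
                           max_divergence=solver.max_divergence,
                           divergence_tolerance=tol,
                           n_cells=int(mask.fluid.sum()))


def womersley_benchmark(alpha: float = 5.0, ny_fluid: int = 32, nx: int = 40,
                        nu: float = 0.01, grad_amplitude: float = 1.0,
                        n_periods: float = 1.5,
                        n_compare: int = 16) -> BenchmarkResult:
    """Oscillatory channel flow against the Womersley closed form.

    The analytic profile is imposed at the inlet and as the initial
    condition; the solver must maintain it downstream.  The reported error
    is the RMS profile error at the mid-channel column over the final half
    period, normalized by the analytic amplitude maximum.
    """
    H = 1.0
    half = H / 2.0
    h = H / ny_fluid
    mask = straight_channel_mask(nx, ny_fluid, h)
    props = PhysicalProperties(density=1.0, dynamic_viscosity=nu)
    config = SolverConfig(dt=1.0, n_cycles=1, cfl_limit=0.8)
    solver = ProjectionSolver(mask, props, config)

    omega = alpha ** 2 * nu / half ** 2
    period = 2.0 * math.pi / omega
    y = (np.arange(ny_fluid + 2) + 0.5) * h - h - half  # centered coordinates

    def exact(t: float) -> np.ndarray:
        prof = womersley_profile(grad_amplitude, alpha, omega * t, y,
                                 half_width=half, density=props.density,
                                 kinematic_viscosity=nu)
        return np.where(mask.fluid[0, :], prof, 0.0)

    u_scale = float(np.abs([exact(period * k / 64.0) for k in range(64)]).max())

    fld = zero_field(mask)
    fld.u[:, :] = exact(0.0)[None, :]
    t = 0.0
    t_end = n_periods * period
    compare_times = t_end - period / 2.0 * (np.arange(n_compare) / n_compare)[::-1]
    errors = []
    ci = 0
    mid = nx // 2
    while t < t_end - 1e-12:
        dt = min(solver.stable_dt(fld, u_scale), t_end - t)
        if ci < n_compare:
            dt = min(dt, compare_times[ci] - t) if compare_times[ci] > t else dt
        fld = solver.step(fld, dt, exact(t + dt))
        t = fld.t
        if ci < n_compare and t >= compare_times[ci] - 1e-12:
            profile = 0.5 * (fld.u[mid, :] + fld.u[mid + 1, :])
            open_rows = mask.fluid[mid, :]
            errors.append(profile[open_rows] - exact(t)[open_rows])
            ci += 1

    rms = float(np.sqrt(np.mean(np.concatenate(errors) ** 2)) / u_scale)
    tol = config.poisson_tolerance * u_scale / h
    return BenchmarkResult(centerline_mean_ratio=None, rel_error=rms,
                           max_divergence=solver.max_divergence,
                           divergence_tolerance=tol,
                           n_cells=int(mask.fluid.sum()))
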