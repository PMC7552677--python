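"""Hemodynamic field diagnostics: vorticity, shear stresses, peak detection.

All quantities are evaluated at cell centers on fluid cells only.  Gradients
next to stair-step solid boundaries are one-sided, taking the no-slip value
(zero velocity) at the wall face half a cell away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .geometry import Region, SolidMask
from .study_grid import PhysicalProperties


def cell_center_velocity(u: np.ndarray, v: np.ndarray,
                         fluid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average face velocities to cell centers; zero on solid cells.

    Accepts either staggered (faces) or already cell-centered arrays.
    """
    uc = u if u.shape == fluid.shape else 0.5 * (u[:-1, :] + u[1:, :])
    vc = v if v.shape == fluid.shape else 0.5 * (v[:, :-1] + v[:, 1:])
    return np.where(fluid, uc, 0.0), np.where(fluid, vc, 0.0)


def masked_gradient(f: np.ndarray, fluid: np.ndarray, h: float,
                    axis: int) -> np.ndarray:
    """d f / d(axis) at cell centers with wall-aware one-sided differences.

    Interior (both neighbors fluid): centered difference over 2h.  A solid
    neighbor is replaced by the no-slip wall value 0 at the wall face, half a
    cell away, giving a one-sided slope over h/2 on that side; the two side
    slopes are averaged.  Domain edges replicate the edge value
    (zero-gradient).
    """
    fwd = np.roll(f, -1, axis=axis)
    bwd = np.roll(f, 1, axis=axis)
    fwd_fluid = np.roll(fluid, -1, axis=axis)
    bwd_fluid = np.roll(fluid, 1, axis=axis)
    if axis == 0:
        fwd[-1, :] = f[-1, :]; fwd_fluid[-1, :] = fluid[-1, :]
        bwd[0, :] = f[0, :]; bwd_fluid[0, :] = fluid[0, :]
    else:
        fwd[:, -1] = f[:, -1]; fwd_fluid[:, -1] = fluid[:, -1]
        bwd[:, 0] = f[:, 0]; bwd_fluid[:, 0] = fluid[:, 0]

    slope_fwd = np.where(fwd_fluid, (fwd - f) / h, (0.0 - f) / (h / 2.0))
    slope_bwd = np.where(bwd_fluid, (f - bwd) / h, (f - 0.0) / (h / 2.0))
    grad = 0.5 * (slope_fwd + slope_bwd)
    return np.where(fluid, grad, 0.0)


@dataclass
class DerivedFields:
    """Per-snapshot derived diagnostics on fluid cells."""

    vorticity_z: np.ndarray   # 1/s
    viscous_shear: np.ndarray  # Pa
    turbulent_shear: np.ndarray  # Pa
    speed: np.ndarray          # m/s


def vorticity(field, mask: SolidMask) -> np.ndarray:
    """Out-of-plane vorticity dv/dx - du/dy at cell centers (1/s)."""
    uc, vc = cell_center_velocity(field.u, field.v, mask.fluid)
    h = mask.spacing_m
    return (masked_gradient(vc, mask.fluid, h, axis=0)
            - masked_gradient(uc, mask.fluid, h, axis=1))


def shear_stresses(field, turb, props: PhysicalProperties,
                   mask: SolidMask) -> tuple[np.ndarray, np.ndarray]:
    """Viscous and modelled turbulent (Reynolds) shear stress fields (Pa).

    viscous = mu * (du/dy + dv/dx); turbulent = rho * nu_t * (du/dy + dv/dx).
    ``turb`` may be a TurbulenceState, a plain nu_t array, or None (laminar:
    the turbulent component is identically zero).
    """
    uc, vc = cell_center_velocity(field.u, field.v, mask.fluid)
    h = mask.spacing_m
    strain = (masked_gradient(uc, mask.fluid, h, axis=1)
              + masked_gradient(vc, mask.fluid, h, axis=0))
    viscous = props.dynamic_viscosity * strain
    if turb is None:
        turbulent = np.zeros_like(strain)
    else:
        nu_t = turb if isinstance(turb, np.ndarray) else turb.nu_t
        turbulent = props.density * nu_t * strain
    return viscous, turbulent


def derive_fields(field, turb, props: PhysicalProperties,
                  mask: SolidMask) -> DerivedFields:
    uc, vc = cell_center_velocity(field.u, field.v, mask.fluid)
    viscous, turbulent = shear_stresses(field, turb, props, mask)
    return DerivedFields(vorticity_z=vorticity(field, mask),
                         viscous_shear=viscous, turbulent_shear=turbulent,
                         speed=np.hypot(uc, vc))


def orifice_jet_speeds(snap, mask: SolidMask) -> list[float]:
    """Peak speed threading each valve orifice, ordered from the lower wall.

    For every orifice (cross-stream fluid interval open along the whole
    valve band, see :func:`bmhvflow.geometry.orifice_gaps`) this reports the
    maximum speed over the band's columns within that interval — the
    strength of the jet carried by that orifice.
    """
    from .geometry import orifice_gaps
    gaps = orifice_gaps(mask)
    uc, vc = cell_center_velocity(snap.u, snap.v, mask.fluid)
    speed = np.hypot(uc, vc)
    i0, i1 = mask.valve_band
    y = mask.y_centers_mm()
    out = []
    for (ylo, yhi) in gaps:
        rows = (y > ylo) & (y < yhi)
        block = speed[i0:i1, rows]
        out.append(float(block.max()) if block.size else 0.0)
    return out


def half_plane_flux_split(snap, mask: SolidMask,
                          x_offset_cells: int = 2) -> tuple[float, float]:
    """Streamwise volume flux (per unit depth) below/above the centerline.

    Evaluated at the first face column downstream of the valve band; a
    closed upper leaflet diverts the flow into the lower half.
    """
    i = min(mask.valve_band[1] + x_offset_cells, mask.shape[0] - 1)
    h = mask.spacing_m
    u = snap.u if snap.u.shape[0] == mask.shape[0] + 1 else None
    if u is None:  # cell-centered field
        col = snap.u[i, :]
    else:
        col = u[i, :]
    ny = mask.shape[1]
    lower = float(col[: ny // 2].sum()) * h
    upper = float(col[ny // 2:].sum()) * h
    return lower, upper


@dataclass(frozen=True)
class PeakResult:
    value: float
    location: tuple[int, int]
    time: float


def region_selector(mask: SolidMask,
                    region_labels: Iterable[Region | int]) -> np.ndarray:
    sel = np.isin(mask.region, [int(r) for r in region_labels]) & mask.fluid
    if not sel.any():
        raise DomainError(f"region selection {list(region_labels)} is empty")
    return sel


def peak_over(series: Sequence, mask: SolidMask,
              region_labels: Iterable[Region | int] = (Region.SINUS, Region.AORTA),
              quantity: str = "speed",
              selector: np.ndarray | None = None) -> PeakResult:
    """Maximum of a derived quantity over region cells and snapshot times.

    Snapshots are visited in increasing time order; ties break to the
    earliest time, then the lowest flattened cell index (strict-greater
    comparison and numpy's first-argmax semantics make this deterministic
    regardless of the input ordering of ``series``).
    """
    sel = selector if selector is not None else region_selector(mask, region_labels)
    if not sel.any():
        raise DomainError("empty region for peak detection")
    series = list(series)
    if not series:
        raise DomainError("peak_over requires at least one snapshot")
    best: PeakResult | None = None
    for snap in sorted(series, key=lambda s: s.t):
        if quantity == "speed":
            uc, vc = cell_center_velocity(snap.u, snap.v, mask.fluid)
            fldvals = np.hypot(uc, vc)
        elif quantity == "vorticity":
            fldvals = np.abs(vorticity(snap, mask))
        else:
            raise DomainError(f"unknown quantity {quantity!r}")
        masked = np.where(sel, fldvals, -np.inf)
        flat = int(np.argmax(masked))
        val = float(masked.flat[flat])
        if best is None or val > best.value:
            best = PeakResult(value=val,
                              location=tuple(np.unravel_index(flat, masked.shape)),
                              time=float(snap.t))
    assert best is not None
    return best
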