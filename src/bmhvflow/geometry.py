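"""Parametric 2D channel geometry: tunnel LVOT stenosis, bileaflet valve, sinus, aorta.

The domain is a straight channel (x streamwise, y cross-stream) rasterized to
a uniform Cartesian cell mask (stair-step solids).  From inlet to outlet:

* LVOT tunnel of width ``lvot_diameter_mm`` (the subaortic stenosis; for a
  27 mm case the tunnel matches the aorta and there is no narrowing),
* the valve housing ring (inner width ``aorta_width - 2*housing_ring``) at the
  valve plane, carrying the two rigid leaflets pivoted at fixed hinge points,
* a sinus segment with a smooth symmetric bulge,
* a straight aorta segment to the outlet.

For a healthy (fully open) valve the leaflets split the valve plane into one
central and two lateral orifices; a fully closed leaflet seals its side of the
housing, leaving the central orifice and the lateral orifice of the
functioning leaflet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Sequence

import numpy as np

from .errors import DomainError, GeometryError, ResolutionError
from .study_grid import CaseSpec, REFERENCE_DIAMETER_MM


class Region(IntEnum):
    SOLID = 0
    LVOT = 1
    VALVE_PLANE = 2
    SINUS = 3
    AORTA = 4


@dataclass(frozen=True)
class GeometryParams:
    """Channel and valve dimensions (mm, degrees).

    Angles are measured from the valve plane: 90 deg would be perfectly
    streamwise, the default open position is 85 deg and the default closed
    position 25 deg (representative published values for a 27 mm bileaflet
    valve).  The leaflet pivot sits ``pivot_fraction`` of the leaflet length
    from its wall-side end.
    """

    aorta_width_mm: float = 27.0
    lvot_length_mm: float = 30.0
    stenosis_length_mm: float = 20.0
    sinus_length_mm: float = 25.0
    aorta_length_mm: float = 80.0
    sinus_bulge_depth_mm: float = 4.0
    leaflet_length_mm: float = 12.0
    leaflet_thickness_mm: float = 2.0
    open_angle_deg: float = 85.0
    closed_angle_deg: float = 25.0
    grid_spacing_mm: float = 0.9
    hinge_offset_mm: float = 5.0
    pivot_fraction: float = 0.4
    housing_ring_mm: float = 2.0
    housing_axial_mm: float = 3.0

    def __post_init__(self) -> None:
        lengths = (self.aorta_width_mm, self.lvot_length_mm, self.stenosis_length_mm,
                   self.sinus_length_mm, self.aorta_length_mm, self.sinus_bulge_depth_mm,
                   self.leaflet_length_mm, self.leaflet_thickness_mm,
                   self.grid_spacing_mm, self.hinge_offset_mm,
                   self.housing_ring_mm, self.housing_axial_mm)
        if any(v <= 0 for v in lengths):
            raise DomainError("all geometry lengths must be positive")
        if not 0 < self.closed_angle_deg < self.open_angle_deg <= 90.0:
            raise DomainError("require 0 < closed_angle_deg < open_angle_deg <= 90")
        if not 0 < self.pivot_fraction < 1:
            raise DomainError("pivot_fraction must lie in (0, 1)")
        if self.leaflet_thickness_mm < 2.0 * self.grid_spacing_mm:
            raise ResolutionError(
                f"grid_spacing_mm={self.grid_spacing_mm} too coarse for leaflet "
                f"thickness {self.leaflet_thickness_mm} (need thickness >= 2*spacing)"
            )

    @property
    def valve_plane_x_mm(self) -> float:
        return self.lvot_length_mm + self.stenosis_length_mm

    @property
    def domain_length_mm(self) -> float:
        return (self.lvot_length_mm + self.stenosis_length_mm
                + self.sinus_length_mm + self.aorta_length_mm)

    def with_spacing(self, spacing_mm: float) -> "GeometryParams":
        return replace(self, grid_spacing_mm=spacing_mm)


@dataclass
class SolidMask:
    """Rasterized geometry: boolean solid field plus region labels.

    Arrays are indexed ``[i, j]`` with i the streamwise cell index (inlet at
    x=0) and j the cross-stream index; cell centers sit at ``(i+1/2)h``.
    """

    solid: np.ndarray            # (nx, ny) bool
    region: np.ndarray           # (nx, ny) int8, Region codes
    spacing_mm: float
    valve_plane_x_mm: float
    valve_band: tuple[int, int]  # [i0, i1) columns spanned by housing + leaflets
    lvot_diameter_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.solid.shape

    @property
    def fluid(self) -> np.ndarray:
        return ~self.solid

    @property
    def spacing_m(self) -> float:
        return self.spacing_mm * 1e-3

    def x_centers_mm(self) -> np.ndarray:
        nx = self.solid.shape[0]
        return (np.arange(nx) + 0.5) * self.spacing_mm + self.origin_mm[0]

    def y_centers_mm(self) -> np.ndarray:
        ny = self.solid.shape[1]
        return (np.arange(ny) + 0.5) * self.spacing_mm + self.origin_mm[1]

    @property
    def centerline_y_mm(self) -> float:
        return self.solid.shape[1] * self.spacing_mm / 2.0 + self.origin_mm[1]


#: A thick segment: (x0, y0, x1, y1, thickness), all in mm.
Segment = tuple[float, float, float, float, float]


def rasterize_segments(segments: Sequence[Segment], nx: int, ny: int,
                       spacing_mm: float,
                       origin_mm: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Mark cells whose center lies inside a segment's thickness envelope.

    The envelope is the rectangle swept by the segment (flat end caps), so an
    axis-aligned segment of length n*h and thickness m*h placed to straddle
    cell centers covers exactly n*m cells.  Deterministic; boundary centers
    (distance exactly thickness/2) count as inside.
    """
    solid = np.zeros((nx, ny), dtype=bool)
    xc = (np.arange(nx) + 0.5) * spacing_mm + origin_mm[0]
    yc = (np.arange(ny) + 0.5) * spacing_mm + origin_mm[1]
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    for (x0, y0, x1, y1, thickness) in segments:
        dx, dy = x1 - x0, y1 - y0
        length = math.hypot(dx, dy)
        if length == 0.0:
            inside = (X - x0) ** 2 + (Y - y0) ** 2 <= (thickness / 2.0) ** 2
            solid |= inside
            continue
        ex, ey = dx / length, dy / length
        along = (X - x0) * ex + (Y - y0) * ey
        perp = -(X - x0) * ey + (Y - y0) * ex
        solid |= (along >= 0.0) & (along <= length) & (np.abs(perp) <= thickness / 2.0)
    return solid


def leaflet_angles(dysfunction_pct: float, params: GeometryParams) -> tuple[float, float]:
    """Angles (deg, from the valve plane) of the functional and affected leaflet.

    The functional leaflet is always fully open; the affected leaflet is
    linearly interpolated between the open and closed positions by the
    dysfunction percentage.
    """
    if not 0 <= dysfunction_pct <= 100:
        raise DomainError(f"dysfunction_pct must lie in [0, 100], got {dysfunction_pct}")
    affected = params.open_angle_deg + (
        params.closed_angle_deg - params.open_angle_deg) * dysfunction_pct / 100.0
    return params.open_angle_deg, affected


def leaflet_segments(dysfunction_pct: float, params: GeometryParams,
                     centerline_y_mm: float) -> list[Segment]:
    """Thick-segment representation of the two leaflets.

    The *upper* leaflet (positive y side) is the affected one by convention.
    Each leaflet pivots about a fixed hinge on the valve plane at
    ``centerline +/- hinge_offset``; its tip sweeps toward the wall as the
    leaflet closes, sealing the lateral orifice against the housing ring.
    """
    functional_deg, affected_deg = leaflet_angles(dysfunction_pct, params)
    xv = params.valve_plane_x_mm
    L = params.leaflet_length_mm
    f = params.pivot_fraction
    segs: list[Segment] = []
    for sign, angle_deg in ((+1.0, affected_deg), (-1.0, functional_deg)):
        theta = math.radians(angle_deg)
        py = centerline_y_mm + sign * params.hinge_offset_mm
        ex, ey = math.sin(theta), sign * math.cos(theta)
        x0, y0 = xv - f * L * ex, py - f * L * ey          # centerline-side end
        x1, y1 = xv + (1.0 - f) * L * ex, py + (1.0 - f) * L * ey  # wall-side tip
        segs.append((x0, y0, x1, y1, params.leaflet_thickness_mm))
    return segs


def _half_width_mm(x: np.ndarray, d_mm: float, params: GeometryParams) -> np.ndarray:
    """Fluid half-width of the channel as a function of streamwise position."""
    xv = params.valve_plane_x_mm
    half = np.full_like(x, params.aorta_width_mm / 2.0)
    half[x < xv - params.housing_axial_mm] = d_mm / 2.0
    housing = (x >= xv - params.housing_axial_mm) & (x < xv)
    half[housing] = params.aorta_width_mm / 2.0 - params.housing_ring_mm
    sinus = (x >= xv) & (x < xv + params.sinus_length_mm)
    half[sinus] = (params.aorta_width_mm / 2.0
                   + params.sinus_bulge_depth_mm
                   * np.sin(np.pi * (x[sinus] - xv) / params.sinus_length_mm))
    return half


def build_geometry(case: CaseSpec, params: GeometryParams | None = None) -> SolidMask:
    """Rasterize the full case geometry onto a uniform Cartesian grid.

    The mask is mirror-symmetric about the channel centerline for a healthy
    valve (cell-exact: the cross-stream cell count is even and all wall and
    leaflet tests are functions of |y - centerline|).
    """
    params = params or GeometryParams()
    h = params.grid_spacing_mm
    d = case.lvot_diameter_mm

    # symmetric y grid: even number of rows about the centerline, plus walls
    half_height = params.aorta_width_mm / 2.0 + params.sinus_bulge_depth_mm
    n_half = int(math.ceil(half_height / h)) + 1  # at least one solid wall row
    ny = 2 * n_half
    yc_off = (np.arange(ny) + 0.5 - n_half) * h   # y - centerline, exactly antisymmetric
    centerline = n_half * h

    nx = int(math.ceil(params.domain_length_mm / h))
    xc = (np.arange(nx) + 0.5) * h

    half_w = _half_width_mm(xc, d, params)
    solid = np.abs(yc_off)[None, :] > half_w[:, None]

    leafs = leaflet_segments(case.dysfunction_pct, params, centerline)
    solid |= rasterize_segments(leafs, nx, ny, h)

    # Solidify fluid pockets not connected to the outlet (e.g. sealed corners
    # behind a closed leaflet) so the flow domain is a single open channel.
    from scipy import ndimage
    labels, _ = ndimage.label(~solid, structure=np.array([[0, 1, 0],
                                                          [1, 1, 1],
                                                          [0, 1, 0]]))
    outlet_labels = set(np.unique(labels[-1, :])) - {0}
    inlet_labels = set(np.unique(labels[0, :])) - {0}
    if not outlet_labels & inlet_labels:
        raise GeometryError("inlet and outlet are not connected by fluid")
    keep = np.isin(labels, sorted(outlet_labels & inlet_labels))
    solid = ~keep

    # region labels
    xv = params.valve_plane_x_mm
    tip_reach = (1.0 - params.pivot_fraction) * params.leaflet_length_mm
    band_hi_mm = xv + tip_reach * math.sin(math.radians(params.open_angle_deg)) + h
    region = np.full((nx, ny), int(Region.AORTA), dtype=np.int8)
    region[xc < xv - params.housing_axial_mm, :] = int(Region.LVOT)
    band = (xc >= xv - params.housing_axial_mm) & (xc < xv + h)
    region[band, :] = int(Region.VALVE_PLANE)
    sinus = (xc >= xv + h) & (xc < xv + params.sinus_length_mm)
    region[sinus, :] = int(Region.SINUS)
    region[solid] = int(Region.SOLID)

    i0 = int(np.searchsorted(xc, xv - params.housing_axial_mm))
    i1 = int(np.searchsorted(xc, band_hi_mm))
    mask = SolidMask(solid=solid, region=region, spacing_mm=h,
                     valve_plane_x_mm=xv, valve_band=(i0, min(i1, nx)),
                     lvot_diameter_mm=d)

    _validate_mask(mask, case, params)
    return mask


def _validate_mask(mask: SolidMask, case: CaseSpec, params: GeometryParams) -> None:
    h = mask.spacing_mm
    inlet_open = np.count_nonzero(~mask.solid[0, :]) * h
    if abs(inlet_open - case.lvot_diameter_mm) > h + 1e-9:
        raise GeometryError(
            f"inlet opening {inlet_open:.2f} mm differs from the LVOT diameter "
            f"{case.lvot_diameter_mm} mm by more than one cell")
    outlet_open = np.count_nonzero(~mask.solid[-1, :]) * h
    if abs(outlet_open - params.aorta_width_mm) > h + 1e-9:
        raise GeometryError(
            f"outlet opening {outlet_open:.2f} mm differs from the aorta width")
    if not (mask.solid[:, 0].all() and mask.solid[:, -1].all()):
        raise GeometryError("domain boundary rows must be solid channel walls")
    if not orifice_gaps(mask):
        raise GeometryError("valve plane fully occluded: no fluid orifice")


def orifice_gaps(mask: SolidMask) -> list[tuple[float, float]]:
    """Fluid orifices across the valve, as (y_start, y_end) intervals in mm.

    Solids are projected along x over the valve band (housing plus leaflet
    sweep), so an orifice is a cross-stream interval that is open along the
    whole band — the path a jet actually threads between the leaflets.
    """
    i0, i1 = mask.valve_band
    if i1 <= i0:
        raise GeometryError("valve band is empty; was the mask built by build_geometry?")
    blocked = mask.solid[i0:i1, :].any(axis=0)
    gaps: list[tuple[float, float]] = []
    h = mask.spacing_mm
    j = 0
    ny = blocked.size
    while j < ny:
        if not blocked[j]:
            j0 = j
            while j < ny and not blocked[j]:
                j += 1
            gaps.append((j0 * h + mask.origin_mm[1], j * h + mask.origin_mm[1]))
        else:
            j += 1
    return gaps


def orifice_widths(mask: SolidMask) -> list[float]:
    """Widths (mm) of the valve orifices, ordered from the lower wall upward."""
    gaps = orifice_gaps(mask)
    if not gaps:
        raise GeometryError("valve plane fully occluded: no fluid orifice")
    return [hi - lo for lo, hi in gaps]
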