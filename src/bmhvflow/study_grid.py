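"""Study parameter space, physical constants and nondimensional numbers.

The study grid crosses subaortic-stenosis severity (LVOT hydraulic diameter
27..19 mm in 2 mm steps), one-leaflet dysfunction (0 / 50 / 100 % opening
restriction of a single leaflet) and mean cardiac output (3 / 5 / 7 L/min)
at a fixed heart rate of 70 bpm — 45 cases in total, 15 per cardiac output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigurationError, DomainError

ALLOWED_LVOT_DIAMETERS_MM = (27.0, 25.0, 23.0, 21.0, 19.0)
ALLOWED_DYSFUNCTION_PCT = (0.0, 50.0, 100.0)
ALLOWED_CARDIAC_OUTPUTS_L_MIN = (3.0, 5.0, 7.0)

#: Valve annulus / aorta reference diameter of the modelled 27 mm bileaflet valve.
REFERENCE_DIAMETER_MM = 27.0


@dataclass(frozen=True)
class PhysicalProperties:
    """Newtonian blood properties (large-artery approximation)."""

    density: float = 1060.0  # kg/m^3
    dynamic_viscosity: float = 0.0035  # Pa.s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise DomainError("density and dynamic_viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho in m^2/s."""
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class CaseSpec:
    """One point of the study grid.

    ``dysfunction_pct`` is the opening restriction of a single leaflet: 0 %
    is a healthy valve, 50 % an intermediate leaflet position and 100 % a
    fully closed (stuck) leaflet.
    """

    lvot_diameter_mm: float
    dysfunction_pct: float
    cardiac_output_l_min: float
    heart_rate_bpm: float = 70.0
    systole_duration_s: float = 0.3

    def __post_init__(self) -> None:
        if self.lvot_diameter_mm not in ALLOWED_LVOT_DIAMETERS_MM:
            raise ConfigurationError(
                f"lvot_diameter_mm={self.lvot_diameter_mm} not in "
                f"{ALLOWED_LVOT_DIAMETERS_MM}"
            )
        if self.dysfunction_pct not in ALLOWED_DYSFUNCTION_PCT:
            raise ConfigurationError(
                f"dysfunction_pct={self.dysfunction_pct} not in "
                f"{ALLOWED_DYSFUNCTION_PCT}"
            )
        if self.cardiac_output_l_min not in ALLOWED_CARDIAC_OUTPUTS_L_MIN:
            raise ConfigurationError(
                f"cardiac_output_l_min={self.cardiac_output_l_min} not in "
                f"{ALLOWED_CARDIAC_OUTPUTS_L_MIN}"
            )
        if self.heart_rate_bpm <= 0:
            raise ConfigurationError("heart_rate_bpm must be positive")
        if not self.systole_duration_s < 60.0 / self.heart_rate_bpm:
            raise ConfigurationError(
                "systole_duration_s must be shorter than the cycle period"
            )

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def case_id(self) -> str:
        d = int(round(self.lvot_diameter_mm))
        f = int(round(self.dysfunction_pct))
        q = int(round(self.cardiac_output_l_min))
        return f"d{d}_f{f}_q{q}"


@dataclass(frozen=True)
class GridConfig:
    """Parameter lists defining a (sub-)grid of the study."""

    lvot_diameters_mm: Sequence[float] = ALLOWED_LVOT_DIAMETERS_MM
    dysfunction_levels_pct: Sequence[float] = ALLOWED_DYSFUNCTION_PCT
    cardiac_outputs_l_min: Sequence[float] = ALLOWED_CARDIAC_OUTPUTS_L_MIN


@dataclass(frozen=True)
class NondimensionalSummary:
    re_peak: float
    re_mean: float
    womersley_alpha: float

    def __post_init__(self) -> None:
        if not (self.re_peak >= self.re_mean >= 0):
            raise DomainError("expected re_peak >= re_mean >= 0")
        if not self.womersley_alpha > 0:
            raise DomainError("womersley_alpha must be positive")


def _check_allowed(values: Iterable[float], allowed: Sequence[float], name: str) -> list[float]:
    values = [float(v) for v in values]
    if not values:
        raise ConfigurationError(f"{name} must be a non-empty list")
    for v in values:
        if v not in allowed:
            raise ConfigurationError(f"{name}: value {v} not in allowed set {allowed}")
    return values


def enumerate_cases(grid_config: GridConfig | None = None) -> list[CaseSpec]:
    """Enumerate the Cartesian product of the configured parameter lists.

    Ordering is deterministic: dysfunction level outermost, LVOT diameter in
    the middle, cardiac output innermost — so outputs are byte-stable.
    """
    cfg = grid_config or GridConfig()
    diameters = _check_allowed(cfg.lvot_diameters_mm, ALLOWED_LVOT_DIAMETERS_MM,
                               "lvot_diameters_mm")
    dysfunctions = _check_allowed(cfg.dysfunction_levels_pct, ALLOWED_DYSFUNCTION_PCT,
                                  "dysfunction_levels_pct")
    outputs = _check_allowed(cfg.cardiac_outputs_l_min, ALLOWED_CARDIAC_OUTPUTS_L_MIN,
                             "cardiac_outputs_l_min")
    return [
        CaseSpec(lvot_diameter_mm=d, dysfunction_pct=f, cardiac_output_l_min=q)
        for f in dysfunctions
        for d in diameters
        for q in outputs
    ]


def stenosis_area_reduction(d_mm: float) -> float:
    """Cross-sectional area reduction of a tunnel stenosis of diameter ``d_mm``.

    The hydraulic diameter is interpreted as a circular cross-section against
    the 27 mm reference: 1 - (d/27)^2.  A 19 mm LVOT is a ~50 % reduction.
    """
    if not 0 < d_mm <= REFERENCE_DIAMETER_MM:
        raise DomainError(f"d_mm must lie in (0, {REFERENCE_DIAMETER_MM}], got {d_mm}")
    return 1.0 - (d_mm / REFERENCE_DIAMETER_MM) ** 2


def valve_area_restriction(dysfunction_pct: float) -> float:
    """Fraction of the *total* valve area restricted by one-leaflet dysfunction.

    With two symmetric leaflets, restricting one leaflet by p % restricts the
    total valve area by p/2 %: 50 % -> 0.25, 100 % -> 0.50.
    """
    if not 0 <= dysfunction_pct <= 100:
        raise DomainError(f"dysfunction_pct must lie in [0, 100], got {dysfunction_pct}")
    return dysfunction_pct / 200.0


def reynolds_number(velocity: float, diameter: float,
                    props: PhysicalProperties = PhysicalProperties()) -> float:
    """Re = rho * V * D / mu (SI units)."""
    if diameter <= 0:
        raise DomainError("diameter must be positive")
    return props.density * velocity * diameter / props.dynamic_viscosity


def womersley_number(radius: float, heart_rate_bpm: float,
                     props: PhysicalProperties = PhysicalProperties()) -> float:
    """alpha = R * sqrt(omega / nu) with omega = 2*pi*f, f the heart rate in Hz."""
    if radius < 0:
        raise DomainError("radius must be non-negative")
    if heart_rate_bpm <= 0:
        raise DomainError("heart_rate_bpm must be positive")
    omega = 2.0 * math.pi * heart_rate_bpm / 60.0
    return radius * math.sqrt(omega / props.kinematic_viscosity)


def nondimensional_summary(case: CaseSpec,
                           props: PhysicalProperties = PhysicalProperties()
                           ) -> NondimensionalSummary:
    """Peak/mean Reynolds numbers and Womersley number for one case.

    Velocity scales come from the half-sine systolic waveform: the cycle-mean
    inlet velocity and its peak (mean * (period/systole) * pi/2), through the
    circular LVOT cross-section of the case's hydraulic diameter.
    """
    d_m = case.lvot_diameter_mm * 1e-3
    area = math.pi * d_m ** 2 / 4.0
    q_mean = case.cardiac_output_l_min / 60000.0  # m^3/s
    v_mean = q_mean / area
    v_peak = v_mean * (case.period_s / case.systole_duration_s) * math.pi / 2.0
    return NondimensionalSummary(
        re_peak=reynolds_number(v_peak, d_m, props),
        re_mean=reynolds_number(v_mean, d_m, props),
        womersley_alpha=womersley_number(d_m / 2.0, case.heart_rate_bpm, props),
    )
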