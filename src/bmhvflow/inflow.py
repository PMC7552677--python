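"""Pulsatile inflow waveform and analytic verification / fixture fields.

The systolic inflow is modelled as a half-sine pulse: zero through diastole
and ``Q(t) = Qpeak * sin(pi t / tau)`` over the systolic window ``tau``, with
``Qpeak = CO * (T/tau) * (pi/2)`` so the cycle mean equals the prescribed
cardiac output.  The oscillatory plane-channel (Womersley) closed form serves
as the solver's verification oracle, and ``synthetic_jet_field`` produces
velocity snapshots with exactly prescribed jet maxima so the Doppler stages
can be tested without running the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .geometry import Region, SolidMask
from .study_grid import CaseSpec


@dataclass
class Waveform:
    """Volumetric inflow over one cardiac cycle (3D-equivalent L/min)."""

    t: np.ndarray
    q_l_min: np.ndarray
    systole_duration_s: float
    period_s: float
    q_peak_l_min: float  # analytic peak, exact regardless of sampling

    @property
    def mean_l_min(self) -> float:
        return float(np.mean(self.q_l_min))

    @property
    def q_peak_cm3_s(self) -> float:
        return self.q_peak_l_min * 1000.0 / 60.0

    def q_at(self, t: float | np.ndarray) -> np.ndarray:
        """Analytic half-sine evaluation at arbitrary times (cycle-periodic)."""
        tau = self.systole_duration_s
        tc = np.mod(np.asarray(t, dtype=float), self.period_s)
        return np.where(tc < tau,
                        self.q_peak_l_min * np.sin(np.pi * tc / tau), 0.0)


def half_sine_waveform(cardiac_output_l_min: float, heart_rate_bpm: float = 70.0,
                       systole_duration_s: float = 0.3,
                       n_samples: int = 512) -> Waveform:
    """Half-sine systolic waveform for arbitrary (non-grid) parameters.

    The amplitude is scaled so the cycle mean equals the cardiac output:
    ``Qpeak = CO * (T/tau) * pi/2``; zero cardiac output gives the
    identically zero waveform.
    """
    if n_samples < 50:
        raise DomainError("n_samples must be at least 50 per cycle")
    if heart_rate_bpm <= 0 or systole_duration_s <= 0:
        raise DomainError("heart rate and systole duration must be positive")
    T = 60.0 / heart_rate_bpm
    tau = systole_duration_s
    if tau >= T:
        raise DomainError("systole must be shorter than the cycle period")
    q_peak = cardiac_output_l_min * (T / tau) * math.pi / 2.0
    t = np.linspace(0.0, T, n_samples, endpoint=False)
    q = np.where(t < tau, q_peak * np.sin(np.pi * t / tau), 0.0)
    return Waveform(t=t, q_l_min=q, systole_duration_s=tau, period_s=T,
                    q_peak_l_min=q_peak)


def pulsatile_waveform(case: CaseSpec, n_samples: int = 512) -> Waveform:
    """Half-sine systolic waveform whose cycle mean equals the case's cardiac
    output."""
    return half_sine_waveform(case.cardiac_output_l_min, case.heart_rate_bpm,
                              case.systole_duration_s, n_samples)


def plug_velocity(q_l_min: float | np.ndarray, diameter_mm: float) -> float | np.ndarray:
    """Mean (plug) velocity in m/s through a circular area of given diameter.

    The 3D-equivalent flow rate is mapped to the 2D inlet through the circular
    LVOT cross-section: U = Q / (pi D^2 / 4).
    """
    if diameter_mm <= 0:
        raise DomainError("diameter_mm must be positive")
    area_m2 = math.pi * (diameter_mm * 1e-3) ** 2 / 4.0
    return np.asarray(q_l_min, dtype=float) / 60000.0 / area_m2


def inlet_velocity(waveform: Waveform, diameter_mm: float, t: float) -> float:
    """Plug inlet velocity (m/s) at time ``t`` for the given hydraulic diameter."""
    return float(plug_velocity(waveform.q_at(t), diameter_mm))


def womersley_profile(pressure_gradient_amplitude: float, alpha: float,
                      phase: float, y: np.ndarray, half_width: float = 1.0,
                      density: float = 1.0,
                      kinematic_viscosity: float = 1.0) -> np.ndarray:
    """Oscillatory plane-channel velocity profile (closed form).

    The flow is driven by the streamwise pressure gradient
    ``-(1/rho) dp/dx = (G/rho) cos(omega t)``; with ``Lambda^2 = i alpha^2``
    the periodic solution is

        u(y, t) = Re{ (G / (i rho omega)) [1 - cosh(Lambda y/h) / cosh(Lambda)]
                      e^{i omega t} }

    evaluated here at phase ``omega t = phase``.  ``y`` are positions in
    [-half_width, half_width]; the angular frequency follows from the
    Womersley number: ``omega = alpha^2 * nu / half_width^2``.  In the
    quasi-steady limit alpha -> 0 the profile tends to the parabolic
    Poiseuille profile ``G (h^2 - y^2) cos(phase) / (2 rho nu)``; at the
    walls it vanishes (no-slip).
    """
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    y = np.asarray(y, dtype=float)
    nu = kinematic_viscosity
    omega = alpha ** 2 * nu / half_width ** 2
    lam = alpha * np.sqrt(1j)
    amp = (pressure_gradient_amplitude / (1j * density * omega)) * (
        1.0 - np.cosh(lam * y / half_width) / np.cosh(lam))
    return np.real(amp * np.exp(1j * phase))


@dataclass
class AnalyticField:
    """Velocity snapshot produced by a closed form (verification / fixture).

    ``u`` and ``v`` are cell-centered (same shape as the mask), unlike the
    staggered solver fields; downstream consumers accept either layout.
    """

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0
    provenance: dict = field(default_factory=dict)


def synthetic_jet_field(vpeak_target: float, vlvot_target: float,
                        mask: SolidMask) -> AnalyticField:
    """Smooth cell-centered speed field with exactly prescribed region maxima.

    The maximum speed over the downstream (sinus + aorta) fluid cells equals
    ``vpeak_target`` and the maximum over the LVOT fluid cells equals
    ``vlvot_target`` (both exactly, by normalization); the field is zero on
    solids.  Used as a fixture for the Doppler metrics stage.
    """
    if not (vpeak_target >= vlvot_target >= 0):
        raise DomainError("require vpeak_target >= vlvot_target >= 0")
    nx, ny = mask.shape
    u = np.zeros((nx, ny))
    X, Y = np.meshgrid(mask.x_centers_mm(), mask.y_centers_mm(), indexing="ij")

    for labels, target in (((Region.SINUS, Region.AORTA), vpeak_target),
                           ((Region.LVOT,), vlvot_target)):
        if target == 0.0:
            continue
        sel = np.isin(mask.region, [int(r) for r in labels]) & mask.fluid
        if not sel.any():
            raise DomainError(f"no fluid cells in region(s) {labels}")
        x0, y0 = X[sel].mean(), Y[sel].mean()
        sigma = max(np.ptp(X[sel]), np.ptp(Y[sel]), mask.spacing_mm) / 4.0
        bump = np.exp(-(((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * sigma ** 2)))
        bump[~sel] = 0.0
        u += target * (bump / bump.max())

    return AnalyticField(u=u, v=np.zeros_like(u),
                         provenance={"kind": "synthetic_jet_field",
                                     "vpeak_target": vpeak_target,
                                     "vlvot_target": vlvot_target})
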