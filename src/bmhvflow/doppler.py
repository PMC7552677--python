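"""Clinical Doppler surrogates: Vpeak, V_LVOT, TPGmean, DVI, EOA.

Definitions follow echocardiographic practice:

* Vpeak — maximum blood speed downstream of the valve (sinus + aorta) over
  systole (m/s);
* V_LVOT — maximum speed in an LVOT sample volume one diameter upstream of
  the valve plane (m/s);
* TPG — simplified-Bernoulli transvalvular pressure gradient 4 V^2 (mmHg
  with V in m/s); TPGmean is its time average over systole;
* DVI = V_LVOT / Vpeak (dimensionless);
* EOA = Qpeak / Vpeak (cm^2 with Q in cm^3/s and V in cm/s), the
  vena-contracta area of the transvalvular jet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, UndefinedMetricError
from .fields import cell_center_velocity, peak_over, region_selector
from .geometry import Region, SolidMask
from .inflow import Waveform
from .study_grid import CaseSpec

#: Simplified-Bernoulli coefficient: mmHg per (m/s)^2.
BERNOULLI_MMHG_PER_M2S2 = 4.0


def bernoulli_tpg(v: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous simplified-Bernoulli gradient 4 v^2 (mmHg, v in m/s)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise DomainError("velocity must be non-negative")
    out = BERNOULLI_MMHG_PER_M2S2 * v ** 2
    return float(out) if out.ndim == 0 else out


def tpg_mean(v_of_t: np.ndarray, t: np.ndarray | None = None) -> float:
    """Trapezoidal time average of the simplified-Bernoulli gradient (mmHg).

    ``v_of_t`` are velocity samples over the systolic window; ``t`` defaults
    to uniform spacing.
    """
    v = np.asarray(v_of_t, dtype=float)
    if v.size < 2:
        raise DomainError("need at least 2 samples within systole")
    tpg = bernoulli_tpg(v)
    if t is None:
        return float(np.trapezoid(tpg, dx=1.0) / (v.size - 1))
    t = np.asarray(t, dtype=float)
    span = t[-1] - t[0]
    if span <= 0:
        raise DomainError("time samples must be increasing")
    return float(np.trapezoid(tpg, t) / span)


def dvi(v_lvot: float, v_peak: float) -> float:
    """Doppler velocity index V_LVOT / Vpeak (no clamping)."""
    if v_peak <= 0:
        raise UndefinedMetricError("DVI undefined for v_peak <= 0")
    return v_lvot / v_peak


def eoa(q_peak_cm3_s: float, v_peak_cm_s: float) -> float:
    """Effective orifice area Q/Vpeak (cm^2; Q in cm^3/s, V in cm/s)."""
    if q_peak_cm3_s < 0:
        raise DomainError("q_peak must be non-negative")
    if v_peak_cm_s <= 0:
        raise UndefinedMetricError("EOA undefined for v_peak <= 0")
    return q_peak_cm3_s / v_peak_cm_s


def percent_change(baseline: float, new: float) -> float:
    """100 * (new - baseline) / baseline; rounding is the caller's choice."""
    if baseline == 0:
        raise DomainError("percent_change undefined for zero baseline")
    return 100.0 * (new - baseline) / baseline


@dataclass(frozen=True)
class DopplerReport:
    """The five clinical surrogates for one case."""

    v_peak: float   # m/s
    v_lvot: float   # m/s
    tpg_mean: float  # mmHg
    dvi: float
    eoa: float      # cm^2
    case: CaseSpec | None = None

    @property
    def case_id(self) -> str | None:
        return self.case.case_id if self.case is not None else None

    def as_dict(self) -> dict:
        d = {"v_peak": self.v_peak, "v_lvot": self.v_lvot,
             "tpg_mean": self.tpg_mean, "dvi": self.dvi, "eoa": self.eoa}
        if self.case is not None:
            d["case_id"] = self.case_id
        return d


def lvot_probe_selector(mask: SolidMask, case: CaseSpec,
                        probe_halfwidth_mm: float = 2.0) -> np.ndarray:
    """LVOT sample volume one diameter upstream of the valve plane.

    Mimics echo sample-volume placement: a short axial band of LVOT fluid
    cells centered ``lvot_diameter`` upstream of the valve plane.
    """
    x = mask.x_centers_mm()
    x_probe = mask.valve_plane_x_mm - case.lvot_diameter_mm
    band = np.abs(x - x_probe) <= probe_halfwidth_mm
    sel = band[:, None] & (mask.region == int(Region.LVOT)) & mask.fluid
    if not sel.any():
        raise DomainError("LVOT probe region is empty; domain too short?")
    return sel


def _speed_trace(series: Sequence, mask: SolidMask, sel: np.ndarray,
                 t0: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-snapshot max speed over ``sel`` and cycle-relative times."""
    speeds, times = [], []
    for snap in sorted(series, key=lambda s: s.t):
        uc, vc = cell_center_velocity(snap.u, snap.v, mask.fluid)
        speeds.append(float(np.hypot(uc, vc)[sel].max()))
        times.append(snap.t - t0)
    return np.asarray(speeds), np.asarray(times)


def doppler_report(series: Sequence, mask: SolidMask, waveform: Waveform,
                   case: CaseSpec, cycle_start_s: float = 0.0,
                   probe_halfwidth_mm: float = 2.0) -> DopplerReport:
    """Assemble the five Doppler surrogates from final-cycle snapshots.

    Vpeak and V_LVOT are systolic peaks of the downstream and LVOT-probe
    speed traces; TPGmean averages 4 V(t)^2 over the systolic window of the
    downstream trace; EOA uses the waveform's (3D-equivalent) peak flow.
    """
    series = list(series)
    if not series:
        raise DomainError("doppler_report requires at least one snapshot")
    downstream = region_selector(mask, (Region.SINUS, Region.AORTA))
    probe = lvot_probe_selector(mask, case, probe_halfwidth_mm)

    tau = waveform.systole_duration_s
    ds_speed, times = _speed_trace(series, mask, downstream, cycle_start_s)
    lv_speed, _ = _speed_trace(series, mask, probe, cycle_start_s)
    systole = (times >= 0.0) & (times <= tau + 1e-9)
    if np.count_nonzero(systole) < 2:
        raise DomainError("snapshot series does not cover the systolic window")

    v_peak = float(ds_speed[systole].max())
    v_lvot = float(lv_speed[systole].max())
    if v_peak <= 0:
        raise UndefinedMetricError("zero flow: Doppler surrogates undefined")
    tpg = tpg_mean(ds_speed[systole], times[systole])
    return DopplerReport(v_peak=v_peak, v_lvot=v_lvot, tpg_mean=tpg,
                         dvi=dvi(v_lvot, v_peak),
                         eoa=eoa(waveform.q_peak_cm3_s, v_peak * 100.0),
                         case=case)
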