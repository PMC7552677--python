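"""File output: VTK-style snapshots, portable array containers, manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .geometry import SolidMask
from .solver import CaseRun, FlowField


def write_rectilinear_vtk(path: str | Path, mask: SolidMask,
                          cell_data: Mapping[str, np.ndarray] | None = None,
                          title: str = "bmhvflow snapshot") -> Path:
    """Write a legacy-ASCII VTK rectilinear grid with cell-centered data.

    Coordinates are in mm; each data array must have the mask's cell shape.
    """
    path = Path(path)
    nx, ny = mask.shape
    h = mask.spacing_mm
    ox, oy = mask.origin_mm
    xs = ox + h * np.arange(nx + 1)
    ys = oy + h * np.arange(ny + 1)
    data = {"solid": mask.solid.astype(np.int8),
            "region": mask.region}
    if cell_data:
        data.update(cell_data)

    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        for name, vals in (("X", xs), ("Y", ys), ("Z", np.array([0.0]))):
            fh.write(f"{name}_COORDINATES {vals.size} float\n")
            fh.write(" ".join(f"{v:g}" for v in vals) + "\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.shape != (nx, ny):
                raise ValueError(f"cell data {name!r} has shape {arr.shape}, "
                                 f"expected {(nx, ny)}")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK cell ordering: x fastest
            fh.write("\n".join(" ".join(f"{v:.6g}" for v in arr[:, j])
                               for j in range(ny)) + "\n")
    return path


def save_run_npz(path: str | Path, run: CaseRun) -> Path:
    """Portable array container for one case run (final-cycle snapshots)."""
    path = Path(path)
    u = np.stack([s.u for s in run.snapshots])
    v = np.stack([s.v for s in run.snapshots])
    p = np.stack([s.p for s in run.snapshots])
    t = np.array([s.t for s in run.snapshots])
    payload = dict(u=u, v=v, p=p, t=t,
                   solid=run.mask.solid, region=run.mask.region,
                   spacing_mm=run.mask.spacing_mm,
                   valve_plane_x_mm=run.mask.valve_plane_x_mm,
                   valve_band=np.array(run.mask.valve_band),
                   lvot_diameter_mm=run.mask.lvot_diameter_mm,
                   cycle_start_s=run.cycle_start_s,
                   waveform_t=run.waveform.t, waveform_q=run.waveform.q_l_min,
                   q_peak_l_min=run.waveform.q_peak_l_min,
                   systole_duration_s=run.waveform.systole_duration_s,
                   period_s=run.waveform.period_s,
                   case_lvot_diameter_mm=run.case.lvot_diameter_mm,
                   case_dysfunction_pct=run.case.dysfunction_pct,
                   case_cardiac_output_l_min=run.case.cardiac_output_l_min,
                   case_heart_rate_bpm=run.case.heart_rate_bpm)
    if run.nu_t_snapshots:
        payload["nu_t"] = np.stack(run.nu_t_snapshots)
    np.savez_compressed(path, **payload)
    return path


def load_snapshots_npz(path: str | Path) -> tuple[list[FlowField], SolidMask, dict]:
    """Load a run container back into snapshots + mask + metadata."""
    from .inflow import Waveform
    with np.load(Path(path)) as z:
        mask = SolidMask(solid=z["solid"].astype(bool),
                         region=z["region"],
                         spacing_mm=float(z["spacing_mm"]),
                         valve_plane_x_mm=float(z["valve_plane_x_mm"]),
                         valve_band=tuple(int(i) for i in z["valve_band"]),
                         lvot_diameter_mm=float(z["lvot_diameter_mm"]))
        snaps = [FlowField(u=z["u"][i], v=z["v"][i], p=z["p"][i],
                           t=float(z["t"][i])) for i in range(z["t"].size)]
        meta = {"cycle_start_s": float(z["cycle_start_s"]),
                "waveform": Waveform(t=z["waveform_t"], q_l_min=z["waveform_q"],
                                     systole_duration_s=float(z["systole_duration_s"]),
                                     period_s=float(z["period_s"]),
                                     q_peak_l_min=float(z["q_peak_l_min"]))}
        if "case_lvot_diameter_mm" in z:
            from .study_grid import CaseSpec
            meta["case"] = CaseSpec(
                lvot_diameter_mm=float(z["case_lvot_diameter_mm"]),
                dysfunction_pct=float(z["case_dysfunction_pct"]),
                cardiac_output_l_min=float(z["case_cardiac_output_l_min"]),
                heart_rate_bpm=float(z["case_heart_rate_bpm"]))
        if "nu_t" in z:
            meta["nu_t"] = z["nu_t"]
    return snaps, mask, meta


@dataclass
class RunManifest:
    """Provenance sidecar for one pipeline invocation."""

    command: str
    case_ids: list[str]
    config_snapshot: dict
    outputs: list[str] = field(default_factory=list)
    periodicity_metrics: dict[str, float] = field(default_factory=dict)
    warning_counts: dict[str, int] = field(default_factory=dict)
    software_version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        if not payload["timestamp"]:
            payload["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path
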