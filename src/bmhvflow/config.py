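"""Structured run configuration: YAML load/save, validation, defaults.

An empty configuration file yields the full default study: the 45-case grid
(5 LVOT diameters x 3 dysfunction levels x 3 cardiac outputs) with the
default geometry, blood properties and solver settings.  Unknown keys are
rejected with their field path so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .geometry import GeometryParams
from .solver import SolverConfig
from .study_grid import GridConfig, PhysicalProperties


@dataclass
class RunConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    properties: PhysicalProperties = field(default_factory=PhysicalProperties)
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        return {
            "grid": dataclasses.asdict(self.grid),
            "geometry": dataclasses.asdict(self.geometry),
            "solver": dataclasses.asdict(self.solver),
            "properties": dataclasses.asdict(self.properties),
            "output_dir": self.output_dir,
        }


_SECTIONS = {
    "grid": GridConfig,
    "geometry": GeometryParams,
    "solver": SolverConfig,
    "properties": PhysicalProperties,
}


def _build_section(cls, payload: dict, path: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} under '{path}'")
    try:
        kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in payload.items()}
        return cls(**kwargs)
    except ConfigurationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file (empty file = defaults)."""
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    unknown = set(payload) - set(_SECTIONS) - {"output_dir"}
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
    sections = {name: _build_section(cls, payload.get(name, {}) or {}, name)
                for name, cls in _SECTIONS.items()}
    # validate grid values against the allowed study sets eagerly
    from .study_grid import enumerate_cases
    enumerate_cases(sections["grid"])
    return RunConfig(output_dir=str(payload.get("output_dir", "runs")), **sections)


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Write a configuration so that save -> load round-trips identically."""
    path = Path(path)
    payload = config.to_dict()
    # YAML-friendly: tuples become lists
    payload["grid"] = {k: list(v) for k, v in payload["grid"].items()}
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path
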