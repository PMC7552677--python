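import numpy as np
import pytest

from bmhvflow import CaseSpec, GeometryParams, build_geometry
from bmhvflow.geometry import Region, SolidMask


@pytest.fixture(scope="session")
def healthy_case() -> CaseSpec:
    return CaseSpec(lvot_diameter_mm=27.0, dysfunction_pct=0.0,
                    cardiac_output_l_min=5.0)


@pytest.fixture(scope="session")
def healthy_mask(healthy_case) -> SolidMask:
    return build_geometry(healthy_case, GeometryParams())


@pytest.fixture(scope="session")
def open_box_mask() -> SolidMask:
    """All-fluid mask (no walls) for homogeneous-turbulence checks."""
    nx = ny = 16
    return SolidMask(solid=np.zeros((nx, ny), dtype=bool),
                     region=np.full((nx, ny), int(Region.AORTA), dtype=np.int8),
                     spacing_mm=10.0, valve_plane_x_mm=0.0, valve_band=(0, 1),
                     lvot_diameter_mm=27.0)
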