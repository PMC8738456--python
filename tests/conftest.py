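import numpy as np
import pytest

from virtradiol.geometry import AcquisitionGeometry, CassetteFrame
from virtradiol.materials import AttenuationTable, Material, load_attenuation_table


@pytest.fixture(scope="session")
def table() -> AttenuationTable:
    """The packaged per-element attenuation tables."""
    return load_attenuation_table()


@pytest.fixture(scope="session")
def water() -> Material:
    return Material("water", {"H": 0.111894, "O": 0.888106}, density=1.0)


def flat_table(mu: float = 0.2) -> AttenuationTable:
    """Synthetic table with constant mu/rho, for closed-form Beer-Lambert checks."""
    energies = np.array([1.0, 10.0, 50.0, 100.0, 200.0])
    rows = np.column_stack([energies, np.full_like(energies, mu)])
    return AttenuationTable({"H": rows})


def flat_material(name: str = "flat", density: float = 1.0) -> Material:
    return Material(name, {"H": 1.0}, density=density)


def simple_geometry(rows: int = 9, cols: int = 9, width: float = 100.0,
                    height: float = 100.0, sid: float = 1000.0,
                    sod: float = 900.0, collimator=None) -> AcquisitionGeometry:
    """Beam along -y; cassette behind the origin, 'up' along +z."""
    return AcquisitionGeometry(
        focus=np.array([0.0, sid - 100.0, 0.0]),
        cassette=CassetteFrame(
            center=np.array([0.0, -100.0, 0.0]),
            normal=np.array([0.0, 1.0, 0.0]),
            up=np.array([0.0, 0.0, 1.0]),
            width=width, height=height, cols=cols, rows=rows,
        ),
        sid=sid, sod=sod, collimator=collimator,
    )
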