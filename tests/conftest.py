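import numpy as np
import pytest

from pipacsim import CavityGeometry, GasProperties
from pipacsim.droplet_transport import TransportRecords


@pytest.fixture(scope="session")
def geometry():
    return CavityGeometry()


@pytest.fixture(scope="session")
def gas():
    return GasProperties()


def make_records(
    positions,
    diameters=None,
    deposited=None,
    plate_labels=None,
    surfaces=None,
    density=1070.0,
):
    """Hand-built transport records for analysis-layer tests."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    diameters = (
        np.full(n, 30e-6) if diameters is None else np.asarray(diameters, float)
    )
    deposited = (
        np.ones(n, dtype=bool) if deposited is None else np.asarray(deposited, bool)
    )
    if plate_labels is None:
        plate_labels = np.full(n, "", dtype=object)
    else:
        plate_labels = np.asarray(plate_labels, dtype=object)
    if surfaces is None:
        surfaces = np.where(deposited, "bottom", "").astype(object)
    return TransportRecords(
        emission_times=np.zeros(n),
        diameters=diameters,
        density=density,
        charge=0.0,
        final_positions=positions,
        deposited=deposited,
        surfaces=surfaces,
        plate_labels=plate_labels,
        flight_times=np.ones(n),
    )
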