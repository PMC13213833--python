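import numpy as np
import pytest

from microkin.qc_io import Geometry, RawQCRecord


@pytest.fixture
def water_geometry() -> Geometry:
    return Geometry(
        elements=["O", "H", "H"],
        coordinates=[
            (0.0, 0.0, 0.117300),
            (0.0, 0.757200, -0.469200),
            (0.0, -0.757200, -0.469200),
        ],
        comment="water",
    )


@pytest.fixture
def water_record(water_geometry) -> RawQCRecord:
    # plausible harmonic frequencies for a bent triatomic
    return RawQCRecord(
        electronic_energy=-76.4,
        geometry=water_geometry,
        frequencies=[1650.0, 3800.0, 3900.0],
        multiplicity=1,
    )


@pytest.fixture
def argon_record() -> RawQCRecord:
    return RawQCRecord(
        electronic_energy=-527.5,
        geometry=Geometry(["Ar"], [(0.0, 0.0, 0.0)]),
        frequencies=[],
        multiplicity=1,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
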