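import numpy as np
import pytest

from lmdgrid import (
    MicrogridSpec,
    TemplateDocument,
    TemplateMetadata,
    build_microgrid,
)

#: Published per-template characteristics used as fixtures across tests:
#: (name, side um, measured avg area um2, relative bridge %, tissue losses,
#:  capture efficiency %).
TEMPLATE_TABLE = [
    ("500x500", 500.0, 246363.0, 12, 13, 86),
    ("270x270", 270.0, 73483.0, 15, 23, 76),
    ("200x200", 200.0, 39969.0, 13, 17, 82),
    ("100x100", 100.0, 10134.0, 8, 8, 92),
    ("50x50", 50.0, 2563.0, 10, 18, 81),
    ("30x30", 30.0, 923.0, 13, None, None),
]

#: Published tissue LLOQ (ug/g) per template at 40 um thickness.
PRINTED_LLOQ = {
    "500x500": 0.9,
    "270x270": 3.1,
    "200x200": 5.7,
    "100x100": 22.3,
    "50x50": 88.4,
    "30x30": 245.3,
}


@pytest.fixture
def spec_500() -> MicrogridSpec:
    return MicrogridSpec(square_side=500.0, bridge_fraction=0.12)


@pytest.fixture
def grid_500(spec_500):
    return build_microgrid(spec_500)


@pytest.fixture
def doc_500(spec_500, grid_500) -> TemplateDocument:
    return TemplateDocument(
        spec=spec_500,
        squares=grid_500,
        metadata=TemplateMetadata(
            name="500x500",
            created="2024-01-01T00:00:00",
            calibration_points=((0.0, 0.0), (6660.0, 0.0)),
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20241223)
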