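import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from riverbiome import OtuTable, RiverNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_table() -> OtuTable:
    counts = np.array(
        [
            [5, 0, 3],
            [1, 2, 0],
            [10, 20, 30],
        ]
    )
    return OtuTable(
        ["OTU1", "OTU2", "OTU3"],
        ["s1", "s2", "s3"],
        counts,
        ["Bacteria; Proteobacteria", "Bacteria; Bacteroidetes", "Bacteria; Proteobacteria"],
    )


@pytest.fixture
def y_network() -> RiverNetwork:
    # two headwater branches (3 km, 5 km) join at J, then 2 km down to SITE
    return RiverNetwork.from_edges(
        [
            ("A", "J", 3.0, 10.0),
            ("B", "J", 5.0, 20.0),
            ("J", "SITE", 2.0, 5.0),
        ],
        outlet_area_km2=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
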