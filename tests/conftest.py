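import numpy as np
import pytest

from grasshydro.anatomy import (
    ConduitGeometry,
    LeafAnatomy,
    SheathGeometry,
    VeinOrderAnatomy,
)
from grasshydro.synthetic import simulate_tree


@pytest.fixture(scope="session")
def fixture_leaf() -> LeafAnatomy:
    """A fully specified 3-order leaf with simple round-number geometry."""
    return LeafAnatomy(
        species="fixture",
        pathway="C3",
        vein_orders=(
            VeinOrderAnatomy(
                order=1,
                conduits=(
                    ConduitGeometry(30.0, 30.0, "protoxylem_lacuna"),
                    ConduitGeometry(20.0, 15.0, "xylem_I"),
                    ConduitGeometry(20.0, 15.0, "xylem_I"),
                    ConduitGeometry(8.0, 6.0, "xylem_II"),
                ),
                Dv_mm_mm2=0.1,
                sheath=SheathGeometry(12.0, 10, 7.0, 8),
            ),
            VeinOrderAnatomy(
                order=2,
                conduits=(
                    ConduitGeometry(25.0, 25.0, "protoxylem_lacuna"),
                    ConduitGeometry(15.0, 12.0, "xylem_I"),
                    ConduitGeometry(6.0, 5.0, "xylem_II"),
                ),
                Dv_mm_mm2=0.8,
                sheath=SheathGeometry(10.0, 8, 6.0, 8),
            ),
            VeinOrderAnatomy(
                order=3,
                conduits=(
                    ConduitGeometry(5.0, 4.0, "xylem_II"),
                    ConduitGeometry(5.0, 4.0, "xylem_II"),
                ),
                Dv_mm_mm2=4.0,
                sheath=SheathGeometry(10.0, 8, 6.0, 8),
            ),
        ),
        leaf_length_m=0.25,
    )


@pytest.fixture(scope="session")
def tree27():
    return simulate_tree(27, 1.0, seed=1)


@pytest.fixture(scope="session")
def tree50():
    return simulate_tree(50, 1.0, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
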