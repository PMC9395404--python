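import numpy as np
import pytest

from viscocap import CapsuleGeometry, Probe, build_shape_table


@pytest.fixture(scope="session")
def geom_cell():
    """Hemispherical MDCK-like cap, colloidal sphere probe."""
    return CapsuleGeometry(R1=12e-6, probe=Probe("sphere", R_p=3.31e-6))


@pytest.fixture(scope="session")
def table_cell(geom_cell):
    """Shape table deep enough for 2.5 um indentations on the 12 um cap."""
    return build_shape_table(geom_cell, 2.8e-6, n=120)


@pytest.fixture(scope="session")
def table_shallow(geom_cell):
    return build_shape_table(geom_cell, 2.3e-6, n=100)
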