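import pytest

from atrifocus import (
    assign_leads_to_quadrants,
    build_atrial_surface,
    default_layout,
)
from atrifocus.io import load_default_table


@pytest.fixture(scope="session")
def surface():
    return build_atrial_surface()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def assignment(layout):
    return assign_leads_to_quadrants(layout.surface_coords())


@pytest.fixture(scope="session")
def table():
    return load_default_table()
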