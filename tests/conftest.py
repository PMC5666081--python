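import numpy as np
import pytest
from hypothesis import settings

from gagtk import glycan, screening

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_library():
    """The 64-member dp4 toy library (2 IdoA x 4 GlcN variants, IdoA start)."""
    return glycan.enumerate_library(glycan.LibrarySpec())


@pytest.fixture
def cluster1_site():
    return screening.SiteDefinition(
        name="cluster1",
        key_residues=("R58", "K60", "R64", "R67", "K72"),
        center=(0.0, 0.0, 0.0),
        radius=16.0,
    )


@pytest.fixture
def cluster1_basic_atoms():
    return [
        ("R58", (2.0, 0.0, 0.0)),
        ("K60", (0.0, 2.0, 0.0)),
        ("R64", (0.0, 0.0, 2.0)),
        ("R67", (-2.0, 0.0, 0.0)),
        ("K72", (0.0, -2.0, 0.0)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
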