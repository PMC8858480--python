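import hypothesis
import pytest

from drugmine.rif_store import build_rif
from drugmine.synthetic_data import PlantedWorldConfig, generate_world

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def tiny_rif():
    """The worked example: A has 4 publications, B has 2."""
    return build_rif([("A", 1), ("A", 2), ("A", 3), ("A", 4), ("B", 3), ("B", 4)])


@pytest.fixture(scope="session")
def planted_world():
    """Default planted world: 200 drugs, 20 terms, 5000 PMIDs, seed 0."""
    return generate_world(PlantedWorldConfig())


@pytest.fixture(scope="session")
def null_world():
    """World with no planted signal (p_planted == p_background)."""
    return generate_world(PlantedWorldConfig(p_planted=0.01, p_background=0.01))
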