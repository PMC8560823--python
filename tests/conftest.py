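import pytest

from agostruct.interface import SasaParams
from agostruct.synthetic import make_beta_ladder, make_sensorgram_set


@pytest.fixture(scope="session")
def fast_sasa():
    """Reduced point density for tests whose tolerances allow it."""
    return SasaParams(points_per_atom=240)


@pytest.fixture(scope="session")
def beta_ladder9():
    return make_beta_ladder(9)


@pytest.fixture(scope="session")
def parent_sensorgrams():
    """Noiseless ladder from the parental antibody's published rates."""
    return make_sensorgram_set()
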