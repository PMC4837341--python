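import numpy as np
import pandas as pd
import pytest

from cpmi import synthdata


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return synthdata.load_table1()


@pytest.fixture(scope="session")
def table1_components(table1):
    return synthdata.components_from_frame(table1)


@pytest.fixture(scope="session")
def paper_scale_bundle():
    """Default-config synthetic bundle (48/61/44/13, 25 connected)."""
    return synthdata.generate_fixture(synthdata.FixtureConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
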