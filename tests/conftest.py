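import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from terpomics import synthetic

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def worked_fixture() -> synthetic.Bundle:
    return synthetic.make_worked_fixture()


@pytest.fixture(scope="session")
def small_bundle() -> synthetic.Bundle:
    """A reduced random bundle shared by read-only tests."""
    config = synthetic.DesignConfig(
        n_transcripts={"MEP": 3, "UGT": 8, "TF": 6, "ripening": 4, "other": 10},
        n_compounds={"free": 3, "bound": 3},
        total_reads_per_library=1e5,
        n_multiread_groups=4,
        seed=42,
    )
    return synthetic.generate_dataset(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_profiles(rng, n, cells=16, prefix="p") -> pd.DataFrame:
    return pd.DataFrame(
        rng.standard_normal((n, cells)),
        index=[f"{prefix}{i}" for i in range(n)],
        columns=[f"c{i}" for i in range(cells)],
    )
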