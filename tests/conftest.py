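import warnings

import numpy as np
import pandas as pd
import pytest

from phyllonet import OtuTable, SyntheticConfig, generate_community


@pytest.fixture
def tiny_table():
    """3 OTUs x 2 samples with simple counts."""
    counts = pd.DataFrame(
        {"S1": [10, 5, 0], "S2": [0, 5, 12]},
        index=["OTU1", "OTU2", "OTU3"],
    )
    return OtuTable(counts=counts)


@pytest.fixture
def tiny_metadata():
    return pd.DataFrame(
        {
            "source": ["leaf", "leaf"],
            "habitat": ["Quercus_coccifera", "Olea_europaea"],
            "season": ["summer", "winter"],
        },
        index=pd.Index(["S1", "S2"], name="sample_id"),
    )


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic dataset shared across tests (seed 1)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_community(seed=1)


@pytest.fixture(scope="session")
def small_community():
    """A cheap, small synthetic dataset for pipeline-level tests."""
    cfg = SyntheticConfig(n_otus=200, depth=800, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_community(cfg)


def make_table(array, otu_ids=None, sample_ids=None) -> OtuTable:
    array = np.asarray(array)
    otu_ids = otu_ids or [f"OTU{i}" for i in range(array.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(array.shape[1])]
    return OtuTable(counts=pd.DataFrame(array, index=otu_ids, columns=sample_ids))
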