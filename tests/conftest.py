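import numpy as np
import pandas as pd
import pytest

from sedimeta.io import FeatureTable
from sedimeta.synthetic import StudyConfig, generate_metadata


@pytest.fixture
def small_cfg() -> StudyConfig:
    """A scaled-down study: fast to simulate, same structure as the defaults."""
    return StudyConfig(
        n_samples=16,
        n_exceed=5,
        n_metagenome_per_group=4,
        n_otus=60,
        depth_range=(2_000, 3_000),
        n_background_families=8,
        mean_reads_per_family=60.0,
        seed=11,
    )


@pytest.fixture
def small_metadata(small_cfg):
    return generate_metadata(small_cfg)


@pytest.fixture
def counts_table() -> FeatureTable:
    data = pd.DataFrame(
        {"s1": [6, 2, 0], "s2": [2, 2, 4], "s3": [0, 1, 9]},
        index=["f1", "f2", "f3"],
        dtype=np.int64,
    )
    return FeatureTable(data, units_tag="counts")
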