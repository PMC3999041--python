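import numpy as np
import pandas as pd
import pytest

from nutrinet import (
    FeatureTable,
    SyntheticConfig,
    generate_cohort,
    toy_growth_reference,
)
from nutrinet.profiles import normalize_abundance, rank_normalize


@pytest.fixture(scope="session")
def reference():
    return toy_growth_reference()


@pytest.fixture(scope="session")
def cohort():
    """Default 20-sample synthetic cohort used across modules."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def scored_metadata(cohort):
    return cohort.metadata


@pytest.fixture(scope="session")
def normalized_genus(cohort):
    totals = cohort.metadata.set_index("sample_id")["total_reads"]
    return normalize_abundance(cohort.genus_counts, totals)


@pytest.fixture(scope="session")
def ranked_genus(normalized_genus):
    return rank_normalize(normalized_genus)


@pytest.fixture()
def tiny_table():
    """3 features x 4 samples normalized table with simple structure."""
    data = pd.DataFrame(
        {
            "s1": [0.10, 0.40, 0.02],
            "s2": [0.20, 0.30, 0.02],
            "s3": [0.30, 0.20, 0.02],
            "s4": [0.40, 0.10, 0.02],
        },
        index=["up", "down", "flat"],
    )
    return FeatureTable(data, kind="taxon-genus", state="normalized")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
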