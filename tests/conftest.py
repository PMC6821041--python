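import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lowbiom import (
    ContaminantModel,
    OtuTable,
    SampleMetadata,
    simulate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    return pd.DataFrame(
        [[10, 0], [5, 5], [0, 1]],
        index=["OTU_1", "OTU_2", "OTU_3"],
        columns=["S1", "S2"],
    )


@pytest.fixture
def tiny_table(tiny_counts) -> OtuTable:
    return OtuTable(tiny_counts)


@pytest.fixture
def tiny_meta() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2"],
                "density": [8e5, 8e5],
                "replicate_group": ["R1", "R1"],
            }
        )
    )


def ladder_table(values_by_otu: dict[str, list[float]]) -> tuple[OtuTable, SampleMetadata]:
    """Eight-sample dilution ladder with one sample per density."""
    densities = [8.0 * 10.0**k for k in range(2, 10)]
    samples = [f"S{i + 1}" for i in range(8)]
    counts = pd.DataFrame(values_by_otu, index=samples).T
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "density": densities,
                "replicate_group": [f"G{i + 1}" for i in range(8)],
            }
        )
    )
    return OtuTable(counts), meta


@pytest.fixture(scope="session")
def default_dataset():
    """Seeded default simulation shared across tests (3 x 8 x 2 design)."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def fitted(default_dataset):
    d = default_dataset
    return ContaminantModel(d.table, d.metadata).fit()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_916)
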