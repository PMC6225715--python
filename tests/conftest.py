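import numpy as np
import pandas as pd
import pytest

from crossfmt import FeatureTable, SimulationConfig, generate_paired_study


@pytest.fixture(scope="session")
def small_bundle():
    """Scaled-down paired study for fast unit tests."""
    config = SimulationConfig(n_otus=60, n_kos=120, n_pathways=8,
                              samples_per_group=8, n_diff_otus=10,
                              n_planted_pathways_per_sign=1, seed=42)
    return generate_paired_study(config)


@pytest.fixture(scope="session")
def default_bundle():
    """One bundle at the study's default design (12 samples/group)."""
    return generate_paired_study(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_count_table(rng, n_samples=5, n_features=8, kind="otu"):
    data = pd.DataFrame(
        rng.integers(0, 50, size=(n_samples, n_features)),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"{kind}{j}" for j in range(n_features)],
    )
    return FeatureTable(data.astype(float), kind=kind)
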