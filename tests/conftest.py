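import numpy as np
import pandas as pd
import pytest

from isletgrid.preprocess import impute_median
from isletgrid.synthetic import (
    SyntheticConfig,
    generate_interactome,
    generate_pathways,
    generate_study,
)


@pytest.fixture(scope="session")
def small_config():
    """A reduced study (fewer proteins) for fast unit tests."""
    return SyntheticConfig(n_proteins=400, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_completed(small_study):
    study, _ = small_study
    return impute_median(study)


@pytest.fixture(scope="session")
def small_pathways(small_study):
    _, truth = small_study
    return generate_pathways(truth, n_random_sets=10, set_size_range=(8, 25))


@pytest.fixture(scope="session")
def small_interactome_edges(small_study):
    _, truth = small_study
    return generate_interactome(truth, background_density=0.02,
                                n_background_nodes=60)


@pytest.fixture(scope="session")
def default_study():
    """Study at the default generator conditions (2000 proteins, 7 images)."""
    return generate_study(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_completed(default_study):
    study, _ = default_study
    return impute_median(study)
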