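import numpy as np
import pytest

import polyrisk as pr


@pytest.fixture(scope="session")
def small_config() -> pr.ScenarioConfig:
    """Desk-scale scenario: common disease, modest cohort, 50 loci."""
    return pr.ScenarioConfig(
        n_loci=50, h2=0.4, prevalence=0.1, n_cases=400, n_controls=400, seed=42
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> pr.CaseControlDataset:
    return pr.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
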