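import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from grnperm import CountMatrix, RegulatorSet, RunConfig
from grnperm.inference import group_correlated_regulators
from grnperm.normalization import log_transform, normalize
from grnperm.synthetic import simulate_dataset


@pytest.fixture
def small_counts() -> CountMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return CountMatrix(values=values)


@pytest.fixture(scope="session")
def planted():
    """Small planted-signal dataset shared across tests (fast to infer on)."""
    return simulate_dataset(
        n_regulators=10, n_targets=60, n_samples=24, edges_per_target=2, seed=7
    )


@pytest.fixture(scope="session")
def planted_normalized(planted):
    normalized, _ = normalize(planted.counts, method="tmm", low_count_threshold=0)
    return normalized


@pytest.fixture(scope="session")
def planted_rf(planted_normalized):
    """The forest input scale of the default pipeline: log2(1+normalized)."""
    return log_transform(planted_normalized)


@pytest.fixture(scope="session")
def planted_grouping(planted, planted_rf):
    return group_correlated_regulators(planted_rf, planted.regulators, rho=0.9)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def fast_config():
    return RunConfig(
        seed=5,
        n_trees=100,
        n_permutations=30,
        density=0.05,
        fdr_threshold=0.05,
        low_count_threshold=0.0,
    )
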