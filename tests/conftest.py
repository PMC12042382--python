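import numpy as np
import pytest

from eguard import qsir
from eguard.synthetic_data import (
    BenchmarkConfig,
    generate_benchmark,
    fixture_pool,
    stratified_split,
)


@pytest.fixture(scope="session")
def benchmark_ds():
    """Small noise-free benchmark: labels perfectly recoverable by rules."""
    return generate_benchmark(
        BenchmarkConfig(n_compounds=600, positive_rate=0.10, label_noise=0.0, seed=42)
    )


@pytest.fixture(scope="session")
def split(benchmark_ds):
    return stratified_split(benchmark_ds, test_fraction=0.25, n_folds=5, seed=42)


@pytest.fixture(scope="session")
def toy_model(split):
    return qsir.train(split.train, qsir.Hyperparams(n_estimators=30), seed=7)


@pytest.fixture(scope="session")
def pool_mols():
    return fixture_pool(150, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
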