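import numpy as np
import pytest

from settlehealth.synthetic import (
    DEFAULT_FEATURE_RANGES,
    SyntheticSpec,
    generate_feature_panel,
)

FEATURES = list(DEFAULT_FEATURE_RANGES)


@pytest.fixture(scope="session")
def default_panel():
    """The canonical synthetic study panel (default conditions, seed 0)."""
    return generate_feature_panel(SyntheticSpec(seed=0)).panel


@pytest.fixture(scope="session")
def benchmark_result(default_panel):
    """Benchmark of all six families on the canonical panel (shared: it is
    the costly fixture behind the additivity and ordering checks)."""
    from settlehealth.bench import run_benchmark

    return run_benchmark(default_panel, FEATURES)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
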