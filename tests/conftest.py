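import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic battery for IO / round-trip tests."""
    from facet2function import DesignConfig, GeneratorParams, simulate_dataset

    cfg = DesignConfig(n_plots=12, n_samples=36, richness_levels=(1, 2, 4, 8))
    params = GeneratorParams(
        n_asv_bacteria=150, n_asv_fungi=80,
        depth_bacteria=2000, depth_fungi=1200,
    )
    return simulate_dataset(cfg, params, seed=20240915)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_counts():
    """3-sample, 4-taxon community matrix with hand-checkable totals."""
    return pd.DataFrame(
        {"s1": [6, 3, 1, 0], "s2": [5, 5, 5, 5], "s3": [10, 0, 0, 0]},
        index=["t1", "t2", "t3", "t4"],
    )
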