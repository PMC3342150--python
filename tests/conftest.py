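import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from circmir import synth

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """Default packaged-style mini-reference (135 entries, 60 miRNAs)."""
    return synth.make_reference(seed=11)


@pytest.fixture(scope="session")
def small_reference():
    return synth.make_reference(
        n_per_class={"miRNA": 8, "tRNA": 4, "rRNA": 2, "scRNA": 2, "snRNA": 2,
                     "snoRNA": 2, "other": 2},
        seed=5,
    )


@pytest.fixture(scope="session")
def cohort(reference):
    """One seeded synthetic cohort at the default study conditions."""
    cfg = synth.SimulationConfig(seed=7, mean_library_size=100_000)
    counts, metadata = synth.simulate_cohort(cfg, reference)
    return counts, metadata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_counts(rng):
    """50 genes x 10 samples of NB-ish counts for filter/normalisation tests."""
    vals = rng.negative_binomial(2, 0.02, size=(50, 10))
    return pd.DataFrame(
        vals,
        index=[f"g{i:02d}" for i in range(50)],
        columns=[f"s{j:02d}" for j in range(10)],
    )
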