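import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from tmhseg import GeneratorSpec, extract_pools, generate_dataset, train_index


@pytest.fixture(scope="session")
def synthetic_train_set():
    """A deterministic annotated training dataset at default conditions."""
    return generate_dataset(GeneratorSpec(n_proteins=40, rng_seed=1), name="train")


@pytest.fixture(scope="session")
def trained_table(synthetic_train_set):
    tmh_pool, non_pool = extract_pools(synthetic_train_set)
    return train_index(tmh_pool, non_pool)
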