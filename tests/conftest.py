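import numpy as np
import pytest

from nitronet.synthetic import SyntheticConfig, generate_bundle


def small_config(**overrides) -> SyntheticConfig:
    """Scaled-down universe for fast unit tests."""
    defaults = dict(
        n_genes=300, n_families=60, family_size_mean=4, n_go_terms=60,
        dag_depth=9, n_experiments=3, responsive_terms=2, families_per_term=8,
        n_modules_planted=2, module_size=20, n_tfs=2, seed=0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
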