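import random

import pytest

from centroscan import panels, simulate


@pytest.fixture(scope="session")
def small_benchmark():
    """A 6-element benchmark (groups A/B/C + decoy) with moderate ages and
    coding divergence; shared across integration-style tests."""
    cfg = simulate.SimConfig(
        n_elements=6, age_years=(0.0, 1.0e6), internal_divergence=0.02
    )
    return simulate.generate_benchmark(cfg, seed=11)


@pytest.fixture(scope="session")
def pristine_benchmark():
    """Age-0, divergence-0 benchmark: every structural feature must be
    recovered exactly."""
    cfg = simulate.SimConfig(n_elements=6, age_years=0.0, internal_divergence=0.0)
    return simulate.generate_benchmark(cfg, seed=23, include_decoy=False)


@pytest.fixture(scope="session")
def domain_profiles():
    return panels.default_domain_profiles()


@pytest.fixture()
def rng():
    return random.Random(1234)
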