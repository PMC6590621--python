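import pytest

from mitosplice.pipeline import simulate_in_memory
from mitosplice.synthetic import FULL_ISOFORM, SHORT_ISOFORM, SimConfig, build_toy_genome


def null_config(seed: int = 0, reads: int = 20_000, **overrides) -> SimConfig:
    """A config where both conditions share every parameter (zero-effect null)."""
    params = dict(
        reads_per_sample=reads,
        mito_fraction={"con": 0.045, "ldl": 0.045},
        isoform_mixture={
            "con": {FULL_ISOFORM: 0.8, SHORT_ISOFORM: 0.2},
            "ldl": {FULL_ISOFORM: 0.8, SHORT_ISOFORM: 0.2},
        },
        precursor_fraction={"con": 0.05, "ldl": 0.05},
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def toy_genome(default_config):
    genome, sequences = build_toy_genome(default_config)
    return genome


@pytest.fixture(scope="session")
def small_experiment():
    """A light-weight simulated experiment for unit tests (not the study scale)."""
    return simulate_in_memory(SimConfig(seed=3, reads_per_sample=5_000))
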