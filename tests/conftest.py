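import numpy as np
import pytest
from hypothesis import settings

from rarepath.synthetic_data import SimConfig, simulate_cohort

settings.register_profile("default-derandomized", derandomize=True,
                          deadline=None)
settings.load_profile("default-derandomized")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (697 subjects, 3 populations)."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def enriched_cohort():
    """Cohort with a strong carrier effect in the genes of SET01."""
    return simulate_cohort(SimConfig(seed=7, n_genes=255, n_sets=51,
                                     genes_per_set=5,
                                     causal_set_ids=("SET01",),
                                     n_causal_genes=5, carrier_effect=2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
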