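import numpy as np
import pytest

import omicdriver as od


@pytest.fixture(scope="session")
def default_cohort():
    """One shared synthetic cohort at the default study conditions."""
    cohort, truth = od.generate_cohort(od.SimConfig(seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def driver_benchmark_config():
    """Cohort configuration of the driver-recovery benchmark: one planted
    regulator per module, mix balanced over the four molecular platforms."""
    def make(seed):
        return od.SimConfig(
            seed=seed, n_genes=200, n_modules=8, genes_per_module=20,
            regulators_per_module=1,
            platform_mix={"mutation": 0.25, "cnv": 0.25,
                          "methylation": 0.25, "mirna": 0.25,
                          "expression": 0.0})
    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
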