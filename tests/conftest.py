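import numpy as np
import pytest

import genomosaic as g


@pytest.fixture(scope="session")
def small_truth():
    """A small landscape with all locus classes, shared across read-only tests."""
    cfg = g.default_landscape_config(n_loci=300, n_generations=60, seed=11)
    return g.simulate_landscape(cfg)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return g.simulate_reads(small_truth, mean_coverage=2.0, error_rate=0.005, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
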