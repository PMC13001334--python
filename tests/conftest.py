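import numpy as np
import pytest

import binderqc as b


@pytest.fixture(scope="session")
def small_cfg():
    """A small but complete study cohort: all four design classes."""
    return b.SimConfig(
        n_designs={
            "functional_enriched": 20,
            "neutral": 60,
            "mpnn_ke_dropout": 40,
            "cys_depleting": 10,
        },
        depth_per_replicate=200_000,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """(designs, truth, counts, results, features) for the small cohort."""
    designs, truth = b.generate_designs(small_cfg)
    counts = b.simulate_screen(designs, small_cfg)
    results = b.test_enrichment(counts)
    features = b.compute_feature_table(designs).set_index("design_id")
    return designs, truth, counts, results, features


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
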