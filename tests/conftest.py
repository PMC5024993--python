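import numpy as np
import pytest

from mosaicdn import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_families=50, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """50 quad families with planted inherited, germline de novo and mosaic variants."""
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def truth_index(truths, classes=("germline_denovo", "mosaic")):
    """(family_id, pos, child_role) -> PlantedVariant for the given truth classes."""
    idx = {}
    for t in truths:
        for pv in t.planted_variants:
            if pv.truth_class in classes:
                idx[(t.family_id, pv.pos, pv.child_role)] = pv
    return idx
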