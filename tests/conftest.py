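import numpy as np
import pytest

import metafuse as mf
from metafuse.errormodel import ReplicateSet, merge_replicates, pair_stats


@pytest.fixture(scope="session")
def study_data():
    """Cohort-sized synthetic dataset (16+15 samples, 43+165 metabolites, 15 pairs)."""
    return mf.generate(mf.SyntheticSpec(seed=123))


@pytest.fixture(scope="session")
def study_replicates(study_data):
    blocks, table, _truth = study_data
    return merge_replicates([pair_stats(b, table) for b in blocks.blocks])


@pytest.fixture(scope="session")
def small_data():
    """Small dataset for fast pipeline-level tests."""
    spec = mf.SyntheticSpec(n_per_class=(10, 10), n_metabolites=(8, 12),
                            lipid_split={"TG": 1}, n_duplicate_pairs=8, seed=7)
    return mf.generate(spec)


def make_replicate_set(x1, x2, group="amine"):
    """Replicate set from raw paired arrays (D × J), single metabolite group."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[0] == 1 and x1.shape[1] > 1 and x1.shape != x2.shape:
        raise ValueError
    d, j = x1.shape
    return ReplicateSet(x1, x2, [f"m{c}" for c in range(j)], [group] * j,
                        [(f"a{p}", f"b{p}", f"r{p}") for p in range(d)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
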