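import numpy as np
import pytest
from hypothesis import settings

from reglrsd import AbundanceTable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_labeled_table(p=6, n=10, n_pos=5, seed=0, class_names=("healthy", "disease")):
    """Small random labeled table; first n_pos samples are class_names[0]."""
    gen = np.random.default_rng(seed)
    values = gen.uniform(0.0, 1.0, size=(p, n))
    sample_ids = [f"s{j}" for j in range(n)]
    labels = {
        s: class_names[0] if j < n_pos else class_names[1]
        for j, s in enumerate(sample_ids)
    }
    return AbundanceTable(
        values=values,
        otu_ids=[f"otu{i}" for i in range(p)],
        sample_ids=sample_ids,
        labels=labels,
    )


@pytest.fixture
def labeled_table():
    return make_labeled_table()
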