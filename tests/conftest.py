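import numpy as np
import pytest

from snvcomp.pileup import BaseCountVector, ReplicateSample


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def make_sample(label, count_list, quality=30):
    """ReplicateSample from a list of (A,C,G,T) quadruples."""
    return ReplicateSample(
        label, [BaseCountVector.from_counts(c, quality=quality) for c in count_list]
    )


def random_sample(rng, label, n_rep=None, cov_range=(5, 200), alpha=(2.0, 2.0, 1.0, 1.0)):
    """Random replicate stack with Dirichlet-multinomial-ish counts."""
    n_rep = n_rep or int(rng.integers(1, 5))
    counts = [
        rng.multinomial(int(rng.integers(*cov_range)), rng.dirichlet(alpha))
        for _ in range(n_rep)
    ]
    return make_sample(label, counts)
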