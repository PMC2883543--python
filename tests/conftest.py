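import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reactvec import fixtures, triplets
from reactvec.reactions import reaction_vector

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def worked():
    """Explicit-hydrogen graphs for the demonstration molecules."""
    return fixtures.worked_example_molecules()


@pytest.fixture(scope="session")
def worked_counts(worked):
    return {name: triplets.enumerate_triplets(g) for name, g in worked.items()}


@pytest.fixture(scope="session")
def worked_vocab(worked_counts):
    """Complete vocabulary over the worked molecules (nothing dropped)."""
    return triplets.build_vocabulary(
        list(worked_counts.values()), max_size=200, min_total=1
    )


@pytest.fixture(scope="session")
def worked_vectors(worked_counts, worked_vocab):
    return {
        name: triplets.vectorize(tc, worked_vocab, name)
        for name, tc in worked_counts.items()
    }


@pytest.fixture(scope="session")
def oxidation_vector(worked_vectors):
    """The secondary-alcohol-to-ketone reaction vector (2-propanol -> acetone)."""
    return reaction_vector(
        worked_vectors["2-propanol"], worked_vectors["acetone"]
    )


@pytest.fixture(scope="session")
def corpus():
    """Default planted-family corpus: vectors, labels, annotations, vocab."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fixtures.corpus_reaction_vectors(fixtures.FixtureSpec(seed=1))


def random_molecules(seed, n, max_heavy=10):
    rng = np.random.default_rng(seed)
    return [
        fixtures.generate_random_molecule(rng, int(rng.integers(1, max_heavy + 1)))
        for _ in range(n)
    ]
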