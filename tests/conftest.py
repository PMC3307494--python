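import pytest

from litrank.features import build_feature_space, vectorize
from litrank.synthetic import default_world


def world_training_vectors(world, n_per_side=None):
    """Build labeled training vectors from a synthetic world's profiles."""
    pmids_a = sorted(world.pmids("A"))[: n_per_side or None]
    pmids_b = sorted(world.pmids("B"))[: n_per_side or None]
    profiles_a = [world.profiles[p] for p in pmids_a]
    profiles_b = [world.profiles[p] for p in pmids_b]
    space = build_feature_space(profiles_a, profiles_b)
    vectors = [vectorize(p, space, "A") for p in profiles_a] \
        + [vectorize(p, space, "B") for p in profiles_b]
    return space, vectors


@pytest.fixture(scope="session")
def separable_world():
    """Disjoint-vocabulary world: the two topics share no keywords."""
    return default_world(delta=1.0, n_per_topic=50, vocab_size=100, seed=11)


@pytest.fixture(scope="session")
def overlapping_world():
    """Half-exclusive vocabulary: separable but with shared keywords."""
    return default_world(delta=0.5, n_per_topic=50, vocab_size=100, seed=13)
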