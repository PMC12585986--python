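import numpy as np
import pytest

from hopbasin.network import WeightedPatternSet, build_weight_matrix, random_patterns


def make_network(n: int, p: int, multiplier: int, seed: int) -> np.ndarray:
    """A random Hebbian network: p random patterns at the given weight."""
    rng = np.random.default_rng(seed)
    pats = random_patterns(p, n, rng)
    return build_weight_matrix(
        WeightedPatternSet(pats, np.full(p, multiplier, dtype=np.int64))
    )


@pytest.fixture(scope="session")
def pretrained_10():
    """A 10-unit network pretrained with 50 random stimuli at weight 10."""
    return make_network(10, 50, 10, seed=1234)
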