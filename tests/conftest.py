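import numpy as np
import pytest

from glimpsetrf.phonemes import (
    PhonemeInterval,
    PhonemeTier,
    PhoneticFeatureMap,
)


def make_tier(spec, total=None):
    """Build a tier from (label, start, end, word) tuples."""
    ivs = [PhonemeInterval(*s) for s in spec]
    return PhonemeTier(ivs, total if total is not None else ivs[-1].end_s)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def arpabet():
    return PhoneticFeatureMap.load_arpabet()


@pytest.fixture
def toy_fmap():
    """Three pseudo-phonemes over 4 features, mutually distinct."""
    return PhoneticFeatureMap(
        {"pa": [1, 0, 0, 1], "pb": [0, 1, 0, 1], "pc": [0, 0, 1, 0]},
        feature_names=("f1", "f2", "f3", "f4"),
    )


@pytest.fixture
def toy_tier():
    # two words: (pa pb) (pc), contiguous, 0.3 s total
    return make_tier([
        ("pa", 0.0, 0.1, 0),
        ("pb", 0.1, 0.2, 0),
        ("pc", 0.2, 0.3, 1),
    ])
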