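import numpy as np
import pytest

from frailtykit import reference
from frailtykit.scales import MSEGA_ITEMS, ZFS_ITEMS


@pytest.fixture(scope="session")
def reconstructed_dist():
    """ZFS score-by-SEGA-frailty distribution recovered from the published ROC rows."""
    return reference.reconstructed_distribution()


@pytest.fixture(scope="session")
def reconstructed_cohort():
    return reference.reconstructed_cohort()


@pytest.fixture
def all_no_zfs():
    return {name: 0 for name in ZFS_ITEMS}


@pytest.fixture
def all_zero_msega():
    return {name: 0 for name in MSEGA_ITEMS}


def random_distribution(rng: np.random.Generator, max_score: int = 6, max_count: int = 12):
    """A small random score distribution with both groups nonempty."""
    from frailtykit.roc import ScoreDistribution

    while True:
        pos = rng.integers(0, max_count, size=max_score + 1)
        neg = rng.integers(0, max_count, size=max_score + 1)
        if pos.sum() > 0 and neg.sum() > 0:
            return ScoreDistribution(tuple(int(c) for c in pos), tuple(int(c) for c in neg))
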