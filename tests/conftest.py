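import numpy as np
import pytest

from fevscore.fixtures import QSOFA_COUNTS
from fevscore.roc import ScoreCounts


@pytest.fixture
def qsofa_counts() -> ScoreCounts:
    """Published qSOFA score-by-outcome contingency (scores 0-3)."""
    return QSOFA_COUNTS


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


def random_counts(rng: np.random.Generator, max_subjects: int = 200) -> ScoreCounts:
    """Random per-level counts with at least one subject in each class."""
    k = int(rng.integers(2, 8))
    while True:
        alive = rng.integers(0, max_subjects // k, size=k)
        dead = rng.integers(0, max_subjects // k, size=k)
        if alive.sum() >= 2 and dead.sum() >= 2:
            return ScoreCounts(tuple(range(k)), tuple(int(x) for x in alive),
                               tuple(int(x) for x in dead))


def counts_to_scores(counts: ScoreCounts):
    """Expand per-level counts into per-subject score/outcome arrays."""
    scores, outcomes = [], []
    for lv, a, d in zip(counts.levels, counts.alive, counts.dead):
        scores.extend([lv] * (a + d))
        outcomes.extend([0] * a + [1] * d)
    return np.array(scores, dtype=float), np.array(outcomes, dtype=int)
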