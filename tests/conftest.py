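import numpy as np
import pytest

from rsmcat import Item, ItemBank, ThresholdSet, builtin_ipq18


@pytest.fixture(scope="session")
def ipq18() -> ItemBank:
    return builtin_ipq18()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def tiny_bank() -> ItemBank:
    """Minimal 3-category bank: one item, thresholds (−1, 1)."""
    return ItemBank(
        items=(Item("a", 0.0),),
        thresholds=ThresholdSet((-1.0, 1.0)),
        name="tiny",
    )


def random_pattern(bank, rng, min_len=3, max_len=None):
    """A random non-extreme response pattern over a random item subset."""
    max_len = max_len or len(bank)
    m = bank.max_score
    while True:
        n = int(rng.integers(min_len, max_len + 1))
        ids = list(rng.choice(bank.item_ids, size=n, replace=False))
        scores = rng.integers(0, m + 1, size=n)
        if not (all(scores == 0) or all(scores == m)):
            return list(zip(ids, (int(s) for s in scores)))
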