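"""Rasch rating scale model (RSM) mathematics.

For an item with overall difficulty ``delta`` and shared category thresholds
``tau_1 < … < tau_m``, the probability of response category ``k`` (0..m) at
person measure ``theta`` is

    P(X = k | theta) = exp(k·(theta − delta) − Σ_{j≤k} tau_j) / Z(theta)

with the empty sum equal to 0 and Z the sum of the numerators over all
categories.  Adjacent categories k−1 and k are equally probable exactly at
theta = delta + tau_k, which is why delta + tau_k is called the step
difficulty.

Item information under the RSM equals the category-score variance
W(theta) = Σ k²P_k − (Σ kP_k)², and test information is additive over items.
All exponentials are max-shifted so the formulas are stable over the whole
working range of theta.
"""
from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .item_bank import Item, ItemBank, ThresholdSet

__all__ = [
    "ResponseVector",
    "category_probabilities",
    "expected_score",
    "score_variance",
    "test_information",
    "log_likelihood",
]

# A response vector is a sequence of (item_id, integer score 0..m) pairs over
# distinct items of one bank.
ResponseVector = Sequence[tuple[str, int]]


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not math.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta!r}")
    return theta


def _cumulative_taus(taus: Sequence[float]) -> np.ndarray:
    # kappa_k = Σ_{j≤k} tau_j, with kappa_0 = 0
    return np.concatenate([[0.0], np.cumsum(taus)])


def log_prob_matrix(
    thetas: np.ndarray | float, delta: float, taus: Sequence[float]
) -> np.ndarray:
    """Log category probabilities for an array of thetas; shape (len(thetas), m+1).

    Vectorized workhorse shared by the scalar API, the grid likelihood oracle
    and the simulator.
    """
    th = np.atleast_1d(np.asarray(thetas, dtype=float))
    k = np.arange(len(taus) + 1, dtype=float)
    psi = np.outer(th - delta, k) - _cumulative_taus(taus)
    psi -= psi.max(axis=1, keepdims=True)
    logz = np.log(np.exp(psi).sum(axis=1))
    return psi - logz[:, None]


def category_probabilities(
    theta: float, item: Item, thresholds: ThresholdSet
) -> np.ndarray:
    """Probability of each response category 0..m at ``theta``.

    Returns an (m+1)-vector of probabilities summing to one.
    """
    theta = _check_theta(theta)
    return np.exp(log_prob_matrix(theta, item.delta, thresholds.taus)[0])


def expected_score(theta: float, item: Item, thresholds: ThresholdSet) -> float:
    """Model-expected category score Σ k·P_k; strictly increasing in theta."""
    p = category_probabilities(theta, item, thresholds)
    return float(np.arange(p.size) @ p)


def score_variance(theta: float, item: Item, thresholds: ThresholdSet) -> float:
    """Category-score variance Σ k²P_k − E²  —  the item information at theta."""
    p = category_probabilities(theta, item, thresholds)
    k = np.arange(p.size)
    e = float(k @ p)
    return float((k * k) @ p - e * e)


def test_information(
    theta: float, items: Iterable[Item], thresholds: ThresholdSet
) -> float:
    """Sum of item informations; 0 for an empty item set."""
    return float(sum(score_variance(theta, it, thresholds) for it in items))


def _validated_pairs(
    responses: ResponseVector, bank: ItemBank
) -> list[tuple[Item, int]]:
    pairs: list[tuple[Item, int]] = []
    seen: set[str] = set()
    m = bank.max_score
    for item_id, score in responses:
        if item_id in seen:
            raise ValueError(f"duplicate response for item {item_id!r}")
        seen.add(item_id)
        score = int(score)
        if not 0 <= score <= m:
            raise ValueError(
                f"score {score} for item {item_id!r} outside 0..{m}"
            )
        pairs.append((bank.item(item_id), score))
    return pairs


def log_likelihood(theta: float, responses: ResponseVector, bank: ItemBank) -> float:
    """Log-likelihood Σ_i log P(X_i = x_i | theta); 0 for no responses.

    Concave in theta (exponential-family score model), so the maximum found
    by Newton-Raphson is global.
    """
    theta = _check_theta(theta)
    total = 0.0
    for item, score in _validated_pairs(responses, bank):
        total += float(
            log_prob_matrix(theta, item.delta, bank.thresholds.taus)[0, score]
        )
    return total
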