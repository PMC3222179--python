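"""Person-fit diagnostics: infit/outfit mean squares and aberrance flagging.

The standardized residual of response x on one item is z = (x − E)/sqrt(W),
with E and W the model-expected score and score variance at the person's
measure.  Outfit MNSQ is the unweighted mean of z² over the administered
items — sensitive to outlying off-target responses; infit MNSQ is the
information-weighted form Σ(x − E)² / ΣW — sensitive to unexpected on-target
patterns.  Both have expectation ≈ 1 for model-consistent responding; an
outfit MNSQ of 2.0 or more flags a possibly aberrant pattern.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .item_bank import Item, ItemBank, ThresholdSet
from .rsm_model import ResponseVector, expected_score, score_variance

__all__ = [
    "FitIndices",
    "standardized_residual",
    "outfit_mnsq",
    "infit_mnsq",
    "person_fit",
    "flag_person",
]

OUTFIT_FLAG_CUTOFF = 2.0


@dataclass(frozen=True)
class FitIndices:
    infit_mnsq: float
    outfit_mnsq: float
    n_items: int
    flagged: bool


def standardized_residual(
    score: int, theta: float, item: Item, thresholds: ThresholdSet
) -> float:
    """z = (x − E)/sqrt(W) for one response at the person measure."""
    e = expected_score(theta, item, thresholds)
    w = score_variance(theta, item, thresholds)
    return (float(score) - e) / math.sqrt(w)


def _residual_parts(responses: ResponseVector, theta: float, bank: ItemBank):
    if not responses:
        raise ValueError("empty response vector")
    taus = bank.thresholds
    sq_resid, weights = [], []
    for item_id, score in responses:
        item = bank.item(item_id)
        e = expected_score(theta, item, taus)
        w = score_variance(theta, item, taus)
        sq_resid.append((float(score) - e) ** 2)
        weights.append(w)
    return sq_resid, weights


def outfit_mnsq(responses: ResponseVector, theta: float, bank: ItemBank) -> float:
    """Unweighted mean-square: (1/N) Σ z_i²."""
    sq, w = _residual_parts(responses, theta, bank)
    return sum(r / wi for r, wi in zip(sq, w)) / len(sq)


def infit_mnsq(responses: ResponseVector, theta: float, bank: ItemBank) -> float:
    """Information-weighted mean-square: Σ(x − E)² / Σ W."""
    sq, w = _residual_parts(responses, theta, bank)
    return sum(sq) / sum(w)


def flag_person(fit: FitIndices, cutoff: float = OUTFIT_FLAG_CUTOFF) -> bool:
    """True iff outfit MNSQ ≥ cutoff (default 2.0)."""
    return fit.outfit_mnsq >= cutoff


def person_fit(
    responses: ResponseVector,
    theta: float,
    bank: ItemBank,
    cutoff: float = OUTFIT_FLAG_CUTOFF,
) -> FitIndices:
    """Infit/outfit MNSQ of one response vector at the (estimated) measure."""
    infit = infit_mnsq(responses, theta, bank)
    outfit = outfit_mnsq(responses, theta, bank)
    return FitIndices(
        infit_mnsq=infit,
        outfit_mnsq=outfit,
        n_items=len(responses),
        flagged=outfit >= cutoff,
    )
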