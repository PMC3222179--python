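"""The adaptive administration loop.

A session starts from a coarse initial measure (optionally seeded by the
respondent's overall satisfaction rating), repeatedly administers the
unanswered item with the highest information at the provisional measure,
re-estimates after every response once at least three responses are in and
the pattern is non-extreme, and stops when the measure is precise enough
(subject to a minimum test length) or the bank is spent.

Stopping precision.  The provisional measure's ML standard error is
1/sqrt(I(theta)).  The stop rule, however, compares a *reliability-consistent*
standard error that also counts the calibration population's prior precision,

    se_stop = 1 / sqrt(I(theta) + 1/SD²),

against the threshold SD·sqrt(1 − R) (0.51 for the IPQ-18, SD 2.09,
person separation reliability R 0.94).  The two together say exactly
"stop when the marginal reliability 1 − se_stop²/SD² of the measure reaches
the full instrument's calibrated reliability".  With the pure ML standard
error the published IPQ-18 test lengths (minimum 10, most sessions stopping
at the minimum) are unattainable — the ten most informative items anywhere
near the population centre carry less than 1/0.51² units of information — so
the prior-augmented form is the reading consistent with the instrument's
observed behaviour.  Set ``StopRules.prior_sd = math.inf`` for the pure-ML
convention.  The person estimate itself is always plain maximum likelihood.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .estimation import AbilityEstimate, is_extreme_pattern, mle_estimate
from .item_bank import Item, ItemBank
from .rsm_model import score_variance, test_information

__all__ = [
    "StopRules",
    "StepRecord",
    "CatSession",
    "StopDecision",
    "SessionResult",
    "SessionError",
    "InvalidResponseError",
    "start_session",
    "select_next_item",
    "record_response",
    "should_stop",
    "run_scripted_session",
]

# Overall-satisfaction rating (0..4) → starting measure in logits.  A coarse
# monotone mapping into the working range; rating 2 (neutral) starts at 0.
INITIAL_RATING_THETA = {0: -2.0, 1: -1.0, 2: 0.0, 3: 1.0, 4: 2.0}

# Pre-estimation warm-up step, logits per response, while fewer than three
# responses (or an all-0/all-4 prefix) make ML estimation unavailable.
WARMUP_STEP = 0.7


class SessionError(RuntimeError):
    """Operation inconsistent with the session state."""


class InvalidResponseError(ValueError):
    """Responder produced an unusable score; carries the partial session."""

    def __init__(self, message: str, session: "CatSession"):
        super().__init__(message)
        self.session = session


@dataclass(frozen=True)
class StopRules:
    """Stop rules for one adaptive administration.

    ``se_threshold``: precision target in logits (IPQ-18 default 0.51 =
    2.09·sqrt(1−0.94)).  ``min_items``/``max_items``: test length bounds
    (``max_items=None`` means the full bank).  ``prior_sd``: calibration
    population SD entering the stopping SE; ``None`` defers to the bank's
    ``pop_sd`` metadata, ``math.inf`` disables the prior term (pure ML SE).
    """

    se_threshold: float = 0.51
    min_items: int = 10
    max_items: int | None = None
    prior_sd: float | None = None

    def __post_init__(self) -> None:
        if self.se_threshold <= 0:
            raise ValueError("se_threshold must be positive")
        if self.min_items < 1:
            raise ValueError("min_items must be at least 1")
        if self.max_items is not None and self.max_items < self.min_items:
            raise ValueError("max_items must be >= min_items")
        if self.prior_sd is not None and self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive (math.inf for no prior)")


@dataclass(frozen=True)
class StepRecord:
    """One administered item: provisional measure state after the response."""

    step: int
    item_id: str
    score: int
    theta: float | None  # None before estimation becomes active
    se: float | None  # ML standard error
    stop_se: float | None  # reliability-consistent SE used by the stop rule


@dataclass(frozen=True)
class StopDecision:
    stop: bool
    reason: str  # se_met | max_items | bank_exhausted | none


@dataclass
class CatSession:
    """Evolving state of one adaptive administration."""

    bank: ItemBank
    rules: StopRules
    records: list[StepRecord] = field(default_factory=list)
    current_theta: float = 0.0
    current_se: float | None = None
    current_stop_se: float | None = None
    estimation_active: bool = False
    stopped: bool = False
    stop_reason: str = "none"
    initial_rating: int | None = None
    pending_item: str | None = None
    prior_precision: float = 0.0  # 1/SD² of the calibration population

    @property
    def n_administered(self) -> int:
        return len(self.records)

    @property
    def responses(self) -> list[tuple[str, int]]:
        return [(r.item_id, r.score) for r in self.records]

    @property
    def administered_ids(self) -> set[str]:
        return {r.item_id for r in self.records}

    def remaining_items(self) -> list[Item]:
        done = self.administered_ids
        return [it for it in self.bank if it.item_id not in done]


def start_session(
    bank: ItemBank,
    initial_rating: int | None = None,
    rules: StopRules | None = None,
) -> CatSession:
    """Open a session; the starting measure comes from the optional 0..4 rating."""
    if len(bank) == 0:
        raise ValueError("cannot run a session on an empty bank")
    rules = rules if rules is not None else StopRules()
    max_items = rules.max_items if rules.max_items is not None else len(bank)
    if max_items > len(bank):
        raise ValueError(
            f"max_items {max_items} exceeds bank size {len(bank)}"
        )
    rules = replace(rules, max_items=max_items)
    if initial_rating is None:
        theta0 = 0.0
    else:
        try:
            theta0 = INITIAL_RATING_THETA[int(initial_rating)]
        except (KeyError, ValueError):
            raise ValueError(
                f"initial_rating must be an integer 0..4, got {initial_rating!r}"
            ) from None
    if rules.prior_sd is not None:
        prior_sd = rules.prior_sd
    else:
        prior_sd = bank.metadata.get("pop_sd", math.inf)
    prior_precision = 0.0 if math.isinf(prior_sd) else 1.0 / prior_sd**2
    return CatSession(
        bank=bank,
        rules=rules,
        current_theta=theta0,
        initial_rating=initial_rating,
        prior_precision=prior_precision,
    )


def select_next_item(session: CatSession) -> str:
    """Unanswered item with the highest information at the provisional measure.

    Ties (identical information) break toward the item whose difficulty is
    closest to the provisional measure, then to the lexicographically
    smallest id, so administrations are reproducible.
    """
    if session.stopped:
        raise SessionError("session already stopped")
    remaining = session.remaining_items()
    if not remaining:
        raise SessionError("no unanswered items remain")
    theta = session.current_theta
    taus = session.bank.thresholds
    scored = [(score_variance(theta, it, taus), it) for it in remaining]
    best_info = max(s for s, _ in scored)
    ties = [it for s, it in scored if best_info - s <= 1e-12]
    ties.sort(key=lambda it: (abs(theta - it.delta), it.item_id))
    choice = ties[0].item_id
    session.pending_item = choice
    return choice


def _stop_se(session: CatSession, theta: float) -> float:
    info = test_information(
        theta,
        [session.bank.item(i) for i in session.administered_ids],
        session.bank.thresholds,
    )
    return 1.0 / math.sqrt(info + session.prior_precision)


def should_stop(session: CatSession) -> StopDecision:
    """Evaluate the stop rules against the current session state."""
    n = session.n_administered
    rules = session.rules
    if (
        n >= rules.min_items
        and session.estimation_active
        and session.current_stop_se is not None
        and session.current_stop_se <= rules.se_threshold
    ):
        return StopDecision(True, "se_met")
    assert rules.max_items is not None
    if n >= rules.max_items:
        return StopDecision(True, "max_items")
    if n >= len(session.bank):  # defensive; max_items <= bank size
        return StopDecision(True, "bank_exhausted")
    return StopDecision(False, "none")


def record_response(session: CatSession, item_id: str, score: int) -> CatSession:
    """Record the response to the currently selected item and update state.

    Once three responses are in and the pattern is not all-0/all-4, the
    provisional measure is re-estimated by ML after every response; before
    that a coarse warm-up step keeps selection adaptive.
    """
    if session.stopped:
        raise SessionError("session already stopped")
    if session.pending_item is None:
        raise SessionError("select_next_item must be called before record_response")
    if item_id != session.pending_item:
        raise SessionError(
            f"response for {item_id!r} but selected item is {session.pending_item!r}"
        )
    if item_id in session.administered_ids:
        raise SessionError(f"item {item_id!r} already administered")
    score = int(score)
    if not 0 <= score <= session.bank.max_score:
        raise ValueError(f"score {score} outside 0..{session.bank.max_score}")

    step_n = session.n_administered + 1
    session.records.append(
        StepRecord(step_n, item_id, score, None, None, None)
    )
    session.pending_item = None

    responses = session.responses
    if len(responses) >= 3 and not is_extreme_pattern(responses, session.bank):
        est = mle_estimate(
            responses, session.bank, start_theta=session.current_theta
        )
        session.current_theta = est.theta
        session.current_se = est.se
        session.current_stop_se = _stop_se(session, est.theta)
        session.estimation_active = True
        session.records[-1] = StepRecord(
            step_n, item_id, score, est.theta, est.se, session.current_stop_se
        )
    else:
        mid = session.bank.max_score / 2.0
        if score > mid:
            session.current_theta += WARMUP_STEP
        elif score < mid:
            session.current_theta -= WARMUP_STEP
        session.current_theta = min(max(session.current_theta, -6.0), 6.0)

    decision = should_stop(session)
    if decision.stop:
        session.stopped = True
        session.stop_reason = decision.reason
    return session


@dataclass(frozen=True)
class SessionResult:
    """Completed administration: final ML estimate plus the step log."""

    estimate: AbilityEstimate
    log: tuple[StepRecord, ...]
    stop_reason: str
    session: CatSession

    @property
    def n_items(self) -> int:
        return len(self.log)

    @property
    def responses(self) -> list[tuple[str, int]]:
        return [(r.item_id, r.score) for r in self.log]


def run_scripted_session(
    bank: ItemBank,
    responder: Callable[[str], int],
    rules: StopRules | None = None,
    initial_rating: int | None = None,
) -> SessionResult:
    """Drive a full session with ``responder(item_id) -> score``.

    The final estimate is recomputed by ML over all administered responses
    (extreme patterns get the adjusted finite estimate).  An invalid responder
    score aborts with the partial session attached to the exception.
    """
    session = start_session(bank, initial_rating=initial_rating, rules=rules)
    while not session.stopped:
        item_id = select_next_item(session)
        score = responder(item_id)
        try:
            score = int(score)
        except (TypeError, ValueError):
            raise InvalidResponseError(
                f"responder returned non-integer {score!r} for item {item_id!r}",
                session,
            ) from None
        if not 0 <= score <= bank.max_score:
            raise InvalidResponseError(
                f"responder returned out-of-range score {score} for item {item_id!r}",
                session,
            )
        record_response(session, item_id, score)
    estimate = mle_estimate(
        session.responses, bank, start_theta=session.current_theta
    )
    return SessionResult(
        estimate=estimate,
        log=tuple(session.records),
        stop_reason=session.stop_reason,
        session=session,
    )


def session_log_rows(result: SessionResult) -> list[dict]:
    """Step log as plain dicts: step,item_id,score,theta,se,stop_se,stopped,reason."""
    rows = []
    last = len(result.log)
    for rec in result.log:
        rows.append(
            {
                "step": rec.step,
                "item_id": rec.item_id,
                "score": rec.score,
                "theta": rec.theta,
                "se": rec.se,
                "stop_se": rec.stop_se,
                "stopped": rec.step == last,
                "reason": result.stop_reason if rec.step == last else "",
            }
        )
    return rows
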