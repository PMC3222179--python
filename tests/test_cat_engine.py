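import math

import pytest

from rsmcat import (
    Item,
    ItemBank,
    StopRules,
    ThresholdSet,
    record_response,
    run_scripted_session,
    score_variance,
    select_next_item,
    should_stop,
    start_session,
)
from rsmcat.cat_engine import (
    InvalidResponseError,
    SessionError,
    StepRecord,
    session_log_rows,
)
from rsmcat.simulation import generate_response


class TestStopRules:
    def test_defaults(self):
        rules = StopRules()
        assert rules.se_threshold == 0.51
        assert rules.min_items == 10
        assert rules.max_items is None

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se_threshold": 0.0},
            {"min_items": 0},
            {"min_items": 12, "max_items": 10},
            {"prior_sd": -1.0},
        ],
    )
    def test_invalid_rules_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StopRules(**kwargs)


class TestStartSession:
    @pytest.mark.parametrize("rating,theta0", [(0, -2.0), (2, 0.0), (4, 2.0), (None, 0.0)])
    def test_initial_rating_maps_to_start_measure(self, ipq18, rating, theta0):
        session = start_session(ipq18, initial_rating=rating)
        assert session.current_theta == theta0
        assert session.n_administered == 0
        assert not session.estimation_active

    def test_invalid_rating_rejected(self, ipq18):
        with pytest.raises(ValueError):
            start_session(ipq18, initial_rating=5)

    def test_prior_precision_from_bank_metadata(self, ipq18):
        session = start_session(ipq18)
        assert session.prior_precision == pytest.approx(1 / 2.09**2)
        pure = start_session(ipq18, rules=StopRules(prior_sd=math.inf))
        assert pure.prior_precision == 0.0

    def test_empty_bank_rejected(self):
        bank = ItemBank((), ThresholdSet((-1.0, 1.0)))
        with pytest.raises(ValueError):
            start_session(bank)


class TestSelection:
    def test_maximizes_information_at_provisional_measure(self, ipq18):
        session = start_session(ipq18, initial_rating=4)  # theta0 = +2
        chosen = select_next_item(session)
        infos = {
            it.item_id: score_variance(2.0, it, ipq18.thresholds) for it in ipq18
        }
        assert infos[chosen] == max(infos.values())

    def test_lexicographic_tie_break_on_identical_items(self):
        bank = ItemBank(
            (Item("17", -1.10), Item("12", -1.10)),
            ThresholdSet((-3.76, -1.91, 1.57, 4.11)),
        )
        session = start_session(bank, rules=StopRules(min_items=1, max_items=2))
        assert select_next_item(session) == "12"

    def test_stopped_session_cannot_select(self, ipq18):
        session = start_session(ipq18)
        session.stopped = True
        with pytest.raises(SessionError):
            select_next_item(session)


class TestRecordResponse:
    def test_estimation_activates_at_third_nonextreme_response(self, ipq18):
        session = start_session(ipq18)
        for score in (2, 3):
            item = select_next_item(session)
            record_response(session, item, score)
            assert not session.estimation_active
            assert session.records[-1].theta is None
        item = select_next_item(session)
        record_response(session, item, 1)
        assert session.estimation_active
        assert session.current_se is not None
        assert session.records[-1].theta == session.current_theta

    def test_extreme_prefix_keeps_warmup_stepping(self, ipq18):
        session = start_session(ipq18)
        thetas = [session.current_theta]
        for _ in range(4):
            item = select_next_item(session)
            record_response(session, item, 4)
            thetas.append(session.current_theta)
        assert not session.estimation_active
        # +0.7 per maximal response
        assert thetas[:4] == pytest.approx([0.0, 0.7, 1.4, 2.1])

    def test_neutral_warmup_response_leaves_theta(self, ipq18):
        session = start_session(ipq18)
        item = select_next_item(session)
        record_response(session, item, 2)
        assert session.current_theta == 0.0

    def test_must_respond_to_selected_item(self, ipq18):
        session = start_session(ipq18)
        with pytest.raises(SessionError):
            record_response(session, ipq18.item_ids[0], 2)
        selected = select_next_item(session)
        other = next(i for i in ipq18.item_ids if i != selected)
        with pytest.raises(SessionError):
            record_response(session, other, 2)

    def test_out_of_range_score_rejected(self, ipq18):
        session = start_session(ipq18)
        item = select_next_item(session)
        with pytest.raises(ValueError):
            record_response(session, item, 5)


class TestShouldStop:
    def _session_with_state(self, ipq18, n, stop_se, active=True):
        session = start_session(ipq18)
        session.records = [
            StepRecord(k + 1, ipq18.item_ids[k], 2, 0.0, 0.5, stop_se)
            for k in range(n)
        ]
        session.estimation_active = active
        session.current_stop_se = stop_se
        return session

    def test_min_items_gate(self, ipq18):
        session = self._session_with_state(ipq18, n=9, stop_se=0.40)
        assert not should_stop(session).stop

    def test_se_met_inclusive(self, ipq18):
        session = self._session_with_state(ipq18, n=10, stop_se=0.50)
        decision = should_stop(session)
        assert decision.stop and decision.reason == "se_met"
        boundary = self._session_with_state(ipq18, n=10, stop_se=0.51)
        assert should_stop(boundary).stop

    def test_max_items_stops_regardless(self, ipq18):
        session = self._session_with_state(ipq18, n=18, stop_se=2.0, active=False)
        decision = should_stop(session)
        assert decision.stop and decision.reason == "max_items"


class TestScriptedSessions:
    def test_constant_responder_terminates(self, ipq18):
        result = run_scripted_session(ipq18, lambda i: 2)
        assert 10 <= result.n_items <= 18
        assert result.stop_reason in ("se_met", "max_items")
        assert len(result.log) == result.n_items

    def test_stop_invariants_on_model_based_sessions(self, ipq18, rng):
        rules = StopRules()
        for true_theta in (-2.0, -0.5, 0.71, 1.5, 3.0):
            for _ in range(4):
                responder = lambda item_id: generate_response(
                    true_theta, ipq18.item(item_id), ipq18.thresholds, rng
                )
                result = run_scripted_session(ipq18, responder, rules=rules)
                ids = [i for i, _ in result.responses]
                assert len(set(ids)) == len(ids)  # no repeats
                assert 10 <= result.n_items <= 18
                session = result.session
                if result.stop_reason == "se_met":
                    assert result.n_items >= rules.min_items
                    assert session.current_stop_se <= rules.se_threshold
                else:
                    assert result.n_items == 18

    def test_selection_optimality_each_step(self, ipq18, rng):
        # replay a session step by step, checking the exhaustive argmax
        session = start_session(ipq18)
        while not session.stopped:
            theta_before = session.current_theta
            chosen = select_next_item(session)
            remaining = {
                it.item_id: score_variance(theta_before, it, ipq18.thresholds)
                for it in session.remaining_items()
            }
            assert remaining[chosen] >= max(remaining.values()) - 1e-12
            record_response(
                session,
                chosen,
                generate_response(0.5, ipq18.item(chosen), ipq18.thresholds, rng),
            )

    def test_all_minimum_session_gets_finite_extreme_estimate(self, ipq18):
        result = run_scripted_session(ipq18, lambda i: 0)
        assert result.estimate.extreme
        assert math.isfinite(result.estimate.theta)
        assert result.stop_reason == "max_items"  # estimation never activates

    def test_invalid_responder_score_aborts_with_log(self, ipq18):
        calls = []

        def responder(item_id):
            calls.append(item_id)
            return 2 if len(calls) < 4 else 9

        with pytest.raises(InvalidResponseError) as exc_info:
            run_scripted_session(ipq18, responder)
        assert exc_info.value.session.n_administered == 3

    def test_log_rows_shape(self, ipq18):
        result = run_scripted_session(ipq18, lambda i: 2)
        rows = session_log_rows(result)
        assert len(rows) == result.n_items
        assert rows[-1]["stopped"] is True
        assert rows[-1]["reason"] == result.stop_reason
        assert rows[0]["theta"] is None  # pre-estimation steps have no measure

    def test_min_equals_max_forces_fixed_length(self, ipq18):
        rules = StopRules(min_items=18, max_items=18)
        result = run_scripted_session(ipq18, lambda i: 2, rules=rules)
        assert result.n_items == 18
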