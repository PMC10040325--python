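"""Reward-engine unit and property tests: classification, escalation/reset,
ledger conservation, and the closed-form maximum-earnings oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from remotecm.protocol import (
    InsufficientFundsError,
    Ledger,
    Phase,
    PhasePlan,
    ProtocolError,
    ReinforcementSchedule,
    SampleEvent,
    SampleWindow,
    classify_event,
    compute_max_earnings,
    default_plan,
    perfect_event_stream,
    process_event_stream,
    reward_for_event,
)


def _ev(**kw):
    base = dict(
        participant_id="P001",
        day_index=1,
        window_index=1,
        submitted=True,
        offset_minutes=5.0,
        brac=0.0,
        match_score=95.0,
        staff_confirmed=None,
    )
    base.update(kw)
    return SampleEvent(**base)


ESC = ReinforcementSchedule(mode="escalating", base_amount=2.00, increment=0.25, cap=3.50)
FLAT = ReinforcementSchedule(mode="flat", base_amount=2.00)


class TestClassify:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(brac=0.0, match_score=95.0), "negative_verified"),
            (dict(submitted=False, offset_minutes=None, brac=None, match_score=None), "missed"),
            (dict(brac=0.05, match_score=95.0), "positive"),
            (dict(brac=0.0, match_score=79.9), "unverified"),
            (dict(brac=0.0, match_score=80.0), "negative_verified"),  # tie confirms
            (dict(offset_minutes=31.0), "out_of_window"),
            (dict(offset_minutes=-1.0), "out_of_window"),  # early submission
            # staff decision overrides the automated score in both directions
            (dict(brac=0.0, match_score=95.0, staff_confirmed=False), "unverified"),
            (dict(brac=0.0, match_score=40.0, staff_confirmed=True), "negative_verified"),
            # identity check precedes the alcohol result
            (dict(brac=0.10, match_score=40.0), "unverified"),
        ],
    )
    def test_outcomes(self, kwargs, expected):
        assert classify_event(_ev(**kwargs), threshold=80.0) == expected

    def test_negative_brac_rejected(self):
        with pytest.raises(ProtocolError, match="brac"):
            _ev(brac=-0.01)

    def test_submitted_requires_fields(self):
        with pytest.raises(ProtocolError, match="offset_minutes"):
            SampleEvent("P001", 1, 1, submitted=True, brac=0.0, match_score=95.0)

    def test_unsubmitted_must_be_null(self):
        with pytest.raises(ProtocolError, match="brac"):
            SampleEvent("P001", 1, 1, submitted=False, brac=0.0)

    def test_bad_threshold(self):
        with pytest.raises(ProtocolError, match="threshold"):
            classify_event(_ev(), threshold=101)

    def test_wider_window_accepts_late_submission(self):
        ev = _ev(offset_minutes=45.0)
        assert classify_event(ev, window=SampleWindow(window_minutes=30)) == "out_of_window"
        assert classify_event(ev, window=SampleWindow(window_minutes=60)) == "negative_verified"


class TestReward:
    @pytest.mark.parametrize(
        "outcome, condition, state, amount, new_state",
        [
            ("negative_verified", "cm", 0, 200, 1),   # first negative pays base
            ("negative_verified", "cm", 5, 325, 6),
            ("negative_verified", "cm", 6, 350, 7),   # cap reached
            ("negative_verified", "cm", 7, 350, 8),   # stays at cap
            ("positive", "cm", 5, 0, 0),              # reset
            ("missed", "cm", 3, 0, 0),
            ("unverified", "cm", 3, 0, 0),
            ("out_of_window", "cm", 3, 0, 0),         # late counts as missed
            ("positive", "control", 4, 200, 4),       # independent of sample result
            ("negative_verified", "control", 0, 200, 0),
            ("unverified", "control", 0, 200, 0),
            ("missed", "control", 0, 0, 0),
            ("out_of_window", "control", 0, 0, 0),
        ],
    )
    def test_amount_and_state(self, outcome, condition, state, amount, new_state):
        sched = ESC if condition == "cm" else FLAT
        assert reward_for_event(outcome, condition, state, sched) == (amount, new_state)

    def test_control_unverified_config_flag(self):
        amt, _ = reward_for_event(
            "unverified", "control", 0, FLAT, control_pays_unverified=False
        )
        assert amt == 0

    def test_unknown_outcome(self):
        with pytest.raises(ProtocolError, match="outcome"):
            reward_for_event("bogus", "cm", 0, ESC)

    def test_unknown_condition(self):
        with pytest.raises(ProtocolError, match="condition"):
            reward_for_event("missed", "treatment", 0, ESC)

    def test_reset_outcomes_configurable(self):
        sched = ReinforcementSchedule(
            mode="escalating", reset_outcomes=frozenset({"positive"})
        )
        # a miss neither pays nor resets under this schedule
        assert reward_for_event("missed", "cm", 4, sched) == (0, 4)


def _cm_only_plan(days, slots=3):
    return PhasePlan(
        phases=(Phase("B", "cm", days, ESC),),
        window=SampleWindow(
            scheduled_times=("09:00", "14:00", "20:00")[:slots]
        ),
    )


class TestStream:
    def test_escalation_and_reset_hand_trace(self):
        plan = _cm_only_plan(2)
        events = [
            _ev(day_index=1, window_index=1),
            _ev(day_index=1, window_index=2),
            SampleEvent("P001", 1, 3, submitted=False),
            _ev(day_index=2, window_index=1),
        ]
        decisions, ledgers = process_event_stream(events, plan)
        amounts = [d.amount_usd for d in decisions[:4]]
        assert amounts == [2.00, 2.25, 0.0, 2.00]

    def test_perfect_participant_earns_maximum(self, plan):
        decisions, ledgers = process_event_stream(perfect_event_stream(plan), plan)
        assert ledgers["P01"].earned_total == pytest.approx(456.75)
        assert len(decisions) == plan.total_slots

    def test_all_missed_earns_nothing(self, plan):
        events = [SampleEvent("P001", 1, 1, submitted=False)]
        _, ledgers = process_event_stream(events, plan)
        assert ledgers["P001"].earned_total == 0.0

    def test_state_resets_at_phase_boundary(self):
        plan = PhasePlan(
            phases=(Phase("B1", "cm", 1, ESC), Phase("B2", "cm", 1, ESC)),
            window=SampleWindow(),
        )
        events = [
            _ev(day_index=d, window_index=w) for d in (1, 2) for w in (1, 2, 3)
        ]
        decisions, _ = process_event_stream(events, plan)
        amounts = [d.amount_usd for d in decisions]
        # escalation restarts from base in the second phase
        assert amounts == [2.00, 2.25, 2.50, 2.00, 2.25, 2.50]

    def test_state_persists_overnight_within_phase(self):
        plan = _cm_only_plan(2)
        events = [
            _ev(day_index=d, window_index=w) for d in (1, 2) for w in (1, 2, 3)
        ]
        decisions, _ = process_event_stream(events, plan)
        assert [d.amount_usd for d in decisions] == [2.00, 2.25, 2.50, 2.75, 3.00, 3.25]

    def test_duplicate_slot_rejected(self, plan):
        events = [_ev(), _ev()]
        with pytest.raises(ProtocolError, match="duplicate"):
            process_event_stream(events, plan)

    def test_day_outside_plan_rejected(self, plan):
        with pytest.raises(ProtocolError, match="day_index"):
            process_event_stream([_ev(day_index=57)], plan)

    def test_missing_slots_autofilled_as_missed(self):
        plan = _cm_only_plan(1)
        decisions, _ = process_event_stream([_ev(day_index=1, window_index=2)], plan)
        assert [d.outcome for d in decisions] == [
            "missed",
            "negative_verified",
            "missed",
        ]

    def test_participant_order_invariance(self, plan):
        rng = np.random.default_rng(5)
        events = []
        for pid in ("PA", "PB", "PC"):
            for day in range(1, 57):
                for w in (1, 2, 3):
                    if rng.random() < 0.6:
                        events.append(
                            _ev(
                                participant_id=pid,
                                day_index=day,
                                window_index=w,
                                brac=0.05 if rng.random() < 0.2 else 0.0,
                            )
                        )
        _, ledgers1 = process_event_stream(events, plan)
        rng.shuffle(events)
        _, ledgers2 = process_event_stream(events, plan)
        assert {p: l.earned_total for p, l in ledgers1.items()} == {
            p: l.earned_total for p, l in ledgers2.items()
        }


class TestMaxEarnings:
    def test_default_plan(self, plan):
        assert compute_max_earnings(plan) == pytest.approx(456.75)

    def test_cm_only_toy_plan_brute_force(self):
        # 12 slots: ramp 2.00..3.25 (6 uncapped) then 6 at the 3.50 cap
        plan = _cm_only_plan(4)
        expected = sum(min(2.00 + 0.25 * k, 3.50) for k in range(12))
        assert expected == pytest.approx(36.75)
        assert compute_max_earnings(plan) == pytest.approx(expected)

    def test_degenerate_flat_escalation(self):
        sched = ReinforcementSchedule(
            mode="escalating", base_amount=1.50, increment=0.0, cap=1.50
        )
        plan = PhasePlan(phases=(Phase("B", "cm", 5, sched),), window=SampleWindow())
        assert compute_max_earnings(plan) == pytest.approx(5 * 3 * 1.50)

    def test_oracle_equivalence_on_randomized_plans(self):
        """Closed form equals the engine run on the perfect participant."""
        rng = np.random.default_rng(123)
        times = ("06:00", "09:00", "12:00", "15:00", "18:00")
        for _ in range(100):
            n_phases = rng.integers(1, 4)
            slots = int(rng.integers(1, 6))
            phases = []
            for j in range(n_phases):
                base = round(float(rng.uniform(0.25, 5.0)), 2)
                if rng.random() < 0.5:
                    sched = ReinforcementSchedule(mode="flat", base_amount=base)
                    cond = "control"
                else:
                    inc = round(float(rng.uniform(0.0, 1.0)), 2)
                    cap = round(base + float(rng.uniform(0.0, 3.0)), 2)
                    sched = ReinforcementSchedule(
                        mode="escalating", base_amount=base, increment=inc, cap=cap
                    )
                    cond = "cm"
                phases.append(
                    Phase(f"PH{j}", cond, int(rng.integers(1, 31)), sched)
                )
            plan = PhasePlan(
                phases=tuple(phases),
                window=SampleWindow(scheduled_times=times[:slots], window_minutes=30),
            )
            _, ledgers = process_event_stream(perfect_event_stream(plan), plan)
            assert ledgers["P01"].earned_total == pytest.approx(
                compute_max_earnings(plan)
            )


class TestLedger:
    def test_bank_moves_available(self):
        led = Ledger()
        led.earn(1000)
        led.bank(4.00)
        assert (led.available, led.banked, led.earned_total) == (6.00, 4.00, 10.00)

    def test_redeem_drains_available_then_bank(self):
        led = Ledger()
        led.earn(1000)
        led.bank(6.00)
        led.redeem(7.00)
        assert (led.available, led.banked, led.redeemed) == (0.00, 3.00, 7.00)

    def test_redeem_beyond_balance_rejected(self):
        led = Ledger()
        led.earn(200)
        led.redeem(2.00)
        with pytest.raises(InsufficientFundsError):
            led.redeem(0.01)
        assert led.redeemed == 2.00 and led.available == 0.0

    def test_bank_beyond_available_rejected(self):
        led = Ledger()
        led.earn(500)
        led.bank(5.00)
        with pytest.raises(InsufficientFundsError):
            led.bank(0.01)

    @given(
        st.lists(
            st.tuples(st.sampled_from(["earn", "bank", "redeem"]),
                      st.integers(min_value=1, max_value=500)),
            max_size=60,
        )
    )
    def test_conservation_under_random_transactions(self, ops):
        """earned == available + banked + redeemed after any valid sequence."""
        led = Ledger()
        for kind, cents in ops:
            try:
                if kind == "earn":
                    led.earn(cents)
                elif kind == "bank":
                    led.bank(cents / 100)
                else:
                    led.redeem(cents / 100)
            except InsufficientFundsError:
                pass
            assert led.earned_cents == (
                led.available_cents + led.banked_cents + led.redeemed_cents
            )
            assert led.available_cents >= 0 and led.banked_cents >= 0


@given(
    st.lists(
        st.sampled_from(["negative_verified", "positive", "unverified", "missed",
                         "out_of_window"]),
        min_size=1,
        max_size=80,
    )
)
def test_escalation_monotonicity(outcomes):
    """Within an unbroken run of verified negatives the CM amounts are
    non-decreasing and capped; the first negative after any reset pays base."""
    state = 0
    prev_amount = None
    after_reset = True
    for outcome in outcomes:
        amount, state = reward_for_event(outcome, "cm", state, ESC)
        if outcome == "negative_verified":
            if after_reset:
                assert amount == ESC.base_cents
            elif prev_amount is not None:
                assert amount >= prev_amount
            assert amount <= ESC.cap_cents
            prev_amount = amount
            after_reset = False
        else:
            assert amount == 0
            prev_amount = None
            after_reset = True
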