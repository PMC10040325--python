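"""Reward engine for an A-B-A remote breathalyzer monitoring trial.

The engine is a deterministic state machine: a stream of scheduled
breathalyzer-sample events (submitted or not, alcohol-negative or not,
identity verified or not) is turned into per-event reward decisions and a
running money ledger.  Two reinforcement rules are supported:

* ``flat`` — a fixed payment for every sample submitted inside its window,
  independent of the sample result (the control condition);
* ``escalating`` — payment starts at a base value and grows by a fixed
  increment for every *consecutive* verified alcohol-negative sample, up to
  a cap; a missed, alcohol-positive or identity-unverified sample resets the
  next payment to the base value (the contingency-management condition).

All money is held in integer cents internally; public constructors and
accessors use USD floats with two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "OUTCOMES",
    "ProtocolError",
    "InsufficientFundsError",
    "usd_to_cents",
    "cents_to_usd",
    "SampleWindow",
    "ReinforcementSchedule",
    "Phase",
    "PhasePlan",
    "default_plan",
    "SampleEvent",
    "RewardDecision",
    "Ledger",
    "classify_event",
    "reward_for_event",
    "process_event_stream",
    "compute_max_earnings",
]

#: Possible classifications of a scheduled sample slot.
OUTCOMES = ("negative_verified", "positive", "unverified", "missed", "out_of_window")


class ProtocolError(ValueError):
    """Validation failure in an event, schedule or plan (names the field)."""


class InsufficientFundsError(ProtocolError):
    """A bank/redeem request exceeds the source balance."""


def usd_to_cents(amount: float) -> int:
    """Convert a USD amount (at most 2 decimals) to integer cents."""
    cents = round(float(amount) * 100)
    if abs(cents - float(amount) * 100) > 1e-6:
        raise ProtocolError(f"amount {amount!r} is not a whole number of cents")
    return int(cents)


def cents_to_usd(cents: int) -> float:
    return cents / 100.0


def _parse_clock(text: str) -> int:
    """'HH:MM' -> minutes since midnight."""
    try:
        hh, mm = text.split(":")
        minutes = int(hh) * 60 + int(mm)
    except (ValueError, AttributeError) as exc:
        raise ProtocolError(f"scheduled_times: bad clock time {text!r}") from exc
    if not 0 <= minutes < 24 * 60:
        raise ProtocolError(f"scheduled_times: {text!r} outside 00:00-23:59")
    return minutes


@dataclass(frozen=True)
class SampleWindow:
    """Daily sample schedule: clock times and the acceptance window.

    A submission is in-window when its offset from the scheduled time lies in
    ``[0, window_minutes]`` (submissions are accepted *after* the prompt, not
    before it).
    """

    scheduled_times: tuple[str, ...] = ("09:00", "14:00", "20:00")
    window_minutes: int = 30

    def __post_init__(self) -> None:
        if self.window_minutes <= 0:
            raise ProtocolError("window_minutes: must be > 0")
        minutes = [_parse_clock(t) for t in self.scheduled_times]
        if not minutes:
            raise ProtocolError("scheduled_times: at least one time required")
        for a, b in zip(minutes, minutes[1:]):
            if b <= a:
                raise ProtocolError("scheduled_times: must be strictly increasing")
            if a + self.window_minutes > b:
                raise ProtocolError("scheduled_times: windows overlap")

    @property
    def slots_per_day(self) -> int:
        return len(self.scheduled_times)

    def in_window(self, offset_minutes: float) -> bool:
        return 0.0 <= offset_minutes <= self.window_minutes


@dataclass(frozen=True)
class ReinforcementSchedule:
    """Parameters of a flat or escalating-with-reset reward rule.

    Amounts are USD.  ``increment``, ``cap`` and ``reset_outcomes`` only
    apply in ``escalating`` mode.  The default escalating parameters are the
    $2.00 base / $0.25 step / $3.50 cap voucher schedule with reset after a
    missed, alcohol-positive or identity-unverified sample.
    """

    mode: str = "flat"
    base_amount: float = 2.00
    increment: float = 0.25
    cap: float = 3.50
    reset_outcomes: frozenset[str] = frozenset({"missed", "positive", "unverified"})

    def __post_init__(self) -> None:
        if self.mode not in ("flat", "escalating"):
            raise ProtocolError(f"mode: unknown schedule mode {self.mode!r}")
        if self.base_amount <= 0:
            raise ProtocolError("base_amount: must be > 0")
        if self.mode == "escalating":
            if self.increment < 0:
                raise ProtocolError("increment: must be >= 0")
            if self.cap < self.base_amount:
                raise ProtocolError("cap: must be >= base_amount")
            bad = set(self.reset_outcomes) - {"missed", "positive", "unverified"}
            if bad:
                raise ProtocolError(f"reset_outcomes: unknown outcomes {sorted(bad)}")
        object.__setattr__(self, "reset_outcomes", frozenset(self.reset_outcomes))

    @property
    def base_cents(self) -> int:
        return usd_to_cents(self.base_amount)

    @property
    def increment_cents(self) -> int:
        return usd_to_cents(self.increment)

    @property
    def cap_cents(self) -> int:
        return usd_to_cents(self.cap)

    def amount_cents(self, level: int) -> int:
        """Reward in cents at a given escalation level (consecutive-negative count)."""
        if level < 0:
            raise ProtocolError("escalation level: must be >= 0")
        if self.mode == "flat":
            return self.base_cents
        return min(self.base_cents + level * self.increment_cents, self.cap_cents)


@dataclass(frozen=True)
class Phase:
    label: str
    condition: str  # "control" | "cm"
    duration_days: int
    schedule: ReinforcementSchedule

    def __post_init__(self) -> None:
        if self.condition not in ("control", "cm"):
            raise ProtocolError(f"condition: unknown condition {self.condition!r}")
        if self.duration_days < 1:
            raise ProtocolError("duration_days: must be >= 1")


@dataclass(frozen=True)
class PhasePlan:
    """Ordered study phases plus the daily sample window.

    Phase day ranges partition ``[1, total_days]`` in order.
    """

    phases: tuple[Phase, ...]
    window: SampleWindow = field(default_factory=SampleWindow)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.phases:
            raise ProtocolError("phases: at least one phase required")
        labels = [p.label for p in self.phases]
        if len(set(labels)) != len(labels):
            raise ProtocolError("phases: duplicate phase labels")

    @property
    def total_days(self) -> int:
        return sum(p.duration_days for p in self.phases)

    @property
    def slots_per_day(self) -> int:
        return self.window.slots_per_day

    @property
    def total_slots(self) -> int:
        return self.total_days * self.slots_per_day

    def day_range(self, label: str) -> tuple[int, int]:
        """Inclusive (first_day, last_day) of a phase."""
        start = 1
        for p in self.phases:
            end = start + p.duration_days - 1
            if p.label == label:
                return start, end
            start = end + 1
        raise ProtocolError(f"phase label {label!r} not in plan")

    def phase_of_day(self, day_index: int) -> Phase:
        if day_index < 1 or day_index > self.total_days:
            raise ProtocolError(
                f"day_index: {day_index} outside plan days [1, {self.total_days}]"
            )
        start = 1
        for p in self.phases:
            if day_index < start + p.duration_days:
                return p
            start += p.duration_days
        raise AssertionError("unreachable")


def default_plan(window_minutes: int = 30) -> PhasePlan:
    """The default 14/28/14-day A-B-A plan with 3 samples/day.

    Control phases (A1, A2) pay $2.00 flat per in-window submission; the CM
    phase (B) runs the $2.00/+$0.25/$3.50 escalating schedule with reset.
    """
    flat = ReinforcementSchedule(mode="flat", base_amount=2.00)
    esc = ReinforcementSchedule(
        mode="escalating", base_amount=2.00, increment=0.25, cap=3.50
    )
    return PhasePlan(
        phases=(
            Phase("A1", "control", 14, flat),
            Phase("B", "cm", 28, esc),
            Phase("A2", "control", 14, flat),
        ),
        window=SampleWindow(window_minutes=window_minutes),
    )


@dataclass(frozen=True)
class SampleEvent:
    """One scheduled breathalyzer slot and what happened in it.

    ``brac`` is breath alcohol content in g/dL; 0.00 encodes alcohol-negative.
    ``match_score`` is the automated facial-match score in percent.
    ``staff_confirmed`` is the staff identity decision (gold standard) or
    ``None`` when only the automated score is available.
    """

    participant_id: str
    day_index: int
    window_index: int
    submitted: bool
    offset_minutes: float | None = None
    brac: float | None = None
    match_score: float | None = None
    staff_confirmed: bool | None = None

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ProtocolError(f"day_index: must be >= 1, got {self.day_index}")
        if self.window_index < 1:
            raise ProtocolError(f"window_index: must be >= 1, got {self.window_index}")
        if not self.submitted:
            for name in ("offset_minutes", "brac", "match_score"):
                if getattr(self, name) is not None:
                    raise ProtocolError(f"{name}: must be null when submitted is false")
        else:
            if self.offset_minutes is None:
                raise ProtocolError("offset_minutes: required when submitted")
            if self.brac is None:
                raise ProtocolError("brac: required when submitted")
            if self.brac < 0:
                raise ProtocolError(f"brac: must be >= 0, got {self.brac}")
            if self.match_score is None and self.staff_confirmed is None:
                raise ProtocolError(
                    "match_score: required when submitted and staff_confirmed is null"
                )
            if self.match_score is not None and not 0 <= self.match_score <= 100:
                raise ProtocolError(
                    f"match_score: must be in [0, 100], got {self.match_score}"
                )


@dataclass(frozen=True)
class RewardDecision:
    """Per-event payout decision.

    ``escalation_level`` is the consecutive verified-negative count *before*
    this event (escalating mode; always 0 in control phases).
    """

    event: SampleEvent
    outcome: str
    amount_cents: int
    escalation_level: int

    @property
    def amount_usd(self) -> float:
        return cents_to_usd(self.amount_cents)


class Ledger:
    """Running money state for one participant.

    Conservation invariant: ``earned_total == available + banked + redeemed``
    after every transaction; no transaction may drive any balance negative.
    Redemption draws from the available balance first, then from the bank.
    """

    def __init__(self) -> None:
        self.earned_cents = 0
        self.available_cents = 0
        self.banked_cents = 0
        self.redeemed_cents = 0
        self.transactions: list[dict] = []

    # -- USD views -------------------------------------------------------
    @property
    def earned_total(self) -> float:
        return cents_to_usd(self.earned_cents)

    @property
    def available(self) -> float:
        return cents_to_usd(self.available_cents)

    @property
    def banked(self) -> float:
        return cents_to_usd(self.banked_cents)

    @property
    def redeemed(self) -> float:
        return cents_to_usd(self.redeemed_cents)

    def _check(self) -> None:
        assert self.earned_cents == (
            self.available_cents + self.banked_cents + self.redeemed_cents
        ), "ledger conservation violated"
        assert min(
            self.earned_cents,
            self.available_cents,
            self.banked_cents,
            self.redeemed_cents,
        ) >= 0, "negative ledger balance"

    def earn(self, cents: int, ref: object = None) -> None:
        if cents < 0:
            raise ProtocolError("earn amount: must be >= 0")
        if cents == 0:
            return
        self.earned_cents += cents
        self.available_cents += cents
        self.transactions.append({"kind": "earn", "amount_cents": cents, "ref": ref})
        self._check()

    def bank(self, amount_usd: float, ref: object = None) -> None:
        cents = usd_to_cents(amount_usd)
        if cents <= 0:
            raise ProtocolError("bank amount: must be > 0")
        if cents > self.available_cents:
            raise InsufficientFundsError(
                f"bank {cents_to_usd(cents):.2f} exceeds available "
                f"{self.available:.2f}"
            )
        self.available_cents -= cents
        self.banked_cents += cents
        self.transactions.append({"kind": "bank", "amount_cents": cents, "ref": ref})
        self._check()

    def redeem(self, amount_usd: float, ref: object = None) -> None:
        cents = usd_to_cents(amount_usd)
        if cents <= 0:
            raise ProtocolError("redeem amount: must be > 0")
        if cents > self.available_cents + self.banked_cents:
            raise InsufficientFundsError(
                f"redeem {cents_to_usd(cents):.2f} exceeds balance "
                f"{cents_to_usd(self.available_cents + self.banked_cents):.2f}"
            )
        from_available = min(cents, self.available_cents)
        self.available_cents -= from_available
        self.banked_cents -= cents - from_available
        self.redeemed_cents += cents
        self.transactions.append({"kind": "redeem", "amount_cents": cents, "ref": ref})
        self._check()

    def to_dict(self) -> dict:
        return {
            "earned_total": self.earned_total,
            "available": self.available,
            "banked": self.banked,
            "redeemed": self.redeemed,
            "n_transactions": len(self.transactions),
        }


def classify_event(
    event: SampleEvent, threshold: float = 80.0, window: SampleWindow | None = None
) -> str:
    """Classify one sample slot.

    Precedence: not submitted -> ``missed``; submitted outside the acceptance
    window -> ``out_of_window``; identity not confirmed -> ``unverified``
    (staff decision overrides the automated match score when present);
    BrAC > 0 -> ``positive``; otherwise ``negative_verified``.
    """
    if not 0 <= threshold <= 100:
        raise ProtocolError(f"threshold: must be in [0, 100], got {threshold}")
    window = window or SampleWindow()
    if not event.submitted:
        return "missed"
    if not window.in_window(event.offset_minutes):
        return "out_of_window"
    if event.staff_confirmed is not None:
        verified = bool(event.staff_confirmed)
    else:
        verified = event.match_score >= threshold
    if not verified:
        return "unverified"
    if event.brac > 0:
        return "positive"
    return "negative_verified"


def reward_for_event(
    outcome: str,
    phase_condition: str,
    escalation_state: int,
    schedule: ReinforcementSchedule,
    *,
    control_pays_unverified: bool = True,
) -> tuple[int, int]:
    """Reward (in cents) for one classified event and the next escalation state.

    Control condition: the base amount for any in-window submission
    independent of the sample result (identity-unverified submissions pay by
    default, configurable); nothing for missed or late slots; escalation
    state untouched.  CM condition: escalating amount for a verified
    negative with the state incremented; any reset-trigger outcome pays
    nothing and clears the state.
    """
    if outcome not in OUTCOMES:
        raise ProtocolError(f"outcome: unknown outcome {outcome!r}")
    if phase_condition not in ("control", "cm"):
        raise ProtocolError(f"condition: unknown condition {phase_condition!r}")
    if escalation_state < 0:
        raise ProtocolError("escalation_state: must be >= 0")

    if phase_condition == "control":
        if outcome in ("negative_verified", "positive"):
            return schedule.base_cents, escalation_state
        if outcome == "unverified":
            return (schedule.base_cents if control_pays_unverified else 0), escalation_state
        return 0, escalation_state

    # CM condition
    if outcome == "negative_verified":
        return schedule.amount_cents(escalation_state), escalation_state + 1
    trigger = "missed" if outcome == "out_of_window" else outcome
    if trigger in schedule.reset_outcomes:
        return 0, 0
    return 0, escalation_state


def process_event_stream(
    events: Iterable[SampleEvent],
    plan: PhasePlan,
    threshold: float = 80.0,
    *,
    control_pays_unverified: bool = True,
) -> tuple[list[RewardDecision], dict[str, Ledger]]:
    """Run the reward engine over a full event stream.

    Emits exactly one decision per scheduled slot per participant (slots
    absent from the stream are auto-filled as missed).  The escalation state
    is carried across days within a phase and reinitialised to 0 at every
    phase boundary.  Duplicate (participant, day, window) rows and days
    outside the plan are errors.  Decisions for a participant depend only on
    that participant's events.
    """
    by_participant: dict[str, dict[tuple[int, int], SampleEvent]] = {}
    for ev in events:
        if ev.day_index > plan.total_days:
            raise ProtocolError(
                f"day_index: {ev.day_index} outside plan days [1, {plan.total_days}] "
                f"(participant {ev.participant_id})"
            )
        if ev.window_index > plan.slots_per_day:
            raise ProtocolError(
                f"window_index: {ev.window_index} exceeds {plan.slots_per_day} "
                f"windows/day (participant {ev.participant_id})"
            )
        slots = by_participant.setdefault(ev.participant_id, {})
        key = (ev.day_index, ev.window_index)
        if key in slots:
            raise ProtocolError(
                f"duplicate slot: participant {ev.participant_id}, "
                f"day {key[0]}, window {key[1]}"
            )
        slots[key] = ev

    decisions: list[RewardDecision] = []
    ledgers: dict[str, Ledger] = {}
    for pid in sorted(by_participant):
        slots = by_participant[pid]
        ledger = Ledger()
        state = 0
        current_label = None
        for day in range(1, plan.total_days + 1):
            phase = plan.phase_of_day(day)
            if phase.label != current_label:
                current_label = phase.label
                state = 0
            for w in range(1, plan.slots_per_day + 1):
                ev = slots.get((day, w))
                if ev is None:
                    ev = SampleEvent(pid, day, w, submitted=False)
                outcome = classify_event(ev, threshold, plan.window)
                amount, new_state = reward_for_event(
                    outcome,
                    phase.condition,
                    state,
                    phase.schedule,
                    control_pays_unverified=control_pays_unverified,
                )
                decisions.append(RewardDecision(ev, outcome, amount, state))
                if amount:
                    ledger.earn(amount, ref=(pid, day, w))
                state = new_state
        ledgers[pid] = ledger
    return decisions, ledgers


def compute_max_earnings(plan: PhasePlan) -> float:
    """Closed-form maximum earnings (USD) for a perfect participant.

    A perfect participant submits every scheduled sample in-window, verified
    and alcohol-negative.  Flat phases contribute days x slots x base; an
    escalating phase contributes the ramp from base to cap followed by the
    cap for the remaining slots.  Equals ``process_event_stream`` on the
    all-negative perfect event log (tested as an oracle property).
    """
    total = 0
    slots_per_day = plan.slots_per_day
    for phase in plan.phases:
        s = phase.duration_days * slots_per_day
        sched = phase.schedule
        if sched.mode == "flat" or sched.increment_cents == 0:
            total += s * (
                sched.base_cents if sched.mode == "flat" else sched.amount_cents(0)
            )
            continue
        # first level at which the cap binds
        k_cap = math.ceil((sched.cap_cents - sched.base_cents) / sched.increment_cents)
        m = min(s, k_cap)
        total += m * sched.base_cents + sched.increment_cents * m * (m - 1) // 2
        total += (s - m) * sched.cap_cents
    return cents_to_usd(total)


def perfect_event_stream(
    plan: PhasePlan, participant_id: str = "P01"
) -> list[SampleEvent]:
    """The all-negative, always-on-time, always-verified event log."""
    return [
        SampleEvent(
            participant_id,
            day,
            w,
            submitted=True,
            offset_minutes=0.0,
            brac=0.0,
            match_score=100.0,
            staff_confirmed=True,
        )
        for day in range(1, plan.total_days + 1)
        for w in range(1, plan.slots_per_day + 1)
    ]
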