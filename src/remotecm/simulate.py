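"""Synthetic participant behavior for remote breathalyzer monitoring.

Generates cohorts of sample-event logs with the statistical structure of a
small A-B-A contingency-management trial: per-phase adherence, drinking
(alcohol-positive) rates, a three-part facial-match-score mixture
(genuine-good / genuine-low-quality / impostor), technical submission
failures, and occasional late submissions.

Design: one root seed; each participant draws from an independent
substream derived from ``SeedSequence((seed, participant_index, purpose))``
so cohorts are reproducible and order-independent.  All per-slot
randomness for a participant is drawn up-front as arrays in a fixed order,
which both vectorises the expensive draws and gives common random numbers
across parameter changes (raising ``cm_effect`` with the same seed can
only turn positives into negatives, never the reverse).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .protocol import PhasePlan, ProtocolError, SampleEvent, default_plan

__all__ = [
    "BetaPrior",
    "TruncNormalPrior",
    "PopulationPriors",
    "ParticipantProfile",
    "SimulationConfig",
    "draw_profiles",
    "simulate_events",
    "simulate_cohort",
]


def _check_prob(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ProtocolError(f"{name}: probability must be in [0, 1], got {value}")
    return float(value)


@dataclass(frozen=True)
class BetaPrior:
    """Beta(mean*kappa, (1-mean)*kappa); kappa is the concentration.

    ``kappa = inf`` (or mean 0/1) degenerates to a point mass at the mean.
    """

    mean: float
    kappa: float = 40.0

    def __post_init__(self) -> None:
        _check_prob("prior mean", self.mean)
        if self.kappa <= 0:
            raise ProtocolError(f"kappa: must be > 0, got {self.kappa}")

    def draw(self, rng: np.random.Generator) -> float:
        if not np.isfinite(self.kappa) or self.mean in (0.0, 1.0):
            return self.mean
        return float(rng.beta(self.mean * self.kappa, (1 - self.mean) * self.kappa))


@dataclass(frozen=True)
class TruncNormalPrior:
    """Normal(mean, sd) truncated to [low, high]."""

    mean: float
    sd: float
    low: float = 0.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ProtocolError(f"sd: must be >= 0, got {self.sd}")
        if self.high < self.low:
            raise ProtocolError("truncation bounds: high < low")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.low, self.high))
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return float(
            truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng)
        )


@dataclass(frozen=True)
class PopulationPriors:
    """Population distributions the per-participant profiles are drawn from.

    Defaults are calibrated so a default 12-participant cohort reproduces,
    in expectation, the aggregate behavior of a small feasibility trial:
    per-phase submission fractions near 0.815 / 0.694 / 0.494, about 14% of
    submitted samples alcohol-positive, roughly 7% of images scoring below
    the 80% match cut-off, and about 1% impostor submissions.
    """

    p_submit: dict = field(
        default_factory=lambda: {
            "A1": BetaPrior(0.83, 40),
            "B": BetaPrior(0.71, 40),
            "A2": BetaPrior(0.50, 40),
        }
    )
    p_positive: BetaPrior = BetaPrior(0.158, 60)
    cm_effect: TruncNormalPrior = TruncNormalPrior(0.04, 0.02, 0.0, 0.5)
    p_lowquality: BetaPrior = BetaPrior(0.06, 80)
    p_impostor: BetaPrior = BetaPrior(0.01, 200)
    p_techfail: BetaPrior = BetaPrior(0.02, 100)
    p_late: float = 0.02


@dataclass(frozen=True)
class ParticipantProfile:
    """Behavioral parameters of one simulated participant.

    ``p_submit`` maps phase label -> probability a scheduled sample is
    attempted; ``p_positive`` is the per-submission probability of an
    alcohol-positive sample in control phases; ``cm_effect`` is subtracted
    from it (clamped at 0) in CM phases.  ``p_lowquality`` / ``p_impostor``
    drive the match-score mixture; ``p_techfail`` is the probability an
    attempted submission is lost to an app failure.
    """

    participant_id: str
    p_submit: dict
    p_positive: float
    cm_effect: float
    p_lowquality: float
    p_impostor: float
    p_techfail: float
    p_late: float = 0.02
    brac_range: tuple[float, float] = (0.01, 0.21)

    def __post_init__(self) -> None:
        for label, p in self.p_submit.items():
            _check_prob(f"p_submit[{label}]", p)
        for name in ("p_positive", "cm_effect", "p_lowquality", "p_impostor",
                     "p_techfail", "p_late"):
            _check_prob(name, getattr(self, name))
        lo, hi = self.brac_range
        if not (0 < lo <= hi <= 0.5):
            raise ProtocolError(f"brac_range: must satisfy 0 < low <= high <= 0.5, got {self.brac_range}")

    def p_positive_effective(self, condition: str) -> float:
        if condition == "cm":
            return min(max(self.p_positive - self.cm_effect, 0.0), 1.0)
        return self.p_positive


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 12
    plan: PhasePlan = field(default_factory=default_plan)
    seed: int = 0
    priors: PopulationPriors = field(default_factory=PopulationPriors)
    brac_range: tuple[float, float] = (0.01, 0.21)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ProtocolError(
                f"n_participants: must be >= 1, got {self.n_participants}"
            )


def _participant_rng(seed: int, index: int, purpose: int) -> np.random.Generator:
    """Substream for participant ``index``; purpose 0 = profile, 1 = events."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index), purpose)))


def draw_profiles(config: SimulationConfig) -> list[ParticipantProfile]:
    """Draw one behavioral profile per participant, deterministic in the seed."""
    labels = [p.label for p in config.plan.phases]
    missing = [lab for lab in labels if lab not in config.priors.p_submit]
    if missing:
        raise ProtocolError(f"p_submit prior missing for phases {missing}")
    profiles = []
    for i in range(1, config.n_participants + 1):
        rng = _participant_rng(config.seed, i, 0)
        # fixed draw order keeps profiles stable under config extension
        p_submit = {lab: config.priors.p_submit[lab].draw(rng) for lab in labels}
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i:03d}",
                p_submit=p_submit,
                p_positive=config.priors.p_positive.draw(rng),
                cm_effect=config.priors.cm_effect.draw(rng),
                p_lowquality=config.priors.p_lowquality.draw(rng),
                p_impostor=config.priors.p_impostor.draw(rng),
                p_techfail=config.priors.p_techfail.draw(rng),
                p_late=config.priors.p_late,
                brac_range=config.brac_range,
            )
        )
    return profiles


def simulate_events(
    profile: ParticipantProfile, plan: PhasePlan, rng: np.random.Generator
) -> list[SampleEvent]:
    """Simulate one participant's full event log (one event per slot).

    All randomness is drawn as fixed-order arrays over the slot grid before
    any event is assembled (common random numbers across parameter values).
    """
    n = plan.total_slots
    w = plan.window
    u_submit = rng.random(n)
    u_techfail = rng.random(n)
    u_late = rng.random(n)
    offset_in = np.round(rng.uniform(0.0, w.window_minutes, n), 1)
    offset_late = np.round(w.window_minutes + rng.uniform(1.0, 60.0, n), 1)
    u_positive = rng.random(n)
    brac_pos = np.round(rng.uniform(*profile.brac_range, n), 2)
    u_impostor = rng.random(n)
    u_lowq = rng.random(n)
    score_good = np.round(
        truncnorm.rvs(
            (80 - 95) / 3.0, (100 - 95) / 3.0, loc=95.0, scale=3.0, size=n,
            random_state=rng,
        ),
        1,
    )
    score_lowq = np.round(rng.uniform(40.0, 80.0, n), 1)
    score_imp = np.round(rng.uniform(0.0, 60.0, n), 1)

    events = []
    k = 0
    for day in range(1, plan.total_days + 1):
        phase = plan.phase_of_day(day)
        p_sub = profile.p_submit[phase.label]
        p_pos = profile.p_positive_effective(phase.condition)
        for win in range(1, plan.slots_per_day + 1):
            submitted = (
                u_submit[k] < p_sub and u_techfail[k] >= profile.p_techfail
            )
            if not submitted:
                events.append(SampleEvent(profile.participant_id, day, win, False))
            else:
                late = u_late[k] < profile.p_late
                offset = float(offset_late[k] if late else offset_in[k])
                brac = float(brac_pos[k]) if u_positive[k] < p_pos else 0.0
                if u_impostor[k] < profile.p_impostor:
                    score, staff = float(score_imp[k]), False
                elif u_lowq[k] < profile.p_lowquality:
                    score, staff = float(score_lowq[k]), True
                else:
                    score, staff = float(score_good[k]), True
                events.append(
                    SampleEvent(
                        profile.participant_id,
                        day,
                        win,
                        True,
                        offset_minutes=offset,
                        brac=brac,
                        match_score=score,
                        staff_confirmed=staff,
                    )
                )
            k += 1
    return events


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleEvent], list[ParticipantProfile]]:
    """Simulate the full cohort; reproducible and order-independent."""
    profiles = draw_profiles(config)
    events: list[SampleEvent] = []
    for i, profile in enumerate(profiles, start=1):
        rng = _participant_rng(config.seed, i, 1)
        events.extend(simulate_events(profile, config.plan, rng))
    return events, profiles


def profiles_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"participant_id": p.participant_id}
        row.update({f"p_submit_{lab}": v for lab, v in p.p_submit.items()})
        row.update(
            {
                "p_positive": p.p_positive,
                "cm_effect": p.cm_effect,
                "p_lowquality": p.p_lowquality,
                "p_impostor": p.p_impostor,
                "p_techfail": p.p_techfail,
                "p_late": p.p_late,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
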