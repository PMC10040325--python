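"""Feasibility and efficacy analysis of an A-B-A monitoring trial.

Feasibility: submission counts and rates (overall and per phase), samples
per day, per-participant retention in weeks, and the share of participants
above submission-adherence thresholds.  Efficacy: the proportion of
verified alcohol-negative samples per phase (under both a per-scheduled
and a per-submitted denominator) and an exchangeable-GEE fit of the phase
effect on the participant-day percent-negative outcome, with sex, age and
baseline EtG (ethylglucuronide, binary at the 500 ng/mL cut-off) as
covariates.

Conventions: an alcohol-positive count is defined from BrAC > 0 among
submitted samples regardless of identity verification; verified-negative
counts require identity confirmation, so identity-unverified submissions
count toward feasibility but never toward efficacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gee import ExchangeableGEE, ExchangeableGEEResults
from .protocol import PhasePlan, ProtocolError, SampleEvent, classify_event
from .verification import MatchRecord, verification_metrics

__all__ = [
    "FeasibilityReport",
    "feasibility_report",
    "negative_rates",
    "build_outcome_table",
    "fit_gee",
    "analysis_report",
]

REPORT_VERSION = "1.0"

_ADHERENCE_THRESHOLDS = (0.55, 0.75)


def _classified(
    events: Sequence[SampleEvent], plan: PhasePlan, threshold: float
) -> pd.DataFrame:
    """One row per event with its phase label and engine classification."""
    rows = []
    for ev in events:
        phase = plan.phase_of_day(ev.day_index)
        rows.append(
            {
                "participant_id": ev.participant_id,
                "day_index": ev.day_index,
                "window_index": ev.window_index,
                "phase_label": phase.label,
                "condition": phase.condition,
                "submitted": ev.submitted,
                "brac": ev.brac,
                "match_score": ev.match_score,
                "staff_confirmed": ev.staff_confirmed,
                "outcome": classify_event(ev, threshold, plan.window),
            }
        )
    df = pd.DataFrame(rows)
    dup = df.duplicated(["participant_id", "day_index", "window_index"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ProtocolError(
            "duplicate slot: participant "
            f"{first['participant_id']}, day {first['day_index']}, "
            f"window {first['window_index']}"
        )
    return df


@dataclass
class FeasibilityReport:
    n_participants: int
    total_possible: int
    total_submitted: int
    per_phase: dict  # label -> {possible, submitted, rate}
    mean_samples_per_day: float
    sd_samples_per_day: float
    positive_count: int
    positive_fraction: float
    negatives_per_phase: dict  # label -> {negatives, rate_scheduled, rate_submitted}
    retention_weeks: dict  # participant_id -> weeks
    retention_mean: float
    retention_sd: float
    fraction_above_thresholds: dict  # "0.55" -> fraction of participants

    @property
    def submission_rate(self) -> float:
        return self.total_submitted / self.total_possible

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "total_possible": self.total_possible,
            "total_submitted": self.total_submitted,
            "submission_rate": self.submission_rate,
            "per_phase": self.per_phase,
            "mean_samples_per_day": self.mean_samples_per_day,
            "sd_samples_per_day": self.sd_samples_per_day,
            "positive_count": self.positive_count,
            "positive_fraction": self.positive_fraction,
            "negatives_per_phase": self.negatives_per_phase,
            "retention_weeks": self.retention_weeks,
            "retention_mean": self.retention_mean,
            "retention_sd": self.retention_sd,
            "fraction_above_thresholds": self.fraction_above_thresholds,
        }


def feasibility_report(
    events: Sequence[SampleEvent],
    plan: PhasePlan,
    threshold: float = 80.0,
    *,
    count_late_as_submitted: bool = False,
) -> FeasibilityReport:
    """Submission feasibility measures over the full cohort.

    A slot counts as submitted when a sample arrived inside its window;
    late (out-of-window) submissions are excluded from the feasibility
    denominator unless ``count_late_as_submitted`` is set.  Retention is
    (last counted-submission day)/7 in weeks.
    """
    df = _classified(events, plan, threshold)
    participants = sorted(df["participant_id"].unique())
    n = len(participants)
    if n == 0:
        raise ProtocolError("no participants in event stream")

    counted = df["submitted"] & (
        (df["outcome"] != "out_of_window") | count_late_as_submitted
    )
    df = df.assign(counted=counted)

    slots = plan.slots_per_day
    per_phase = {}
    for phase in plan.phases:
        possible = n * phase.duration_days * slots
        sub = int(df.loc[df["phase_label"] == phase.label, "counted"].sum())
        per_phase[phase.label] = {
            "possible": possible,
            "submitted": sub,
            "rate": sub / possible,
        }
    total_possible = n * plan.total_slots
    total_submitted = int(df["counted"].sum())

    # daily counts over the full participant-day grid (days with no events count 0)
    daily = (
        df.groupby(["participant_id", "day_index"])["counted"].sum()
        .reindex(
            pd.MultiIndex.from_product(
                [participants, range(1, plan.total_days + 1)],
                names=["participant_id", "day_index"],
            ),
            fill_value=0,
        )
    )
    mean_per_day = total_submitted / (n * plan.total_days)
    sd_per_day = float(daily.std(ddof=1)) if len(daily) > 1 else 0.0

    positive_count = int(((df["brac"].fillna(0) > 0) & df["counted"]).sum())
    positive_fraction = positive_count / total_submitted if total_submitted else 0.0

    negatives_per_phase = {}
    for phase in plan.phases:
        sel = df["phase_label"] == phase.label
        neg = int((df.loc[sel, "outcome"] == "negative_verified").sum())
        possible = per_phase[phase.label]["possible"]
        sub = per_phase[phase.label]["submitted"]
        negatives_per_phase[phase.label] = {
            "negatives": neg,
            "rate_scheduled": neg / possible,
            "rate_submitted": neg / sub if sub else None,
        }

    retention = {}
    for pid in participants:
        days = df.loc[(df["participant_id"] == pid) & df["counted"], "day_index"]
        retention[pid] = (int(days.max()) / 7.0) if len(days) else 0.0
    rvals = np.array(list(retention.values()))
    retention_mean = float(rvals.mean())
    retention_sd = float(rvals.std(ddof=1)) if n > 1 else 0.0

    possible_each = plan.total_slots
    totals = df.groupby("participant_id")["counted"].sum()
    fraction_above = {
        f"{t:.2f}": float((totals >= t * possible_each).mean())
        for t in _ADHERENCE_THRESHOLDS
    }

    return FeasibilityReport(
        n_participants=n,
        total_possible=total_possible,
        total_submitted=total_submitted,
        per_phase=per_phase,
        mean_samples_per_day=mean_per_day,
        sd_samples_per_day=sd_per_day,
        positive_count=positive_count,
        positive_fraction=positive_fraction,
        negatives_per_phase=negatives_per_phase,
        retention_weeks=retention,
        retention_mean=retention_mean,
        retention_sd=retention_sd,
        fraction_above_thresholds=fraction_above,
    )


def negative_rates(
    events: Sequence[SampleEvent],
    plan: PhasePlan,
    denominator: str = "scheduled",
    threshold: float = 80.0,
) -> dict[str, float | None]:
    """Per-phase verified-alcohol-negative rates.

    ``denominator="scheduled"`` divides by every scheduled slot;
    ``"submitted"`` divides by in-window submissions only.  Both
    conventions appear in feasibility reporting and give materially
    different numbers when adherence differs across phases.
    """
    if denominator not in ("scheduled", "submitted"):
        raise ProtocolError(f"denominator: unknown convention {denominator!r}")
    report = feasibility_report(events, plan, threshold)
    key = "rate_scheduled" if denominator == "scheduled" else "rate_submitted"
    return {
        label: stats[key] for label, stats in report.negatives_per_phase.items()
    }


def build_outcome_table(
    events: Sequence[SampleEvent],
    plan: PhasePlan,
    covariates: pd.DataFrame,
    threshold: float = 80.0,
) -> pd.DataFrame:
    """Participant-day outcome table for the phase-effect model.

    One row per participant-day; ``y`` is the percentage (0-100) of that
    day's scheduled samples that were verified alcohol-negative.  The
    covariate frame must provide ``sex`` (M/F or 0/1), ``age`` and binary
    ``baseline_etg`` per participant; missing participants are an error.
    """
    df = _classified(events, plan, threshold)
    participants = sorted(df["participant_id"].unique())

    cov = covariates.copy()
    if "participant_id" not in cov.columns:
        raise ProtocolError("covariates: participant_id column required")
    cov = cov.set_index("participant_id")
    missing = [p for p in participants if p not in cov.index]
    if missing:
        raise ProtocolError(f"covariates missing for participants: {missing}")
    if cov["sex"].dtype == object:
        sex_map = {"M": 0.0, "F": 1.0, "m": 0.0, "f": 1.0}
        bad = sorted(set(cov["sex"]) - set(sex_map))
        if bad:
            raise ProtocolError(f"covariates: unknown sex codes {bad}")
        cov = cov.assign(sex=cov["sex"].map(sex_map))

    slots = plan.slots_per_day
    neg = (
        df.assign(is_neg=(df["outcome"] == "negative_verified").astype(int))
        .groupby(["participant_id", "day_index"])["is_neg"]
        .sum()
        .reindex(
            pd.MultiIndex.from_product(
                [participants, range(1, plan.total_days + 1)],
                names=["participant_id", "day_index"],
            ),
            fill_value=0,
        )
        .reset_index()
    )
    neg["phase_label"] = [
        plan.phase_of_day(d).label for d in neg["day_index"]
    ]
    neg["y"] = 100.0 * neg["is_neg"] / slots
    for col in ("sex", "age", "baseline_etg"):
        neg[col] = neg["participant_id"].map(cov[col]).astype(float)
    return neg[
        ["participant_id", "day_index", "phase_label", "y", "sex", "age", "baseline_etg"]
    ]


def fit_gee(
    table: pd.DataFrame,
    reference_phase: str = "B",
    *,
    small_sample: bool = False,
    covariate_names: Sequence[str] = ("sex", "age", "baseline_etg"),
) -> ExchangeableGEEResults:
    """Fit the phase-effect GEE on a participant-day outcome table.

    Identity-link, Gaussian-variance GEE with exchangeable working
    correlation; clusters are participants.  Phase indicators use
    ``reference_phase`` (the CM phase by convention) as the reference, so
    each phase coefficient is that phase's adjusted percentage-point
    difference from the CM condition.
    """
    labels = list(
        table.groupby("phase_label")["day_index"].min().sort_values().index
    )
    if reference_phase not in labels:
        raise ProtocolError(f"reference phase {reference_phase!r} not present")
    others = [lab for lab in labels if lab != reference_phase]
    data = table.copy()
    for lab in others:
        data[f"phase_{lab}"] = (data["phase_label"] == lab).astype(float)
    predictors = [f"phase_{lab}" for lab in others] + list(covariate_names)
    model = ExchangeableGEE.from_dataframe(
        data, outcome="y", predictors=predictors, group="participant_id"
    )
    return model.fit(small_sample=small_sample)


def analysis_report(
    events: Sequence[SampleEvent],
    plan: PhasePlan,
    covariates: pd.DataFrame | None = None,
    threshold: float = 80.0,
    *,
    reference_phase: str = "B",
    small_sample: bool = False,
) -> dict:
    """Bundle feasibility, efficacy, identity metrics and the GEE into one report.

    The GEE section is present only when a covariate frame is supplied.
    Identity metrics use every submitted sample that carries both a match
    score and a staff decision.
    """
    feas = feasibility_report(events, plan, threshold)
    report = {
        "version": REPORT_VERSION,
        "plan": {
            "phases": [
                {
                    "label": p.label,
                    "condition": p.condition,
                    "duration_days": p.duration_days,
                }
                for p in plan.phases
            ],
            "slots_per_day": plan.slots_per_day,
            "total_days": plan.total_days,
        },
        "feasibility": feas.to_dict(),
        "negative_rates": {
            "scheduled": negative_rates(events, plan, "scheduled", threshold),
            "submitted": negative_rates(events, plan, "submitted", threshold),
        },
    }
    records = [
        MatchRecord(ev.match_score, ev.staff_confirmed)
        for ev in events
        if ev.submitted and ev.match_score is not None and ev.staff_confirmed is not None
    ]
    if records:
        report["identity_verification"] = verification_metrics(records, threshold)
    if covariates is not None:
        table = build_outcome_table(events, plan, covariates, threshold)
        result = fit_gee(
            table, reference_phase=reference_phase, small_sample=small_sample
        )
        report["gee"] = result.to_dict()
    return report
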