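"""Deterministic reconstruction of the 12-participant feasibility pilot.

Only aggregate counts of the pilot cohort are public (per-phase submission
and verified-negative counts, alcohol-positive totals, facial-match score
bands, adherence and retention summaries), so this module fabricates a
fixed participant-level event log whose aggregates equal every published
count.  The participant-level allocation is arbitrary but frozen; every
statistic the analysis modules compute from it reproduces the published
aggregate exactly.

Aggregate targets built in:

* 2016 scheduled slots (12 participants x 56 days x 3 windows);
* 411 / 700 / 249 in-window submissions in phases A1 / B / A2 (1360 total);
* 64 / 85 / 40 alcohol-positive samples (189 total, BrAC 0.01-0.21);
* verified negatives 347 / 615 / 209;
* 1266 images at or above the 80% match cut-off (all staff-confirmed),
  94 below it of which 13 staff-unconfirmed — the 13 are placed on
  alcohol-positive submissions, the only placement consistent with the
  verified-negative counts above;
* 10 of 12 participants above 55% adherence, 7 of 12 above 75%;
* 10 participants retained to day 56, 2 to day 35 (mean retention 7.5 weeks).
"""

from __future__ import annotations

import pandas as pd

from .protocol import PhasePlan, SampleEvent, default_plan

__all__ = ["pilot_cohort", "pilot_covariates", "PILOT_SUBMISSIONS"]

# per-participant in-window submission counts by phase (sums: 411/700/249)
PILOT_SUBMISSIONS: dict[str, tuple[int, int, int]] = {
    "P001": (38, 70, 25),
    "P002": (38, 70, 25),
    "P003": (38, 70, 25),
    "P004": (38, 70, 25),
    "P005": (38, 70, 25),
    "P006": (38, 70, 25),
    "P007": (38, 70, 25),
    "P008": (28, 51, 24),
    "P009": (28, 51, 25),
    "P010": (29, 52, 25),
    "P011": (30, 28, 0),
    "P012": (30, 28, 0),
}

# the two early-exit participants stop submitting after day 35
_LAST_DAY = {"P011": 35, "P012": 35}

_POSITIVES_PER_PHASE = {"A1": 64, "B": 85, "A2": 40}
_UNVERIFIED_PER_PHASE = {"A1": 5, "B": 5, "A2": 3}  # sums to 13
_N_LOWQUALITY_CONFIRMED = 81  # staff-confirmed images below the cut-off

_BRAC_CYCLE = (0.01, 0.05, 0.10, 0.15, 0.21)

_SCORE_GOOD = 95.0
_SCORE_LOWQUALITY = 65.0
_SCORE_UNVERIFIED = 50.0


def pilot_cohort(plan: PhasePlan | None = None) -> list[SampleEvent]:
    """The frozen pilot event log: one row per scheduled slot (2016 events)."""
    plan = plan or default_plan()
    labels = [p.label for p in plan.phases]

    # choose submitted slots: per participant and phase, the *last* k slots
    # of the eligible day range (which pins retention to the intended day)
    submitted: set[tuple[str, int, int]] = set()
    for pid, counts in PILOT_SUBMISSIONS.items():
        for label, k in zip(labels, counts):
            first, last = plan.day_range(label)
            last = min(last, _LAST_DAY.get(pid, last))
            slots = [
                (d, w)
                for d in range(first, last + 1)
                for w in range(1, plan.slots_per_day + 1)
            ]
            for d, w in slots[len(slots) - k:]:
                submitted.add((pid, d, w))

    # alcohol-positive samples: the chronologically first n_pos submissions
    # of each phase; the first few of those are the staff-unconfirmed images
    positive: dict[tuple[str, int, int], float] = {}
    unverified: set[tuple[str, int, int]] = set()
    for label in labels:
        first, last = plan.day_range(label)
        phase_slots = sorted(
            (d, w, pid) for (pid, d, w) in submitted if first <= d <= last
        )
        n_pos = _POSITIVES_PER_PHASE.get(label, 0)
        for j, (d, w, pid) in enumerate(phase_slots[:n_pos]):
            positive[(pid, d, w)] = _BRAC_CYCLE[j % len(_BRAC_CYCLE)]
            if j < _UNVERIFIED_PER_PHASE.get(label, 0):
                unverified.add((pid, d, w))

    # low-quality but staff-confirmed images: the chronologically first 81
    # submissions that are not already staff-unconfirmed
    lowquality: set[tuple[str, int, int]] = set()
    for d, w, pid in sorted((d, w, pid) for (pid, d, w) in submitted):
        if len(lowquality) == _N_LOWQUALITY_CONFIRMED:
            break
        if (pid, d, w) not in unverified:
            lowquality.add((pid, d, w))

    events = []
    for pid in sorted(PILOT_SUBMISSIONS):
        for d in range(1, plan.total_days + 1):
            for w in range(1, plan.slots_per_day + 1):
                key = (pid, d, w)
                if key not in submitted:
                    events.append(SampleEvent(pid, d, w, submitted=False))
                    continue
                if key in unverified:
                    score, staff = _SCORE_UNVERIFIED, False
                elif key in lowquality:
                    score, staff = _SCORE_LOWQUALITY, True
                else:
                    score, staff = _SCORE_GOOD, True
                events.append(
                    SampleEvent(
                        pid,
                        d,
                        w,
                        submitted=True,
                        offset_minutes=5.0,
                        brac=positive.get(key, 0.0),
                        match_score=score,
                        staff_confirmed=staff,
                    )
                )
    return events


def pilot_covariates() -> pd.DataFrame:
    """Synthetic baseline covariates matching published marginals.

    9 of 12 male; ages average 39.5 years; 11 of 12 EtG-positive at the
    500 ng/mL cut-off.  Individual values are fabricated (the pilot
    publishes only these marginals) and frozen.
    """
    ages = [25, 31, 34, 36, 38, 39, 41, 43, 45, 48, 52, 42]
    rows = []
    for i, pid in enumerate(sorted(PILOT_SUBMISSIONS), start=1):
        rows.append(
            {
                "participant_id": pid,
                "sex": "M" if i <= 9 else "F",
                "age": ages[i - 1],
                "baseline_etg": 0 if pid == "P005" else 1,
            }
        )
    return pd.DataFrame(rows)
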