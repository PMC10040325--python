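"""Reading and writing the standard CSV/JSON/YAML artifacts.

CSV dialect: UTF-8, comma-separated, LF line endings, mandatory headers,
empty field = null.  Lines starting with ``#`` are provenance comments and
are skipped on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from ._version import __version__
from .protocol import (
    Ledger,
    Phase,
    PhasePlan,
    ProtocolError,
    ReinforcementSchedule,
    RewardDecision,
    SampleEvent,
    SampleWindow,
)
from .verification import MatchRecord

EVENT_COLUMNS = [
    "participant_id",
    "day_index",
    "window_index",
    "submitted",
    "offset_minutes",
    "brac",
    "match_score",
    "staff_confirmed",
]

DECISION_COLUMNS = [
    "participant_id",
    "day_index",
    "window_index",
    "outcome",
    "amount_usd",
    "escalation_level",
]


def provenance_line(seed: int | None = None, config_text: str | None = None) -> str:
    parts = [f"remotecm {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_text is not None:
        digest = hashlib.sha256(config_text.encode()).hexdigest()[:12]
        parts.append(f"config_sha256={digest}")
    return "# " + " | ".join(parts)


def _bool_str(value: bool | None) -> str:
    return "" if value is None else ("true" if value else "false")


def _opt(value, fmt: str) -> str:
    return "" if value is None else format(value, fmt)


def events_to_frame(events: Sequence[SampleEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": ev.participant_id,
                "day_index": ev.day_index,
                "window_index": ev.window_index,
                "submitted": "true" if ev.submitted else "false",
                "offset_minutes": _opt(ev.offset_minutes, ".1f"),
                "brac": _opt(ev.brac, ".2f"),
                "match_score": _opt(ev.match_score, ".1f"),
                "staff_confirmed": _bool_str(ev.staff_confirmed),
            }
            for ev in events
        ],
        columns=EVENT_COLUMNS,
    )


def write_events(
    events: Sequence[SampleEvent], path: str | Path, header_line: str | None = None
) -> None:
    path = Path(path)
    frame = events_to_frame(events)
    with open(path, "w", newline="\n") as fh:
        if header_line:
            fh.write(header_line + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def _parse_bool(text: str, field: str) -> bool:
    if text in ("true", "True", "1"):
        return True
    if text in ("false", "False", "0"):
        return False
    raise ProtocolError(f"{field}: cannot parse boolean from {text!r}")


def read_events(path: str | Path) -> list[SampleEvent]:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ProtocolError(f"event log missing columns: {missing}")
    if df.empty:
        raise ProtocolError("event log is empty")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            SampleEvent(
                participant_id=row.participant_id,
                day_index=int(row.day_index),
                window_index=int(row.window_index),
                submitted=_parse_bool(row.submitted, "submitted"),
                offset_minutes=float(row.offset_minutes) if row.offset_minutes else None,
                brac=float(row.brac) if row.brac else None,
                match_score=float(row.match_score) if row.match_score else None,
                staff_confirmed=(
                    _parse_bool(row.staff_confirmed, "staff_confirmed")
                    if row.staff_confirmed
                    else None
                ),
            )
        )
    return events


def write_decisions(
    decisions: Sequence[RewardDecision], path: str | Path, header_line: str | None = None
) -> None:
    frame = pd.DataFrame(
        [
            {
                "participant_id": d.event.participant_id,
                "day_index": d.event.day_index,
                "window_index": d.event.window_index,
                "outcome": d.outcome,
                "amount_usd": f"{d.amount_usd:.2f}",
                "escalation_level": d.escalation_level,
            }
            for d in decisions
        ],
        columns=DECISION_COLUMNS,
    )
    with open(path, "w", newline="\n") as fh:
        if header_line:
            fh.write(header_line + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def write_ledgers(ledgers: dict[str, Ledger], path: str | Path, provenance: dict | None = None) -> None:
    payload = {
        "provenance": provenance or {"version": __version__},
        "ledgers": {pid: ledger.to_dict() for pid, ledger in ledgers.items()},
        "cohort_earned_total": round(
            sum(ledger.earned_total for ledger in ledgers.values()), 2
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_matches(path: str | Path) -> list[MatchRecord]:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for col in ("match_score", "staff_confirmed"):
        if col not in df.columns:
            raise ProtocolError(f"match file missing column: {col}")
    if df.empty:
        raise ProtocolError("match file is empty")
    return [
        MatchRecord(
            float(row.match_score), _parse_bool(row.staff_confirmed, "staff_confirmed")
        )
        for row in df.itertuples(index=False)
    ]


def write_matches(
    records: Sequence[MatchRecord], path: str | Path, header_line: str | None = None
) -> None:
    frame = pd.DataFrame(
        [
            {"match_score": f"{r.match_score:.1f}",
             "staff_confirmed": _bool_str(r.staff_confirmed)}
            for r in records
        ],
        columns=["match_score", "staff_confirmed"],
    )
    with open(path, "w", newline="\n") as fh:
        if header_line:
            fh.write(header_line + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [
        c for c in ("participant_id", "sex", "age", "baseline_etg") if c not in df.columns
    ]
    if missing:
        raise ProtocolError(f"covariates file missing columns: {missing}")
    return df


def plan_from_dict(payload: dict) -> PhasePlan:
    """Build a PhasePlan from the plan block of a config mapping."""
    window_cfg = payload.get("windows", {})
    window = SampleWindow(
        scheduled_times=tuple(window_cfg.get("scheduled_times", ("09:00", "14:00", "20:00"))),
        window_minutes=int(window_cfg.get("window_minutes", 30)),
    )
    phases = []
    for ph in payload.get("phases", []):
        sched = ph.get("schedule", {})
        schedule = ReinforcementSchedule(
            mode=sched.get("mode", "flat"),
            base_amount=float(sched.get("base_amount", 2.00)),
            increment=float(sched.get("increment", 0.25)),
            cap=float(sched.get("cap", sched.get("base_amount", 3.50))),
            reset_outcomes=frozenset(
                sched.get("reset_outcomes", ("missed", "positive", "unverified"))
            ),
        )
        phases.append(
            Phase(
                label=str(ph["label"]),
                condition=str(ph["condition"]),
                duration_days=int(ph["duration_days"]),
                schedule=schedule,
            )
        )
    if not phases:
        raise ProtocolError("plan: no phases defined")
    return PhasePlan(phases=tuple(phases), window=window)


def load_config_text(path: str | Path) -> tuple[dict, str]:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text), text
    return yaml.safe_load(text), text
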