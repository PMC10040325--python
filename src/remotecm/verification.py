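"""Identity-verification accuracy of automated facial matching.

Each breathalyzer submission carries an automated facial-match score
(percent similarity to a reference image) and a staff identity decision,
treated as the gold standard.  A submission is auto-confirmed when its
score meets a cut-off (default 80, ties confirm).  This module builds the
resulting confusion matrix and the usual accuracy metrics, with exact
Clopper-Pearson intervals since true negatives are typically very scarce
in this setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import beta as _beta_dist

__all__ = [
    "MatchRecord",
    "ConfusionMatrix",
    "classify_match",
    "build_confusion",
    "sensitivity",
    "specificity",
    "clopper_pearson",
    "threshold_sweep",
]


class VerificationError(ValueError):
    pass


@dataclass(frozen=True)
class MatchRecord:
    """One image: automated match score (percent) and the staff gold standard."""

    match_score: float
    staff_confirmed: bool

    def __post_init__(self) -> None:
        if not 0 <= self.match_score <= 100:
            raise VerificationError(
                f"match_score: must be in [0, 100], got {self.match_score}"
            )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise VerificationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_match(score: float, threshold: float = 80.0) -> bool:
    """Automated identity confirmation: True iff score >= threshold."""
    if not 0 <= score <= 100:
        raise VerificationError(f"score: must be in [0, 100], got {score}")
    if not 0 <= threshold <= 100:
        raise VerificationError(f"threshold: must be in [0, 100], got {threshold}")
    return score >= threshold


def build_confusion(
    records: Sequence[MatchRecord], threshold: float = 80.0
) -> ConfusionMatrix:
    """Confusion matrix of automated confirmation against the staff decision."""
    records = list(records)
    if not records:
        raise VerificationError("records: empty list")
    tp = fp = tn = fn = 0
    for r in records:
        auto = classify_match(r.match_score, threshold)
        if auto and r.staff_confirmed:
            tp += 1
        elif auto and not r.staff_confirmed:
            fp += 1
        elif not auto and not r.staff_confirmed:
            tn += 1
        else:
            fn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(cm: ConfusionMatrix) -> float | None:
    """tp / (tp + fn); None when there are no gold-standard positives."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else None


def specificity(cm: ConfusionMatrix) -> float | None:
    """tn / (tn + fp); None when there are no gold-standard negatives."""
    denom = cm.tn + cm.fp
    return cm.tn / denom if denom else None


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float] | None:
    """Exact binomial confidence interval for a proportion k/n.

    Returns None for an empty denominator (undefined proportion).
    """
    if n == 0:
        return None
    if not 0 <= k <= n:
        raise VerificationError(f"k={k} outside [0, {n}]")
    lo = 0.0 if k == 0 else float(_beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(_beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def threshold_sweep(
    records: Sequence[MatchRecord], thresholds: Iterable[float]
) -> pd.DataFrame:
    """Confusion counts and sensitivity/specificity at each cut-off.

    As the cut-off increases, sensitivity is non-increasing and specificity
    non-decreasing (fewer images auto-confirm).
    """
    rows = []
    for t in thresholds:
        t = float(t)
        # allow 101 as a conventional "confirm nothing" cut-off in sweeps
        cm = build_confusion(records, min(t, 100.0)) if t <= 100 else _confirm_none(records)
        rows.append(
            {
                "threshold": t,
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
                "sensitivity": sensitivity(cm),
                "specificity": specificity(cm),
            }
        )
    return pd.DataFrame(rows)


def _confirm_none(records: Sequence[MatchRecord]) -> ConfusionMatrix:
    records = list(records)
    if not records:
        raise VerificationError("records: empty list")
    fn = sum(1 for r in records if r.staff_confirmed)
    tn = len(records) - fn
    return ConfusionMatrix(tp=0, fp=0, tn=tn, fn=fn)


def verification_metrics(
    records: Sequence[MatchRecord], threshold: float = 80.0
) -> dict:
    """Point estimates plus 95% Clopper-Pearson intervals, as a plain dict."""
    cm = build_confusion(records, threshold)
    sens = sensitivity(cm)
    spec = specificity(cm)
    below = cm.tn + cm.fn
    return {
        "threshold": threshold,
        "n_images": cm.total,
        "tp": cm.tp,
        "fp": cm.fp,
        "tn": cm.tn,
        "fn": cm.fn,
        "fraction_at_or_above_threshold": (cm.tp + cm.fp) / cm.total,
        "true_negative_share_below_threshold": (cm.tn / below) if below else None,
        "sensitivity": sens,
        "sensitivity_ci95": clopper_pearson(cm.tp, cm.tp + cm.fn),
        "specificity": spec,
        "specificity_ci95": clopper_pearson(cm.tn, cm.tn + cm.fp),
    }
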