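"""Event-matching and statistics for grip-detection studies.

Detected triggers (or in-game jumps) are matched one-to-one to
ground-truth squeeze events within a +/-0.2 s tolerance; matched pairs are
true positives, unmatched truth events false negatives, unmatched
detections false positives, and reliability is summarized as
F1 = 2 TP / (2 TP + FP + FN).

Group comparisons follow the exploratory-study convention of a liberal
critical p-value (alpha = 0.25) with two-sample t-tests (Welch by
default, paired variant available).  Questionnaire aggregation covers the
six-item 1-5 Likert user-satisfaction instrument (USEQ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchSummary",
    "GroupComparison",
    "match_events",
    "f1_score",
    "compare_groups",
    "summarize_useq",
    "useq_grand_mean",
    "descriptive_stats",
]

USEQ_QUESTIONS = ["Q1", "Q2", "Q3", "Q4", "Q5", "Q6"]


@dataclass(frozen=True)
class MatchSummary:
    """Confusion counts and F1 of a tolerance-based event matching."""

    tp: int
    fp: int
    fn: int

    @property
    def f1(self) -> float:
        return f1_score(self.tp, self.fp, self.fn)


@dataclass(frozen=True)
class GroupComparison:
    group_a_values: tuple
    group_b_values: tuple
    t_statistic: float
    p_value: float
    alpha: float = 0.25

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _check_sorted(name: str, values: np.ndarray) -> None:
    if np.any(np.diff(values) < 0):
        raise ValueError(f"{name} must be sorted in increasing time")


def match_events(
    truth_times, detected_times, tolerance_s: float = 0.2
) -> tuple[MatchSummary, list[tuple[float, float]]]:
    """One-to-one matching of truth events to detections within
    ``|dt| <= tolerance_s``.

    Greedy over truth events in increasing time, each matched to the
    earliest unused detection inside its tolerance window.  For
    equal-width windows this greedy is maximum-cardinality (an exchange
    argument: swapping any optimal matching toward earliest-eligible
    never loses a pair), so it agrees with brute-force optimal
    assignment.  Returns the confusion summary and the matched
    (truth, detection) time pairs.
    """
    truth = np.asarray(list(truth_times), dtype=float)
    det = np.asarray(list(detected_times), dtype=float)
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be non-negative")
    _check_sorted("truth_times", truth)
    _check_sorted("detected_times", det)
    used = np.zeros(det.size, dtype=bool)
    pairs: list[tuple[float, float]] = []
    j = 0
    for t in truth:
        while j < det.size and (used[j] or det[j] < t - tolerance_s):
            j += 1
        if j < det.size and det[j] <= t + tolerance_s:
            used[j] = True
            pairs.append((float(t), float(det[j])))
    tp = len(pairs)
    return MatchSummary(tp=tp, fp=int(det.size - tp), fn=int(truth.size - tp)), pairs


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); defined as 0 (with a warning) when
    all counts are zero."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("F1 undefined for all-zero counts; returning 0", stacklevel=2)
        return 0.0
    return 2 * tp / denom


def compare_groups(
    values_a,
    values_b,
    alpha: float = 0.25,
    paired: bool = False,
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test between groups (Welch by default;
    ``equal_var=True`` for the pooled-variance variant, ``paired=True``
    for a paired test)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        tuple(a), tuple(b), float(res.statistic), float(res.pvalue), alpha
    )


def summarize_useq(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a respondent x question Likert table.

    ``table`` must carry integer scores 1-5 in columns Q1..Q6 (a free-text
    Q7 column, if present, is ignored).  Returns per-question mean and
    sample SD plus a ``grand`` row whose mean is the mean of the six
    question means.
    """
    missing = [q for q in USEQ_QUESTIONS if q not in table.columns]
    if missing:
        raise ValueError(f"missing questionnaire columns: {missing}")
    if len(table) < 1:
        raise ValueError("need at least one respondent")
    scores = table[USEQ_QUESTIONS].astype(float)
    if ((scores < 1) | (scores > 5)).any().any():
        raise ValueError("Likert scores must lie in 1..5")
    means = scores.mean(axis=0)
    sds = scores.std(axis=0, ddof=1) if len(table) > 1 else pd.Series(0.0, index=USEQ_QUESTIONS)
    out = pd.DataFrame({"mean": means, "sd": sds})
    out.loc["grand"] = [float(means.mean()), float("nan")]
    return out


def useq_grand_mean(question_means) -> float:
    """Grand mean of the questionnaire: the mean of the six per-question
    mean responses."""
    means = np.asarray(list(question_means), dtype=float)
    if means.size != len(USEQ_QUESTIONS):
        raise ValueError(f"expected {len(USEQ_QUESTIONS)} question means")
    return float(np.mean(means))


def descriptive_stats(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("sample SD requires at least two values")
    return float(np.mean(x)), float(np.std(x, ddof=1))
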