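"""Accuracy, coverage and per-class metrics against a reference standard.

Two accuracy definitions are first-class, because a selective-prediction
framework has two natural denominators:

* ``accuracy_decided`` — correct decisions / decided items (the headline
  metric: how often the consensus is right *when it speaks*);
* ``accuracy_overall`` — correct decisions / all items, counting every
  withheld item as not correct.

They are tied by the exact count identity
``accuracy_overall = accuracy_decided * coverage``.  Counts, not floats, are
primary throughout; percentages are rounded to one decimal only at the
reporting layer.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd

from .core import (
    MISSING,
    ConsensusDecision,
    RaterAnswer,
    Status,
    TaskKind,
    parse_value,
)

__all__ = [
    "TruthRecord",
    "ClassMetrics",
    "MetricReport",
    "StratifiedReport",
    "truth_from_frame",
    "read_truth",
    "score_decisions",
    "score_single_rater",
    "score_by_stratum",
    "round_pct",
]

log = logging.getLogger(__name__)


def round_pct(fraction: Optional[float]) -> Optional[float]:
    """Fraction -> percentage rounded to one decimal (reporting convention)."""
    if fraction is None:
        return None
    return round(100.0 * fraction, 1)


@dataclass(frozen=True)
class TruthRecord:
    """Reference answer for one (item, task), with stratification flags."""

    item_id: str
    task: TaskKind
    true_value: Union[str, int]
    strata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass
class MetricReport:
    """Metric bundle for one set of decisions (or one rater) vs a reference."""

    n_items: int
    n_decided: int
    n_correct: int
    n_format_issue: int = 0
    per_class: list = field(default_factory=list)

    @property
    def coverage(self) -> float:
        return self.n_decided / self.n_items if self.n_items else 0.0

    @property
    def accuracy_decided(self) -> Optional[float]:
        """Correct / decided; absent (None) when nothing was decided."""
        if self.n_decided == 0:
            return None
        return self.n_correct / self.n_decided

    @property
    def accuracy_overall(self) -> float:
        """Correct / all items; a withheld item counts as not correct."""
        return self.n_correct / self.n_items if self.n_items else 0.0

    def to_dict(self) -> dict:
        return {
            "n_items": self.n_items,
            "n_decided": self.n_decided,
            "n_correct": self.n_correct,
            "n_format_issue": self.n_format_issue,
            "coverage": self.coverage,
            "accuracy_decided": self.accuracy_decided,
            "accuracy_overall": self.accuracy_overall,
            "coverage_pct": round_pct(self.coverage),
            "accuracy_decided_pct": round_pct(self.accuracy_decided),
            "accuracy_overall_pct": round_pct(self.accuracy_overall),
            "per_class": [
                {
                    "class": c.label,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f1": c.f1,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                }
                for c in self.per_class
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class StratifiedReport:
    """Per-stratum reports plus the derived accuracy contrast.

    ``accuracy_gap`` is accuracy_decided(flag False) − accuracy_decided(flag
    True) for a boolean flag — e.g. how much harder requires-calculation
    items are — and None when either stratum decided nothing.
    """

    flag_name: str
    reports: dict
    accuracy_gap: Optional[float] = None


# ---------------------------------------------------------------------------
# Truth-table interchange: CSV / JSON-lines with item_id, task, true_value and
# arbitrary boolean flag columns.
# ---------------------------------------------------------------------------

_RESERVED = {"item_id", "task", "true_value"}


def truth_from_frame(frame: pd.DataFrame) -> list[TruthRecord]:
    missing_cols = _RESERVED - set(frame.columns)
    if missing_cols:
        raise ValueError(f"truth table lacks columns {sorted(missing_cols)}")
    flag_cols = [c for c in frame.columns if c not in _RESERVED]
    seen = set()
    out = []
    for row in frame.itertuples(index=False):
        task = TaskKind(row.task)
        key = (str(row.item_id), task)
        if key in seen:
            raise ValueError(f"duplicate truth record for {key!r}")
        seen.add(key)
        strata = {}
        for c in flag_cols:
            v = getattr(row, c)
            if isinstance(v, str):
                v = v.strip().lower() in {"true", "1", "yes"}
            strata[c] = bool(v)
        out.append(
            TruthRecord(
                item_id=str(row.item_id),
                task=task,
                true_value=parse_value(row.true_value, task),
                strata=strata,
            )
        )
    return out


def read_truth(path) -> list[TruthRecord]:
    path = str(path)
    if path.endswith((".jsonl", ".ndjson")):
        frame = pd.read_json(path, lines=True, dtype={"true_value": str})
    else:
        frame = pd.read_csv(path, dtype={"true_value": str}, keep_default_na=False)
    return truth_from_frame(frame)


def _truth_map(truth: Union[Sequence[TruthRecord], pd.DataFrame]) -> dict:
    if isinstance(truth, pd.DataFrame):
        truth = truth_from_frame(truth)
    return {t.item_id: t for t in truth}


def _per_class(pairs: list[tuple]) -> list[ClassMetrics]:
    """Precision/recall/F1 per class over (predicted, true) pairs.

    Withheld items never appear here: abstentions are not predictions.
    F1 is defined as 0 when precision + recall = 0.
    """
    labels = sorted({p for p, _ in pairs} | {t for _, t in pairs}, key=str)
    out = []
    for lab in labels:
        tp = sum(1 for p, t in pairs if p == lab and t == lab)
        fp = sum(1 for p, t in pairs if p == lab and t != lab)
        fn = sum(1 for p, t in pairs if p != lab and t == lab)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        if precision + recall == 0.0:
            if tp + fp + fn:
                log.debug("class %r: precision + recall = 0, F1 set to 0", lab)
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        out.append(ClassMetrics(str(lab), precision, recall, f1, tp, fp, fn))
    return out


def _classification_pairs(task: TaskKind, pairs: list[tuple]) -> list[tuple]:
    # For extraction tasks, classification-style metrics are only meaningful
    # for the MISSING class; fold every numeric answer into one rest-class.
    if task is TaskKind.EXTRACTION:
        return [
            (
                MISSING if p == MISSING else "reported",
                MISSING if t == MISSING else "reported",
            )
            for p, t in pairs
        ]
    return pairs


def score_decisions(
    decisions: Sequence[ConsensusDecision],
    truth: Union[Sequence[TruthRecord], pd.DataFrame],
) -> MetricReport:
    """Score consensus decisions against a reference standard.

    Every decided item must be covered by ``truth``; a decided item absent
    from the reference is an error naming the item.
    """
    tmap = _truth_map(truth)
    n_decided = n_correct = 0
    pairs = []
    task = None
    for d in decisions:
        if not d.decided:
            continue
        rec = tmap.get(d.item_id)
        if rec is None:
            raise ValueError(f"decided item {d.item_id!r} absent from the truth table")
        task = rec.task
        n_decided += 1
        if d.value == rec.true_value:
            n_correct += 1
        pairs.append((d.value, rec.true_value))
    per_class = (
        _per_class(_classification_pairs(task, pairs)) if pairs and task else []
    )
    return MetricReport(
        n_items=len(decisions),
        n_decided=n_decided,
        n_correct=n_correct,
        per_class=per_class,
    )


def score_single_rater(
    responses: Sequence[RaterAnswer],
    truth: Union[Sequence[TruthRecord], pd.DataFrame],
) -> MetricReport:
    """Score one rater's raw responses against the reference.

    FORMAT_ISSUE / NO_RESPONSE rows count as incorrect in
    ``accuracy_overall`` and are excluded from ``accuracy_decided``; both
    variants are reported, along with the format-issue count, so either
    reading of an individual-accuracy table is reproducible.
    """
    raters = {a.rater_id for a in responses}
    if len(raters) > 1:
        raise ValueError(f"expected a single rater, got {sorted(raters)}")
    tmap = _truth_map(truth)
    n_valid = n_correct = n_format = 0
    pairs = []
    task = None
    for a in responses:
        rec = tmap.get(a.item_id)
        if rec is None:
            raise ValueError(f"item {a.item_id!r} absent from the truth table")
        task = rec.task
        if a.status is Status.FORMAT_ISSUE:
            n_format += 1
            continue
        if a.status is not Status.VALID:
            continue
        n_valid += 1
        if a.value == rec.true_value:
            n_correct += 1
        pairs.append((a.value, rec.true_value))
    per_class = (
        _per_class(_classification_pairs(task, pairs)) if pairs and task else []
    )
    return MetricReport(
        n_items=len(responses),
        n_decided=n_valid,
        n_correct=n_correct,
        n_format_issue=n_format,
        per_class=per_class,
    )


def score_by_stratum(
    decisions: Sequence[ConsensusDecision],
    truth: Union[Sequence[TruthRecord], pd.DataFrame],
    flag_name: str,
) -> StratifiedReport:
    """Independent metric reports per stratum of a truth-table flag.

    For a boolean flag the report also carries the accuracy contrast between
    the False and True strata (positive when flagged items are harder).
    """
    if isinstance(truth, pd.DataFrame):
        truth = truth_from_frame(truth)
    tmap = {t.item_id: t for t in truth}
    for t in truth:
        if flag_name not in t.strata:
            raise ValueError(
                f"flag {flag_name!r} not defined for item {t.item_id!r}"
            )
    groups: dict = {}
    for d in decisions:
        rec = tmap.get(d.item_id)
        if rec is None:
            raise ValueError(f"item {d.item_id!r} absent from the truth table")
        groups.setdefault(rec.strata[flag_name], []).append(d)
    reports = {}
    for value in sorted(groups, key=str):
        sub_truth = [t for t in truth if t.strata[flag_name] == value]
        reports[value] = score_decisions(groups[value], sub_truth)
    gap = None
    if set(reports) == {False, True}:
        a_false = reports[False].accuracy_decided
        a_true = reports[True].accuracy_decided
        if a_false is not None and a_true is not None:
            gap = a_false - a_true
    return StratifiedReport(flag_name=flag_name, reports=reports, accuracy_gap=gap)
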