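"""Agreement-threshold consensus over multi-rater panels.

The decision rule at the heart of the package: an item's answer is accepted
("decided") only when at least ``threshold`` of the ``n_models`` raters on the
panel give the *identical* answer; otherwise the decision is withheld and the
item is left for human review.  The rule is unweighted — every rater's vote
counts once — and applies to two task kinds:

* CATEGORICAL — answers drawn from a finite label set (here drug / nondrug
  intervention labels for randomized-trial abstracts);
* EXTRACTION — answers are non-negative integers (the number of randomized
  patients) or the distinguished token :data:`MISSING`, matched by exact
  integer equality after normalization.

Responses whose structured output could not be parsed carry status
FORMAT_ISSUE: they occupy a panel slot but can never support any answer, so a
panel with ``f`` unparseable responses can only decide when
``threshold <= n_valid``.
"""

from __future__ import annotations

import enum
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from typing import Any, Optional, Union

import pandas as pd

__all__ = [
    "MISSING",
    "DRUG",
    "NONDRUG",
    "DEFAULT_LABELS",
    "TaskKind",
    "Status",
    "DecisionStatus",
    "RaterAnswer",
    "ConsensusRule",
    "Tally",
    "ConsensusDecision",
    "tally_answers",
    "decide_item",
    "decide_batch",
    "parse_value",
    "format_value",
    "answers_from_frame",
    "answers_to_frame",
    "read_responses",
    "decisions_to_frame",
    "write_decisions",
]

#: Distinguished extraction answer meaning "the abstract reports no sample
#: size".  A first-class answer value: a panel can reach consensus on it.
MISSING = "missing"

DRUG = "drug"
NONDRUG = "nondrug"
#: Default label set for the binary intervention-classification task.
DEFAULT_LABELS = (DRUG, NONDRUG)

#: An answer value: a categorical label, a non-negative integer, or MISSING.
AnswerValue = Union[str, int]


class TaskKind(str, enum.Enum):
    """The two task families the framework supports."""

    CATEGORICAL = "categorical"
    EXTRACTION = "extraction"


class Status(str, enum.Enum):
    """Per-response parse status."""

    VALID = "valid"
    FORMAT_ISSUE = "format_issue"
    NO_RESPONSE = "no_response"


class DecisionStatus(str, enum.Enum):
    DECIDED = "decided"
    WITHHELD = "withheld"


def _as_task(task: Union[TaskKind, str]) -> TaskKind:
    return TaskKind(task)


def _validate_value(task: TaskKind, value: AnswerValue) -> AnswerValue:
    if task is TaskKind.EXTRACTION:
        if value == MISSING:
            return MISSING
        if isinstance(value, bool) or not isinstance(value, int):
            raise ValueError(
                f"extraction value must be a non-negative int or {MISSING!r}, "
                f"got {value!r}"
            )
        if value < 0:
            raise ValueError(f"extraction value must be non-negative, got {value!r}")
        return int(value)
    if not isinstance(value, str):
        raise ValueError(f"categorical value must be a string label, got {value!r}")
    return value


@dataclass(frozen=True)
class RaterAnswer:
    """One rater's response to one item.

    ``value`` is present iff ``status`` is VALID.  For EXTRACTION tasks the
    value is stored fully normalized: a plain non-negative ``int`` or the
    token :data:`MISSING` — never a formatted string.
    """

    item_id: str
    rater_id: str
    task: TaskKind
    status: Status = Status.VALID
    value: Optional[AnswerValue] = None
    rationale: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", _as_task(self.task))
        object.__setattr__(self, "status", Status(self.status))
        if self.status is Status.VALID:
            if self.value is None:
                raise ValueError(
                    f"VALID answer for item {self.item_id!r} by {self.rater_id!r} "
                    "has no value"
                )
            object.__setattr__(self, "value", _validate_value(self.task, self.value))
        elif self.value is not None:
            raise ValueError(
                f"{self.status.value} answer for item {self.item_id!r} by "
                f"{self.rater_id!r} must not carry a value"
            )


@dataclass(frozen=True)
class ConsensusRule:
    """The framework's two parameters: panel size N and agreement threshold T.

    A decision is taken only if at least ``threshold`` of the ``n_models``
    raters give the identical answer.  For binary categorical tasks,
    ``threshold > n_models // 2`` guarantees at most one label can reach the
    threshold (pigeonhole), so decisions are never ambiguous; smaller
    thresholds are legal but ties are then resolved by withholding.
    """

    n_models: int
    threshold: int

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError(f"n_models must be >= 1, got {self.n_models}")
        if not 1 <= self.threshold <= self.n_models:
            raise ValueError(
                f"threshold must satisfy 1 <= T <= N, got T={self.threshold}, "
                f"N={self.n_models}"
            )


@dataclass(frozen=True)
class Tally:
    """Vote counts over the VALID responses of one item.

    FORMAT_ISSUE and NO_RESPONSE rows never contribute to any answer's count;
    they are tracked separately.  MISSING is an ordinary countable answer for
    extraction tasks.
    """

    counts: dict
    n_valid: int
    n_format_issue: int
    n_no_response: int


@dataclass(frozen=True)
class ConsensusDecision:
    """Per-item consensus outcome."""

    item_id: str
    status: DecisionStatus
    value: Optional[AnswerValue] = None
    support: int = 0
    tally: dict = field(default_factory=dict)
    n_valid: int = 0
    n_format_issue: int = 0

    @property
    def decided(self) -> bool:
        return self.status is DecisionStatus.DECIDED


def _check_group(answers: Sequence[RaterAnswer], rule: ConsensusRule) -> None:
    if not answers:
        return
    item = answers[0].item_id
    task = answers[0].task
    seen: set = set()
    for a in answers:
        if a.item_id != item:
            raise ValueError(
                f"answers mix items {item!r} and {a.item_id!r}; tally one item at a time"
            )
        if a.task is not task:
            raise ValueError(
                f"answers for item {item!r} mix task kinds "
                f"{task.value} and {a.task.value}"
            )
        key = (a.item_id, a.rater_id)
        if key in seen:
            raise ValueError(f"duplicate response for (item, rater) = {key!r}")
        seen.add(key)
    if len(answers) > rule.n_models:
        raise ValueError(
            f"item {item!r} has {len(answers)} responses but the rule's panel "
            f"size is {rule.n_models}"
        )


def tally_answers(answers: Sequence[RaterAnswer], rule: ConsensusRule) -> Tally:
    """Count identical VALID answers for a single item.

    Raises ``ValueError`` on a duplicate (item, rater) pair, mixed task kinds
    or more responses than the rule's panel size.
    """
    answers = list(answers)
    _check_group(answers, rule)
    counts: Counter = Counter()
    n_format = n_none = 0
    for a in answers:
        if a.status is Status.VALID:
            counts[a.value] += 1
        elif a.status is Status.FORMAT_ISSUE:
            n_format += 1
        else:
            n_none += 1
    return Tally(
        counts=dict(counts),
        n_valid=sum(counts.values()),
        n_format_issue=n_format,
        n_no_response=n_none,
    )


def decide_item(
    answers: Sequence[RaterAnswer], rule: ConsensusRule
) -> ConsensusDecision:
    """Apply the agreement rule to one item's responses.

    DECIDED with value ``v`` iff ``v`` is the *only* answer whose count
    reaches ``rule.threshold``; WITHHELD otherwise — no answer reaches the
    threshold, two or more answers reach it (possible for extraction tasks or
    sub-majority thresholds), or too few valid responses exist.  The outcome
    is invariant under permutation of the input list.
    """
    answers = list(answers)
    item_id = answers[0].item_id if answers else ""
    t = tally_answers(answers, rule)
    at_threshold = [v for v, c in t.counts.items() if c >= rule.threshold]
    if len(at_threshold) == 1:
        value = at_threshold[0]
        return ConsensusDecision(
            item_id=item_id,
            status=DecisionStatus.DECIDED,
            value=value,
            support=t.counts[value],
            tally=t.counts,
            n_valid=t.n_valid,
            n_format_issue=t.n_format_issue,
        )
    return ConsensusDecision(
        item_id=item_id,
        status=DecisionStatus.WITHHELD,
        tally=t.counts,
        n_valid=t.n_valid,
        n_format_issue=t.n_format_issue,
    )


def decide_batch(
    responses: Union[pd.DataFrame, Iterable[RaterAnswer]],
    rule: ConsensusRule,
    items: Optional[Sequence[str]] = None,
) -> list[ConsensusDecision]:
    """Apply the rule to every item of a response table.

    ``responses`` may be a response DataFrame (see :func:`read_responses`) or
    an iterable of :class:`RaterAnswer`.  Items are decided in stable
    first-appearance order; ``items`` may supply an explicit item list, in
    which case items with zero responses yield WITHHELD decisions with
    ``n_valid = 0``.
    """
    if isinstance(responses, pd.DataFrame):
        answers = answers_from_frame(responses)
    else:
        answers = list(responses)
    by_item: dict[str, list[RaterAnswer]] = {}
    order: list[str] = []
    for a in answers:
        if a.item_id not in by_item:
            by_item[a.item_id] = []
            order.append(a.item_id)
        by_item[a.item_id].append(a)
    if items is not None:
        order = list(items)
    decisions = []
    for item in order:
        group = by_item.get(item, [])
        if group:
            decisions.append(decide_item(group, rule))
        else:
            decisions.append(
                ConsensusDecision(item_id=item, status=DecisionStatus.WITHHELD)
            )
    return decisions


# ---------------------------------------------------------------------------
# Tabular interchange.  Response tables are CSV / JSON-lines with columns
# item_id, rater_id, task, status, value, rationale; extraction values are
# serialized as integers or the literal string "missing".
# ---------------------------------------------------------------------------


def parse_value(raw: Any, task: Union[TaskKind, str]) -> AnswerValue:
    """Parse one serialized answer value into its in-memory form."""
    task = _as_task(task)
    if task is TaskKind.EXTRACTION:
        if isinstance(raw, str):
            raw = raw.strip()
            if raw.lower() == MISSING:
                return MISSING
            return _validate_value(task, int(raw))
        if isinstance(raw, float):
            if not float(raw).is_integer():
                raise ValueError(f"non-integer extraction value {raw!r}")
            return _validate_value(task, int(raw))
        return _validate_value(task, raw)
    return _validate_value(task, str(raw).strip())


def format_value(value: Optional[AnswerValue]) -> str:
    return "" if value is None else str(value)


def answers_from_frame(frame: pd.DataFrame) -> list[RaterAnswer]:
    """Convert a response table into :class:`RaterAnswer` records."""
    required = {"item_id", "rater_id", "task", "status"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"response table lacks columns {sorted(missing_cols)}")
    out = []
    has_rationale = "rationale" in frame.columns
    for row in frame.itertuples(index=False):
        status = Status(row.status)
        task = _as_task(row.task)
        value = None
        if status is Status.VALID:
            value = parse_value(row.value, task)
        rationale = getattr(row, "rationale", None) if has_rationale else None
        if rationale is not None and (pd.isna(rationale) or rationale == ""):
            rationale = None
        out.append(
            RaterAnswer(
                item_id=str(row.item_id),
                rater_id=str(row.rater_id),
                task=task,
                status=status,
                value=value,
                rationale=rationale,
            )
        )
    return out


def answers_to_frame(answers: Iterable[RaterAnswer]) -> pd.DataFrame:
    rows = [
        {
            "item_id": a.item_id,
            "rater_id": a.rater_id,
            "task": a.task.value,
            "status": a.status.value,
            "value": format_value(a.value),
            "rationale": a.rationale or "",
        }
        for a in answers
    ]
    return pd.DataFrame(
        rows, columns=["item_id", "rater_id", "task", "status", "value", "rationale"]
    )


def read_responses(path) -> pd.DataFrame:
    """Read a response table from CSV or JSON-lines (by extension)."""
    path = str(path)
    if path.endswith((".jsonl", ".ndjson")):
        frame = pd.read_json(path, lines=True, dtype={"value": str})
    else:
        frame = pd.read_csv(path, dtype={"value": str}, keep_default_na=False)
    return frame


def decisions_to_frame(decisions: Iterable[ConsensusDecision]) -> pd.DataFrame:
    rows = [
        {
            "item_id": d.item_id,
            "status": d.status.value,
            "value": format_value(d.value),
            "support": d.support,
            "n_valid": d.n_valid,
            "n_format_issue": d.n_format_issue,
        }
        for d in decisions
    ]
    return pd.DataFrame(
        rows,
        columns=["item_id", "status", "value", "support", "n_valid", "n_format_issue"],
    )


def write_decisions(decisions: Iterable[ConsensusDecision], path) -> None:
    frame = decisions_to_frame(decisions)
    path = str(path)
    if path.endswith((".jsonl", ".ndjson")):
        frame.to_json(path, orient="records", lines=True)
    else:
        frame.to_csv(path, index=False)
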