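"""Gold-standard construction and the platinum revision workflow.

The *gold standard* is the conventional human reference: two independent
reviewers answer every item and a third reviewer adjudicates disagreements.
The *platinum standard* re-examines the gold standard wherever a strong
multi-rater consensus contradicts it: an item is flagged when at least
``flag_threshold`` raters of the full pool give the identical answer that
differs from gold (default 4 of 8); a fourth reviewer then accepts or rejects
each flagged revision, and the accepted consensus values replace the gold
values.  The accounting identity

    gold-vs-platinum accuracy = 1 - n_accepted / n_items

holds exactly on counts, and per-class flows conserve class totals:
final(c) = initial(c) - outflow(c) + inflow(c).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import pandas as pd

from .core import (
    ConsensusRule,
    RaterAnswer,
    TaskKind,
    answers_from_frame,
    format_value,
    parse_value,
    tally_answers,
)
from .metrics import TruthRecord, round_pct, truth_from_frame

__all__ = [
    "ReviewRecord",
    "FlagOutcome",
    "RevisionFlag",
    "PlatinumLedger",
    "build_gold",
    "flag_for_revision",
    "resolve_flags_by_truth",
    "apply_revisions",
    "reviews_from_frame",
    "reviews_to_frame",
    "ledger_to_frame",
    "ledger_from_frame",
    "DEFAULT_FLAG_THRESHOLD",
]

#: Raters contradicting gold needed to flag an item for re-review.
DEFAULT_FLAG_THRESHOLD = 4


@dataclass(frozen=True)
class ReviewRecord:
    """Dual review plus adjudication for one item.

    ``adjudicated_value`` is present exactly when the reviewers disagree;
    the derived gold value is the shared answer or the adjudicator's.
    """

    item_id: str
    task: TaskKind
    reviewer1_value: Union[str, int]
    reviewer2_value: Union[str, int]
    adjudicated_value: Optional[Union[str, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", TaskKind(self.task))
        disagree = self.reviewer1_value != self.reviewer2_value
        if disagree and self.adjudicated_value is None:
            raise ValueError(
                f"item {self.item_id!r}: reviewers disagree but no adjudication"
            )
        if not disagree and self.adjudicated_value is not None:
            raise ValueError(
                f"item {self.item_id!r}: adjudication present without disagreement"
            )

    @property
    def disagreement(self) -> bool:
        return self.reviewer1_value != self.reviewer2_value

    @property
    def gold_value(self) -> Union[str, int]:
        return (
            self.adjudicated_value if self.disagreement else self.reviewer1_value
        )


class FlagOutcome(str, enum.Enum):
    PENDING = "pending"
    ACCEPTED = "accepted"
    REJECTED = "rejected"


@dataclass(frozen=True)
class RevisionFlag:
    """One item where a strong consensus contradicted the gold standard."""

    item_id: str
    gold_value: Union[str, int]
    consensus_value: Union[str, int]
    support: int
    flag_threshold: int
    outcome: FlagOutcome = FlagOutcome.PENDING

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome", FlagOutcome(self.outcome))
        if self.consensus_value == self.gold_value:
            raise ValueError(
                f"item {self.item_id!r}: flagged value equals gold — not a revision"
            )
        if self.support < self.flag_threshold:
            raise ValueError(
                f"item {self.item_id!r}: support {self.support} below the "
                f"flag threshold {self.flag_threshold}"
            )

    @property
    def final_value(self) -> Union[str, int]:
        if self.outcome is FlagOutcome.PENDING:
            raise ValueError(f"item {self.item_id!r}: revision still pending")
        return (
            self.consensus_value
            if self.outcome is FlagOutcome.ACCEPTED
            else self.gold_value
        )


@dataclass
class PlatinumLedger:
    """The revision bookkeeping: flags plus accept/reject tallies."""

    flags: list
    flag_threshold: int = DEFAULT_FLAG_THRESHOLD

    @property
    def n_flagged(self) -> int:
        return len(self.flags)

    @property
    def n_accepted(self) -> int:
        return sum(1 for f in self.flags if f.outcome is FlagOutcome.ACCEPTED)

    @property
    def n_rejected(self) -> int:
        return sum(1 for f in self.flags if f.outcome is FlagOutcome.REJECTED)

    @property
    def n_pending(self) -> int:
        return sum(1 for f in self.flags if f.outcome is FlagOutcome.PENDING)

    def class_flow(self) -> dict:
        """(from_class, to_class) -> count over ACCEPTED flags."""
        flow: Counter = Counter()
        for f in self.flags:
            if f.outcome is FlagOutcome.ACCEPTED:
                flow[(f.gold_value, f.consensus_value)] += 1
        return dict(flow)


def build_gold(reviews: Sequence[ReviewRecord]) -> tuple[list[TruthRecord], int]:
    """Derive the gold truth table from dual reviews; also return the
    disagreement count (flags concentrate on adjudicated items)."""
    seen = set()
    truth = []
    n_disagree = 0
    for r in reviews:
        key = (r.item_id, r.task)
        if key in seen:
            raise ValueError(f"duplicate review for {key!r}")
        seen.add(key)
        if r.disagreement:
            n_disagree += 1
        truth.append(
            TruthRecord(item_id=r.item_id, task=r.task, true_value=r.gold_value)
        )
    return truth, n_disagree


def flag_for_revision(
    panel_responses: Union[pd.DataFrame, Sequence[RaterAnswer]],
    gold: Union[Sequence[TruthRecord], pd.DataFrame],
    flag_threshold: int = DEFAULT_FLAG_THRESHOLD,
    n_models: Optional[int] = None,
) -> list[RevisionFlag]:
    """Flag items where >= ``flag_threshold`` raters of the full pool agree
    on an answer different from gold.

    Flagging always uses the raw responses of the *full* rater pool — never a
    sweep subset — so there is a single flagged set per study.  If several
    non-gold values reach the threshold (possible for extraction), the one
    with the highest count is flagged, ties broken by value order.
    """
    if flag_threshold < 1:
        raise ValueError("flag_threshold must be >= 1")
    if isinstance(panel_responses, pd.DataFrame):
        answers = answers_from_frame(panel_responses)
    else:
        answers = list(panel_responses)
    if isinstance(gold, pd.DataFrame):
        gold = truth_from_frame(gold)
    gmap = {t.item_id: t.true_value for t in gold}

    by_item: dict[str, list[RaterAnswer]] = {}
    order: list[str] = []
    for a in answers:
        if a.item_id not in by_item:
            by_item[a.item_id] = []
            order.append(a.item_id)
        by_item[a.item_id].append(a)

    pool_size = n_models or max((len(g) for g in by_item.values()), default=1)
    rule = ConsensusRule(n_models=pool_size, threshold=min(flag_threshold, pool_size))

    flags = []
    for item in order:
        if item not in gmap:
            raise ValueError(f"item {item!r} absent from the gold table")
        tally = tally_answers(by_item[item], rule)
        contenders = [
            (c, v)
            for v, c in tally.counts.items()
            if v != gmap[item] and c >= flag_threshold
        ]
        if not contenders:
            continue
        count, value = max(contenders, key=lambda cv: (cv[0], str(cv[1])))
        flags.append(
            RevisionFlag(
                item_id=item,
                gold_value=gmap[item],
                consensus_value=value,
                support=count,
                flag_threshold=flag_threshold,
            )
        )
    return flags


def resolve_flags_by_truth(
    flags: Sequence[RevisionFlag],
    truth: Union[Sequence[TruthRecord], pd.DataFrame],
) -> list[RevisionFlag]:
    """Simulation hook: resolve each flag by comparing the consensus value
    with the (known, simulated) truth — ACCEPTED when the consensus is right.
    Stands in for the fourth human reviewer in end-to-end tests."""
    if isinstance(truth, pd.DataFrame):
        truth = truth_from_frame(truth)
    tmap = {t.item_id: t.true_value for t in truth}
    out = []
    for f in flags:
        correct = f.consensus_value == tmap[f.item_id]
        out.append(
            replace(f, outcome=FlagOutcome.ACCEPTED if correct
                    else FlagOutcome.REJECTED)
        )
    return out


def apply_revisions(
    ledger: PlatinumLedger,
    gold: Union[Sequence[TruthRecord], pd.DataFrame],
) -> tuple[list[TruthRecord], dict]:
    """Substitute accepted revisions into gold, producing the platinum truth
    table and a full accounting report.

    All flags must be resolved.  The report carries the flag counts, the
    acceptance rate, per-class flows with initial/final class counts, and
    the gold-vs-platinum accuracy 1 - n_accepted / n_items.
    """
    if isinstance(gold, pd.DataFrame):
        gold = truth_from_frame(gold)
    pending = [f.item_id for f in ledger.flags if f.outcome is FlagOutcome.PENDING]
    if pending:
        raise ValueError(f"unresolved revision flags for items {pending}")
    revised = {
        f.item_id: f.consensus_value
        for f in ledger.flags
        if f.outcome is FlagOutcome.ACCEPTED
    }
    platinum = [
        replace(t, true_value=revised[t.item_id]) if t.item_id in revised else t
        for t in gold
    ]

    n_items = len(gold)
    initial = Counter(t.true_value for t in gold)
    final = Counter(t.true_value for t in platinum)
    flow = ledger.class_flow()
    gold_accuracy = 1.0 - ledger.n_accepted / n_items if n_items else 1.0
    report = {
        "n_items": n_items,
        "n_flagged": ledger.n_flagged,
        "n_accepted": ledger.n_accepted,
        "n_rejected": ledger.n_rejected,
        "acceptance_rate": (
            ledger.n_accepted / ledger.n_flagged if ledger.n_flagged else None
        ),
        "acceptance_rate_pct": round_pct(
            ledger.n_accepted / ledger.n_flagged if ledger.n_flagged else None
        ),
        "gold_accuracy": gold_accuracy,
        "gold_accuracy_pct": round_pct(gold_accuracy),
        "initial_class_counts": {str(k): v for k, v in sorted(
            initial.items(), key=lambda kv: str(kv[0]))},
        "final_class_counts": {str(k): v for k, v in sorted(
            final.items(), key=lambda kv: str(kv[0]))},
        "class_flow": {
            f"{frm}->{to}": n for (frm, to), n in sorted(
                flow.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
        },
    }
    return platinum, report


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------


def reviews_from_frame(frame: pd.DataFrame) -> list[ReviewRecord]:
    """Reviews CSV: item_id, task, reviewer1, reviewer2, adjudicated
    (blank when the reviewers agree)."""
    required = {"item_id", "task", "reviewer1", "reviewer2"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ValueError(f"review table lacks columns {sorted(missing_cols)}")
    out = []
    for row in frame.itertuples(index=False):
        task = TaskKind(row.task)
        adj = getattr(row, "adjudicated", "")
        if pd.isna(adj) or adj == "":
            adj_value = None
        else:
            adj_value = parse_value(adj, task)
        out.append(
            ReviewRecord(
                item_id=str(row.item_id),
                task=task,
                reviewer1_value=parse_value(row.reviewer1, task),
                reviewer2_value=parse_value(row.reviewer2, task),
                adjudicated_value=adj_value,
            )
        )
    return out


def reviews_to_frame(reviews: Sequence[ReviewRecord]) -> pd.DataFrame:
    rows = [
        {
            "item_id": r.item_id,
            "task": r.task.value,
            "reviewer1": format_value(r.reviewer1_value),
            "reviewer2": format_value(r.reviewer2_value),
            "adjudicated": format_value(r.adjudicated_value),
        }
        for r in reviews
    ]
    return pd.DataFrame(
        rows, columns=["item_id", "task", "reviewer1", "reviewer2", "adjudicated"]
    )


def ledger_to_frame(ledger: PlatinumLedger, task: TaskKind) -> pd.DataFrame:
    rows = [
        {
            "item_id": f.item_id,
            "task": task.value,
            "gold_value": format_value(f.gold_value),
            "consensus_value": format_value(f.consensus_value),
            "support": f.support,
            "flag_threshold": f.flag_threshold,
            "outcome": f.outcome.value,
        }
        for f in ledger.flags
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "item_id", "task", "gold_value", "consensus_value",
            "support", "flag_threshold", "outcome",
        ],
    )


def ledger_from_frame(frame: pd.DataFrame) -> PlatinumLedger:
    flags = []
    threshold = DEFAULT_FLAG_THRESHOLD
    for row in frame.itertuples(index=False):
        task = TaskKind(row.task)
        threshold = int(row.flag_threshold)
        flags.append(
            RevisionFlag(
                item_id=str(row.item_id),
                gold_value=parse_value(row.gold_value, task),
                consensus_value=parse_value(row.consensus_value, task),
                support=int(row.support),
                flag_threshold=threshold,
                outcome=FlagOutcome(str(row.outcome).strip().lower()),
            )
        )
    return PlatinumLedger(flags=flags, flag_threshold=threshold)
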