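"""Synthetic rater panels with known truth.

Generates items, reference truth, dual human reviews and multi-rater
responses with the statistical structure that drives the framework's
behaviour on real abstract panels:

* **accuracy heterogeneity** — each rater has an ability on the logit scale,
  calibrated so marginal accuracies span a stated range (default 0.80–0.95);
* **item difficulty** — a shared per-item difficulty d_i (Rasch-style):
  rater r answers item i correctly with probability
  ``sigmoid(ability_r - d_i)``, so hard items produce *correlated* failures
  across raters and reviewers alike;
* **diverse wrong answers** — extraction errors draw from a mixture of
  realistic modes (reporting a single arm's size, an arithmetic slip, a
  corrupted digit, a spurious "missing"), so two independent wrong raters
  rarely coincide; categorical errors flip to the other label;
* **format failures** — each rater occasionally produces unparseable output
  (status FORMAT_ISSUE), one rater markedly more often than the rest;
* **calculation burden** — items whose total must be summed from per-arm
  counts apply an ability penalty, small for the machine raters and large
  for the simulated humans.

Everything is reproducible from the mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    DEFAULT_LABELS,
    DRUG,
    MISSING,
    NONDRUG,
    RaterAnswer,
    Status,
    TaskKind,
    answers_to_frame,
)
from .standards import ReviewRecord, reviews_to_frame

__all__ = [
    "ONE_ARM",
    "ARITHMETIC_SLIP",
    "DIGIT_CORRUPT",
    "SPURIOUS_MISSING",
    "ERROR_MODES",
    "DEFAULT_ERROR_WEIGHTS",
    "CALC_ERROR_WEIGHTS",
    "DEFAULT_TARGET_ACCURACIES",
    "RaterProfile",
    "SimConfig",
    "SimDataset",
    "sigmoid",
    "calibrate_ability",
    "calibrate_adjudicator_ability",
    "default_raters",
    "default_config",
    "simulate_panel",
    "simulate_human_review",
    "simulate_study",
    "analytic_consensus_probability",
    "simulate_iid_consensus",
]

# Extraction wrong-answer modes
ONE_ARM = "one_arm"
ARITHMETIC_SLIP = "arithmetic_slip"
DIGIT_CORRUPT = "digit_corrupt"
SPURIOUS_MISSING = "spurious_missing"
ERROR_MODES = (ONE_ARM, ARITHMETIC_SLIP, DIGIT_CORRUPT, SPURIOUS_MISSING)

#: Error-mode mixture when the total is reported directly.
DEFAULT_ERROR_WEIGHTS = {
    ONE_ARM: 0.30,
    ARITHMETIC_SLIP: 0.30,
    DIGIT_CORRUPT: 0.30,
    SPURIOUS_MISSING: 0.10,
}
#: Mixture for requires-calculation items: the signature error there is
#: reporting one arm instead of the summed total.
CALC_ERROR_WEIGHTS = {
    ONE_ARM: 0.60,
    ARITHMETIC_SLIP: 0.15,
    DIGIT_CORRUPT: 0.15,
    SPURIOUS_MISSING: 0.10,
}

#: Marginal accuracies of the default 8-rater panel (the 0.80-0.95 band a
#: panel of small open models spans in practice).
DEFAULT_TARGET_ACCURACIES = (0.95, 0.94, 0.93, 0.92, 0.90, 0.88, 0.85, 0.80)
#: Per-item unparseable-output rates; one rater is markedly worse.
DEFAULT_FORMAT_RATES = (0.005, 0.005, 0.005, 0.005, 0.005, 0.05, 0.005, 0.005)

_RATER_CALC_PENALTY = 0.4   # logits; yields a few-points accuracy drop
_HUMAN_CALC_PENALTY = 2.0   # logits; humans lose ~20 points on such items


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _validate_weights(w: dict) -> dict:
    w = {m: float(w.get(m, 0.0)) for m in ERROR_MODES}
    if any(v < 0 for v in w.values()):
        raise ValueError(f"error-mode weights must be non-negative: {w}")
    total = sum(w.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"error-mode weights must sum to 1, got {total}")
    return w


@dataclass(frozen=True)
class RaterProfile:
    """One simulated rater: ability, error style and failure rates."""

    rater_id: str
    ability: float
    format_issue_rate: float = 0.0
    calc_penalty: float = 0.0
    error_weights: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_WEIGHTS))
    calc_error_weights: dict = field(default_factory=lambda: dict(CALC_ERROR_WEIGHTS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.format_issue_rate <= 1.0:
            raise ValueError("format_issue_rate must lie in [0, 1]")
        object.__setattr__(self, "error_weights",
                           _validate_weights(self.error_weights))
        object.__setattr__(self, "calc_error_weights",
                           _validate_weights(self.calc_error_weights))


@dataclass(frozen=True)
class SimConfig:
    """Generative specification of one synthetic study.

    Defaults mirror the study conditions the framework targets: 1020
    randomized-trial abstracts, a 44% drug-label prevalence, 22/1020 items
    with no reported sample size, and an 8-rater panel spanning marginal
    accuracies 0.80-0.95.
    """

    task: TaskKind
    seed: int
    n_items: int = 1020
    label_prevalence: float = 0.44           # P(label == drug)
    p_missing_truth: float = 22 / 1020       # P(no sample size reported)
    p_requires_calculation: float = 0.30     # P(total must be summed)
    difficulty_mean: float = 0.0
    difficulty_sd: float = 1.0
    arm_low: int = 20                        # per-arm size range (uniform)
    arm_high: int = 300
    raters: tuple = ()
    reviewer_abilities: tuple = ()           # two human reviewers
    adjudicator_ability: float = 0.0
    human_calc_penalty: float = _HUMAN_CALC_PENALTY

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", TaskKind(self.task))
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        for name in ("label_prevalence", "p_missing_truth",
                     "p_requires_calculation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.difficulty_sd < 0:
            raise ValueError("difficulty_sd must be >= 0")
        if not self.arm_low <= self.arm_high or self.arm_low < 1:
            raise ValueError("need 1 <= arm_low <= arm_high")
        object.__setattr__(self, "raters", tuple(self.raters))
        object.__setattr__(self, "reviewer_abilities",
                           tuple(float(a) for a in self.reviewer_abilities))


@dataclass
class SimDataset:
    """Output of one simulation: the standard truth/response/review tables
    plus the latent per-item state."""

    truth: pd.DataFrame
    responses: pd.DataFrame
    reviews: Optional[pd.DataFrame]
    difficulty: np.ndarray
    requires_calculation: np.ndarray


# ---------------------------------------------------------------------------
# Ability calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(101)


def _expected_accuracy(ability: float, mean: float, sd: float) -> float:
    """E_d[sigmoid(ability - d)] for d ~ Normal(mean, sd), Gauss-Hermite."""
    if sd == 0.0:
        return float(sigmoid(ability - mean))
    d = mean + sd * _GH_NODES
    w = _GH_WEIGHTS / math.sqrt(2 * math.pi)
    return float(np.sum(w * sigmoid(ability - d)))


def calibrate_ability(
    target_accuracy: float, difficulty_mean: float = 0.0,
    difficulty_sd: float = 0.0,
) -> float:
    """Ability a with E_d[sigmoid(a - d)] = target, solved to < 1e-6.

    With a point-mass difficulty this is the logit identity
    a = mean + log(t / (1 - t)).
    """
    if not 0.0 < target_accuracy < 1.0:
        raise ValueError(f"target accuracy must lie in (0, 1), got {target_accuracy}")
    logit = math.log(target_accuracy / (1.0 - target_accuracy))
    if difficulty_sd == 0.0:
        return difficulty_mean + logit
    lo = difficulty_mean + logit - 10 * difficulty_sd - 10
    hi = difficulty_mean + logit + 10 * difficulty_sd + 10
    return float(brentq(
        lambda a: _expected_accuracy(a, difficulty_mean, difficulty_sd)
        - target_accuracy,
        lo, hi, xtol=1e-9,
    ))


def calibrate_adjudicator_ability(
    target_gold_accuracy: float,
    reviewer_ability: float,
    difficulty_mean: float = 0.0,
    difficulty_sd: float = 0.0,
) -> float:
    """Adjudicator ability giving the requested dual-review-plus-adjudication
    accuracy under the binary-label law.

    Gold is correct when both reviewers are correct, or when they disagree
    and the adjudicator is correct:
    ``E_d[p^2 + 2 p (1 - p) sigmoid(a_adj - d)]`` with
    ``p = sigmoid(a_rev - d)``.  Raises if the target exceeds the ceiling
    ``E_d[1 - (1 - p)^2]`` reached by a perfect adjudicator.
    """
    if difficulty_sd == 0.0:
        d_nodes = np.array([difficulty_mean])
        w = np.array([1.0])
    else:
        d_nodes = difficulty_mean + difficulty_sd * _GH_NODES
        w = _GH_WEIGHTS / math.sqrt(2 * math.pi)
    p = sigmoid(reviewer_ability - d_nodes)

    def gold_acc(a_adj: float) -> float:
        return float(np.sum(w * (p * p + 2 * p * (1 - p)
                                 * sigmoid(a_adj - d_nodes))))

    ceiling = float(np.sum(w * (1.0 - (1.0 - p) ** 2)))
    floor = float(np.sum(w * p * p))
    if not floor < target_gold_accuracy < ceiling:
        raise ValueError(
            f"gold accuracy {target_gold_accuracy} unattainable: range "
            f"({floor:.4f}, {ceiling:.4f}) for reviewer ability "
            f"{reviewer_ability:.3f}"
        )
    return float(brentq(lambda a: gold_acc(a) - target_gold_accuracy,
                        -60.0, 60.0, xtol=1e-9))


def default_raters(
    difficulty_mean: float = 0.0,
    difficulty_sd: float = 1.0,
    target_accuracies: Sequence[float] = DEFAULT_TARGET_ACCURACIES,
    format_rates: Sequence[float] = DEFAULT_FORMAT_RATES,
) -> tuple:
    """The default 8-rater panel, abilities calibrated against the stated
    difficulty distribution so marginal accuracies hit their targets."""
    profiles = []
    for i, (acc, fr) in enumerate(zip(target_accuracies, format_rates), start=1):
        profiles.append(RaterProfile(
            rater_id=f"llm{i}",
            ability=calibrate_ability(acc, difficulty_mean, difficulty_sd),
            format_issue_rate=fr,
            calc_penalty=_RATER_CALC_PENALTY,
        ))
    return tuple(profiles)


def default_config(task: Union[TaskKind, str], seed: int,
                   n_items: int = 1020, **overrides) -> SimConfig:
    """The study-condition defaults for one task, humans included.

    Single-reviewer accuracy targets 0.90 (classification) / 0.94
    (extraction); the adjudicator is calibrated so the gold standard lands
    near 0.96 / 0.98.
    """
    task = TaskKind(task)
    mean = float(overrides.pop("difficulty_mean", 0.0))
    sd = float(overrides.pop("difficulty_sd", 1.0))
    raters = overrides.pop("raters", None) or default_raters(mean, sd)
    reviewer_target = 0.90 if task is TaskKind.CATEGORICAL else 0.94
    gold_target = 0.96 if task is TaskKind.CATEGORICAL else 0.98
    rev_ability = calibrate_ability(reviewer_target, mean, sd)
    adj_ability = calibrate_adjudicator_ability(gold_target, rev_ability, mean, sd)
    return SimConfig(
        task=task,
        seed=seed,
        n_items=n_items,
        difficulty_mean=mean,
        difficulty_sd=sd,
        raters=raters,
        reviewer_abilities=(rev_ability, rev_ability),
        adjudicator_ability=adj_ability,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _streams(seed: int) -> tuple:
    truth_ss, panel_ss, review_ss = np.random.SeedSequence(seed).spawn(3)
    return (np.random.default_rng(truth_ss), np.random.default_rng(panel_ss),
            np.random.default_rng(review_ss))


def _item_ids(n: int) -> list:
    width = len(str(n))
    return [f"item{str(i + 1).zfill(width)}" for i in range(n)]


@dataclass
class _Latent:
    """Per-item latent state shared by raters and reviewers."""

    items: list
    difficulty: np.ndarray
    requires_calculation: np.ndarray
    truth_values: list
    arms: Optional[np.ndarray]  # (n, 2) per-arm sizes; extraction only


def _draw_latent(cfg: SimConfig, rng: np.random.Generator) -> _Latent:
    n = cfg.n_items
    items = _item_ids(n)
    difficulty = rng.normal(cfg.difficulty_mean, cfg.difficulty_sd, size=n)
    if cfg.task is TaskKind.CATEGORICAL:
        labels = np.where(rng.random(n) < cfg.label_prevalence, DRUG, NONDRUG)
        return _Latent(items, difficulty, np.zeros(n, dtype=bool),
                       list(labels), None)
    arms = rng.integers(cfg.arm_low, cfg.arm_high + 1, size=(n, 2))
    req = rng.random(n) < cfg.p_requires_calculation
    miss = rng.random(n) < cfg.p_missing_truth
    truth = [MISSING if miss[i] else int(arms[i].sum()) for i in range(n)]
    return _Latent(items, difficulty, req, truth, arms)


def _corrupt_digit(value: int, rng: np.random.Generator) -> int:
    s = str(value)
    pos = int(rng.integers(len(s)))
    old = int(s[pos])
    new = int(rng.integers(9))
    if new >= old:
        new += 1
    return int(s[:pos] + str(new) + s[pos + 1:])


def _wrong_extraction_value(
    cfg: SimConfig, latent: _Latent, i: int, weights: dict,
    rng: np.random.Generator,
):
    truth = latent.truth_values[i]
    if truth == MISSING:
        # Nothing to extract: a wrong answer is a hallucinated total.
        return int(rng.integers(cfg.arm_low, cfg.arm_high + 1, size=2).sum())
    mode = rng.choice(ERROR_MODES, p=[weights[m] for m in ERROR_MODES])
    if mode == ONE_ARM:
        return int(latent.arms[i, int(rng.integers(2))])
    if mode == ARITHMETIC_SLIP:
        delta = int(rng.integers(1, 11)) * (1 if rng.random() < 0.5 else -1)
        return max(0, int(truth) + delta)
    if mode == DIGIT_CORRUPT:
        return _corrupt_digit(int(truth), rng)
    return MISSING  # SPURIOUS_MISSING


def _draw_rater_answers(
    cfg: SimConfig, latent: _Latent, profile: RaterProfile,
    rng: np.random.Generator, with_format_issues: bool,
) -> list[RaterAnswer]:
    n = cfg.n_items
    penalty = profile.calc_penalty * latent.requires_calculation
    p_correct = sigmoid(profile.ability - latent.difficulty - penalty)
    correct = rng.random(n) < p_correct
    fmt = (rng.random(n) < profile.format_issue_rate) if with_format_issues \
        else np.zeros(n, dtype=bool)
    answers = []
    for i, item in enumerate(latent.items):
        if fmt[i]:
            answers.append(RaterAnswer(item, profile.rater_id, cfg.task,
                                       Status.FORMAT_ISSUE))
            continue
        truth = latent.truth_values[i]
        if correct[i]:
            value = truth
        elif cfg.task is TaskKind.CATEGORICAL:
            value = NONDRUG if truth == DRUG else DRUG
        else:
            weights = (profile.calc_error_weights
                       if latent.requires_calculation[i]
                       else profile.error_weights)
            value = _wrong_extraction_value(cfg, latent, i, weights, rng)
        answers.append(RaterAnswer(item, profile.rater_id, cfg.task,
                                   Status.VALID, value))
    return answers


def _truth_frame(latent: _Latent, task: TaskKind) -> pd.DataFrame:
    return pd.DataFrame({
        "item_id": latent.items,
        "task": task.value,
        "true_value": [str(v) for v in latent.truth_values],
        "requires_calculation": latent.requires_calculation,
        "sample_size_missing": [v == MISSING for v in latent.truth_values],
    })


def simulate_panel(config: SimConfig) -> SimDataset:
    """Generate truth and the full rater-panel response table.

    Fully reproducible from ``config.seed``; the response table holds exactly
    ``n_items * n_raters`` rows.  Reviews are not generated here — see
    :func:`simulate_human_review` / :func:`simulate_study`.
    """
    if not config.raters:
        raise ValueError("config.raters is empty")
    truth_rng, panel_rng, _ = _streams(config.seed)
    latent = _draw_latent(config, truth_rng)
    all_answers: list[RaterAnswer] = []
    for profile in config.raters:
        all_answers.extend(_draw_rater_answers(
            config, latent, profile, panel_rng, with_format_issues=True))
    return SimDataset(
        truth=_truth_frame(latent, config.task),
        responses=answers_to_frame(all_answers),
        reviews=None,
        difficulty=latent.difficulty,
        requires_calculation=latent.requires_calculation,
    )


def _human_profile(rater_id: str, ability: float, cfg: SimConfig) -> RaterProfile:
    return RaterProfile(rater_id=rater_id, ability=ability,
                        format_issue_rate=0.0,
                        calc_penalty=cfg.human_calc_penalty)


def simulate_human_review(
    config: SimConfig, latent: Optional[_Latent] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[ReviewRecord]:
    """Dual review plus adjudication under the same difficulty-ability law.

    Reviewers share the items' difficulty with the machine raters, so
    review disagreements concentrate on the same hard items that defeat the
    panel — the mechanism behind revision flags landing on adjudicated
    items.  Adjudication is generated exactly on disagreement rows.
    """
    if len(config.reviewer_abilities) != 2:
        raise ValueError("config.reviewer_abilities must hold two abilities")
    if latent is None:
        truth_rng, _, review_rng = _streams(config.seed)
        latent = _draw_latent(config, truth_rng)
        rng = review_rng
    assert rng is not None
    r1, r2 = (
        _draw_rater_answers(
            config, latent,
            _human_profile(f"reviewer{k + 1}", a, config),
            rng, with_format_issues=False)
        for k, a in enumerate(config.reviewer_abilities)
    )
    adjudicator = _human_profile("adjudicator", config.adjudicator_ability, config)
    adj = _draw_rater_answers(config, latent, adjudicator, rng,
                              with_format_issues=False)
    reviews = []
    for i, item in enumerate(latent.items):
        v1, v2 = r1[i].value, r2[i].value
        reviews.append(ReviewRecord(
            item_id=item,
            task=config.task,
            reviewer1_value=v1,
            reviewer2_value=v2,
            adjudicated_value=adj[i].value if v1 != v2 else None,
        ))
    return reviews


def simulate_study(config: SimConfig) -> SimDataset:
    """Truth + panel responses + human reviews, one seed, one pass."""
    truth_rng, panel_rng, review_rng = _streams(config.seed)
    latent = _draw_latent(config, truth_rng)
    all_answers: list[RaterAnswer] = []
    for profile in config.raters:
        all_answers.extend(_draw_rater_answers(
            config, latent, profile, panel_rng, with_format_issues=True))
    reviews = simulate_human_review(config, latent, review_rng)
    return SimDataset(
        truth=_truth_frame(latent, config.task),
        responses=answers_to_frame(all_answers),
        reviews=reviews_to_frame(reviews),
        difficulty=latent.difficulty,
        requires_calculation=latent.requires_calculation,
    )


# ---------------------------------------------------------------------------
# Analytic oracle for the agreement rule under independence
# ---------------------------------------------------------------------------


def analytic_consensus_probability(
    p_correct: float, n: int, t: int, k_wrong_alternatives: int,
    assume_iid_uniform_errors: bool = True,
) -> tuple[float, float, float]:
    """Exact (p_decided_correct, p_decided_wrong, p_withheld) for n iid
    raters, correct with probability p and otherwise uniform over k wrong
    alternatives.

    A decision is correct iff the correct answer's count reaches ``t`` and is
    the unique value doing so; wrong iff a single wrong value uniquely
    reaches ``t``.  Computed by exact multinomial enumeration; the three
    probabilities sum to 1 within 1e-12.
    """
    if not assume_iid_uniform_errors:
        raise NotImplementedError(
            "only the iid-uniform-errors law is defined for this oracle")
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must lie in [0, 1]")
    if not 1 <= t <= n:
        raise ValueError(f"need 1 <= t <= n, got t={t}, n={n}")
    k = int(k_wrong_alternatives)
    if k < 1:
        raise ValueError("k_wrong_alternatives must be >= 1")
    p_wrong_each = (1.0 - p_correct) / k
    probs = [p_correct] + [p_wrong_each] * k

    p_dec_correct = p_dec_wrong = p_withheld = 0.0
    for counts in _compositions(n, k + 1):
        pr = _multinomial_pmf(counts, probs)
        if pr == 0.0:
            continue
        reached = [j for j, c in enumerate(counts) if c >= t]
        if len(reached) == 1:
            if reached[0] == 0:
                p_dec_correct += pr
            else:
                p_dec_wrong += pr
        else:
            p_withheld += pr
    return p_dec_correct, p_dec_wrong, p_withheld


def _compositions(n: int, parts: int):
    """All tuples of ``parts`` non-negative ints summing to n."""
    if parts == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, parts - 1):
            yield (first,) + rest


def _multinomial_pmf(counts: Sequence[int], probs: Sequence[float]) -> float:
    coef = math.factorial(sum(counts))
    pr = 1.0
    for c, p in zip(counts, probs):
        coef //= math.factorial(c)
        if c:
            if p == 0.0:
                return 0.0
            pr *= p ** c
    return coef * pr


def simulate_iid_consensus(
    p_correct: float, n: int, t: int, k_wrong_alternatives: int,
    n_items: int, seed: int,
) -> tuple[float, float, float]:
    """Monte-Carlo counterpart of :func:`analytic_consensus_probability`."""
    rng = np.random.default_rng(seed)
    k = int(k_wrong_alternatives)
    probs = [p_correct] + [(1.0 - p_correct) / k] * k
    draws = rng.choice(k + 1, size=(n_items, n), p=probs)
    n_correct = n_wrong = 0
    for row in draws:
        counts = np.bincount(row, minlength=k + 1)
        reached = np.flatnonzero(counts >= t)
        if reached.size == 1:
            if reached[0] == 0:
                n_correct += 1
            else:
                n_wrong += 1
    return (n_correct / n_items, n_wrong / n_items,
            (n_items - n_correct - n_wrong) / n_items)
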