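"""The synthetic rater-panel generator and its analytic oracle."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest
from scipy.integrate import quad

from quorum.core import (
    MISSING,
    ConsensusRule,
    Status,
    TaskKind,
    answers_from_frame,
    decide_batch,
)
from quorum.simulate import (
    RaterProfile,
    SimConfig,
    analytic_consensus_probability,
    calibrate_ability,
    calibrate_adjudicator_ability,
    default_config,
    default_raters,
    sigmoid,
    simulate_human_review,
    simulate_iid_consensus,
    simulate_panel,
    simulate_study,
)
from quorum.standards import reviews_from_frame

CAT = TaskKind.CATEGORICAL
EXT = TaskKind.EXTRACTION


def _flat_config(task, seed, n_items, abilities, **kw):
    """Config with point-mass difficulty and plain raters (no format issues,
    no calculation penalty) — the iid regime."""
    raters = tuple(
        RaterProfile(rater_id=f"r{i + 1}", ability=a)
        for i, a in enumerate(abilities)
    )
    kw.setdefault("difficulty_sd", 0.0)
    kw.setdefault("p_missing_truth", 0.0)
    kw.setdefault("p_requires_calculation", 0.0)
    kw.setdefault("reviewer_abilities", (5.0, 5.0))
    kw.setdefault("adjudicator_ability", 5.0)
    return SimConfig(task=task, seed=seed, n_items=n_items, raters=raters,
                     **kw)


class TestDeterminism:
    @pytest.mark.parametrize("task", [CAT, EXT])
    def test_same_seed_same_bytes(self, task):
        cfg = default_config(task, seed=33, n_items=60)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert a.responses.to_csv() == b.responses.to_csv()
        assert a.truth.to_csv() == b.truth.to_csv()
        assert a.reviews.to_csv() == b.reviews.to_csv()

    def test_different_seed_different_data(self):
        a = simulate_study(default_config(CAT, seed=1, n_items=60))
        b = simulate_study(default_config(CAT, seed=2, n_items=60))
        assert a.responses.to_csv() != b.responses.to_csv()

    def test_row_count_is_items_times_raters(self):
        ds = simulate_panel(default_config(CAT, seed=5, n_items=37))
        assert len(ds.responses) == 37 * 8


class TestMarginalAccuracy:
    def test_flat_difficulty_hits_sigmoid_rate(self):
        """With difficulty sd 0 and ability = logit(0.9), each rater's
        marginal accuracy sits within 3 binomial SE of 0.9."""
        n = 10_000
        ability = calibrate_ability(0.9)
        cfg = _flat_config(CAT, seed=11, n_items=n,
                           abilities=[ability, ability])
        ds = simulate_panel(cfg)
        truth = dict(zip(ds.truth["item_id"], ds.truth["true_value"]))
        se3 = 3 * math.sqrt(0.9 * 0.1 / n)
        for rater, grp in ds.responses.groupby("rater_id"):
            acc = (grp["value"].to_numpy()
                   == [truth[i] for i in grp["item_id"]]).mean()
            assert abs(acc - 0.9) < se3

    def test_format_rate_one_withholds_everything(self):
        raters = tuple(RaterProfile(f"r{i}", 2.0, format_issue_rate=1.0)
                       for i in range(4))
        cfg = SimConfig(task=CAT, seed=3, n_items=25, raters=raters,
                        reviewer_abilities=(5.0, 5.0),
                        adjudicator_ability=5.0)
        ds = simulate_panel(cfg)
        assert (ds.responses["status"] == "format_issue").all()
        decisions = decide_batch(ds.responses, ConsensusRule(4, 2))
        assert not any(d.decided for d in decisions)

    def test_wrong_answers_rarely_coincide(self):
        """Two independent raters' extraction errors almost never agree:
        measured coincidence below 0.1 of the joint error rate."""
        n = 20_000
        ability = calibrate_ability(0.7)  # high error rate for counting
        cfg = _flat_config(EXT, seed=21, n_items=n,
                           abilities=[ability, ability])
        ds = simulate_panel(cfg)
        truth = dict(zip(ds.truth["item_id"], ds.truth["true_value"]))
        piv = ds.responses.pivot(index="item_id", columns="rater_id",
                                 values="value")
        t = np.array([truth[i] for i in piv.index])
        v1, v2 = piv["r1"].to_numpy(), piv["r2"].to_numpy()
        both_wrong = (v1 != t) & (v2 != t)
        coincide = both_wrong & (v1 == v2)
        assert both_wrong.sum() > 500
        assert coincide.sum() < 0.1 * both_wrong.sum()

    def test_requires_calculation_items_are_harder(self):
        cfg = default_config(EXT, seed=9, n_items=4000)
        ds = simulate_panel(cfg)
        truth = dict(zip(ds.truth["item_id"], ds.truth["true_value"]))
        req = dict(zip(ds.truth["item_id"], ds.truth["requires_calculation"]))
        resp = ds.responses[ds.responses["status"] == "valid"]
        correct = np.array([v == truth[i] for v, i
                            in zip(resp["value"], resp["item_id"])])
        flag = np.array([req[i] for i in resp["item_id"]])
        assert correct[~flag].mean() > correct[flag].mean()


class TestHumanReview:
    def test_infinite_ability_reviewers_reproduce_truth(self):
        cfg = _flat_config(CAT, seed=4, n_items=200, abilities=[2.0] * 3,
                           reviewer_abilities=(60.0, 60.0),
                           adjudicator_ability=60.0)
        ds = simulate_study(cfg)
        reviews = reviews_from_frame(ds.reviews)
        truth = dict(zip(ds.truth["item_id"], ds.truth["true_value"]))
        for r in reviews:
            assert str(r.gold_value) == truth[r.item_id]
            assert not r.disagreement

    def test_adjudication_exactly_on_disagreement_rows(self, categorical_study):
        reviews = reviews_from_frame(categorical_study.reviews)
        for r in reviews:
            assert (r.adjudicated_value is not None) == r.disagreement

    def test_calibrated_reviewer_and_gold_accuracy(self):
        """Root-finding calibration hits ~0.90 single-reviewer and ~0.96
        adjudicated gold accuracy, verified by Monte Carlo at 10,000 items."""
        n = 10_000
        cfg = default_config(CAT, seed=17, n_items=n)
        ds = simulate_study(cfg)
        reviews = reviews_from_frame(ds.reviews)
        truth = dict(zip(ds.truth["item_id"], ds.truth["true_value"]))
        rev1_acc = np.mean([str(r.reviewer1_value) == truth[r.item_id]
                            for r in reviews])
        gold_acc = np.mean([str(r.gold_value) == truth[r.item_id]
                            for r in reviews])
        assert abs(rev1_acc - 0.90) < 0.015
        assert abs(gold_acc - 0.96) < 0.015


class TestCalibration:
    def test_point_mass_target_half_gives_zero(self):
        assert calibrate_ability(0.5) == pytest.approx(0.0, abs=1e-9)

    def test_point_mass_logit_identity(self):
        assert calibrate_ability(0.9) == pytest.approx(math.log(9), abs=1e-9)

    def test_normal_difficulty_matches_quadrature_oracle(self):
        """E_d[sigmoid(a - d)] under d ~ N(0,1) checked against independent
        adaptive quadrature."""
        a = calibrate_ability(0.9, 0.0, 1.0)
        val, _ = quad(
            lambda d: sigmoid(a - d)
            * math.exp(-d * d / 2) / math.sqrt(2 * math.pi),
            -12, 12)
        assert abs(val - 0.9) < 1e-3

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_ability(1.0)
        with pytest.raises(ValueError):
            calibrate_adjudicator_ability(0.9999, calibrate_ability(0.6))

    def test_default_panel_spans_accuracy_band(self):
        raters = default_raters()
        assert len(raters) == 8
        assert raters[0].ability > raters[-1].ability


class TestAnalyticOracle:
    def test_unanimity_closed_form(self):
        pc, pw, pwh = analytic_consensus_probability(0.9, 5, 5, 3)
        assert pc == pytest.approx(0.9 ** 5)

    def test_perfect_raters_always_decide_correctly(self):
        for t in range(1, 6):
            pc, pw, pwh = analytic_consensus_probability(1.0, 5, t, 2)
            assert pc == pytest.approx(1.0) and pw == 0.0

    def test_probabilities_sum_to_one(self):
        for p, n, t, k in [(0.9, 5, 3, 2), (0.5, 7, 4, 4), (0.8, 8, 4, 1)]:
            total = sum(analytic_consensus_probability(p, n, t, k))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        """(n=5, t=3, k=2): sum over all 3^5 outcome vectors, computed
        independently of the multinomial path."""
        p, n, t, k = 0.9, 5, 3, 2
        probs = [p, (1 - p) / k, (1 - p) / k]
        ref = [0.0, 0.0, 0.0]  # correct, wrong, withheld
        for outcome in product(range(k + 1), repeat=n):
            pr = 1.0
            for o in outcome:
                pr *= probs[o]
            counts = [outcome.count(c) for c in range(k + 1)]
            reached = [c for c, cnt in enumerate(counts) if cnt >= t]
            if len(reached) == 1:
                ref[0 if reached[0] == 0 else 1] += pr
            else:
                ref[2] += pr
        got = analytic_consensus_probability(p, n, t, k)
        for g, r in zip(got, ref):
            assert g == pytest.approx(r, abs=1e-12)

    def test_unsupported_error_law_rejected(self):
        with pytest.raises(NotImplementedError):
            analytic_consensus_probability(0.9, 5, 3, 2,
                                           assume_iid_uniform_errors=False)

    def test_monte_carlo_within_three_se(self):
        n_items = 10_000
        p, n, t, k = 0.9, 5, 3, 2
        ana = analytic_consensus_probability(p, n, t, k)
        mc = simulate_iid_consensus(p, n, t, k, n_items, seed=77)
        for a, m in zip(ana, mc):
            se = math.sqrt(max(a * (1 - a), 1e-12) / n_items)
            assert abs(a - m) <= 3 * se + 1e-9

    def test_panel_simulator_matches_analytic_in_iid_regime(self):
        """simulate_panel with flat difficulty on the binary task is the
        k=1 iid law; consensus rates agree with the oracle within 3 SE."""
        n_items, p, n_raters, t = 10_000, 0.85, 5, 4
        ability = calibrate_ability(p)
        cfg = _flat_config(CAT, seed=55, n_items=n_items,
                           abilities=[ability] * n_raters)
        ds = simulate_panel(cfg)
        decisions = decide_batch(ds.responses, ConsensusRule(n_raters, t))
        truth = dict(zip(ds.truth["item_id"], ds.truth["true_value"]))
        n_corr = sum(d.decided and str(d.value) == truth[d.item_id]
                     for d in decisions)
        n_with = sum(not d.decided for d in decisions)
        pc, pw, pwh = analytic_consensus_probability(p, n_raters, t, 1)
        for obs, exp in [(n_corr / n_items, pc), (n_with / n_items, pwh)]:
            se = math.sqrt(exp * (1 - exp) / n_items)
            assert abs(obs - exp) <= 3 * se


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(task=CAT, seed=1, label_prevalence=1.5)

    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            SimConfig(task=CAT, seed=None)

    def test_error_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            RaterProfile("r", 1.0, error_weights={"one_arm": 0.5})

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="raters"):
            simulate_panel(SimConfig(task=CAT, seed=1,
                                     reviewer_abilities=(1.0, 1.0)))
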