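"""Confusion arithmetic, threshold sweep, AUC and category breakdowns."""

import numpy as np
import pytest
from scipy import stats

from pentail.errors import EvaluationError
from pentail.evaluation import (
    THRESHOLD_GRID,
    Confusion,
    category_breakdown,
    confusion_at,
    metrics,
    threshold_sweep,
)
from pentail.reference import CATEGORY_COUNTS, synthesize_scores


class TestConfusion:
    def test_simple_tally(self):
        c = confusion_at([0.9, 0.2], [1, 0], 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_threshold_one_predicts_nothing_positive(self, rng):
        probs = rng.random(50)
        c = confusion_at(probs, rng.integers(0, 2, 50), 1.0)
        assert c.tp == 0 and c.fp == 0

    def test_strict_inequality_at_half(self):
        c = confusion_at([0.5], [1], 0.5)
        assert c.fn == 1  # 0.5 is NOT above 0.5

    def test_brute_force_oracle_full_grid(self, rng):
        probs = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        for t in THRESHOLD_GRID:
            c = confusion_at(probs, labels, float(t))
            # plain python tally
            tp = sum(1 for p, y in zip(probs, labels) if p > t and y == 1)
            fp = sum(1 for p, y in zip(probs, labels) if p > t and y == 0)
            assert (c.tp, c.fp) == (tp, fp)
            assert c.n == 1000


class TestMetrics:
    def test_published_lstm_combined_rates(self):
        m = metrics(Confusion(tp=66, fn=8, tn=1080, fp=956))
        assert round(100 * m.sensitivity, 2) == 89.19
        assert round(100 * m.specificity, 2) == 53.05

    def test_published_cnn_combined_sensitivity(self):
        m = metrics(Confusion(tp=83, fn=141, tn=5624, fp=484))
        assert round(100 * m.sensitivity, 2) == 37.05

    def test_perfect_classifier(self):
        m = metrics(Confusion(tp=5, fn=0, tn=7, fp=0))
        assert (m.sensitivity, m.specificity, m.fpr, m.mma) == (1.0, 1.0, 0.0, 1.0)

    def test_degenerate_denominators_flagged(self):
        m = metrics(Confusion(tp=0, fn=0, tn=3, fp=1))
        assert np.isnan(m.sensitivity) and np.isnan(m.mma)
        assert "no_positives" in m.flags


class TestThresholdSweep:
    def test_perfect_separation(self):
        labels = np.array([1, 0, 1, 0, 0])
        report = threshold_sweep(labels.astype(float), labels)
        assert report.btmma == 1.0
        # under strict '>' the 0/1 scores are already separated at t=0.00,
        # and ties break toward the smallest threshold
        assert report.best_threshold == 0.0
        interior = report.curve.iloc[1:100]
        assert (interior["mma"] == 1.0).all()

    def test_constant_half_probs_give_chance_nmma(self):
        report = threshold_sweep([0.5] * 10, [1, 0] * 5)
        assert report.nmma == 0.5  # all predicted negative at t=0.50

    def test_grid_max_equals_brute_force_over_cutpoints(self, rng):
        probs = rng.random(500)
        labels = rng.integers(0, 2, 500)
        report = threshold_sweep(probs, labels)
        best = 0.0
        for t in THRESHOLD_GRID:
            pred = probs > t
            sens = np.mean(pred[labels == 1])
            spec = np.mean(~pred[labels == 0])
            best = max(best, (sens + spec) / 2)
        assert report.btmma == pytest.approx(best, abs=1e-12)

    def test_btmma_never_below_nmma(self, rng):
        for _ in range(10):
            probs = rng.random(100)
            labels = rng.integers(0, 2, 100)
            report = threshold_sweep(probs, labels)
            assert report.btmma >= report.nmma

    def test_count_conservation_and_monotonicity(self, rng):
        probs = rng.random(300)
        labels = rng.integers(0, 2, 300)
        curve = threshold_sweep(probs, labels).curve
        n_pos, n_neg = labels.sum(), (1 - labels).sum()
        assert ((curve["tp"] + curve["fn"]) == n_pos).all()
        assert ((curve["tn"] + curve["fp"]) == n_neg).all()
        assert (np.diff(curve["tp"]) <= 0).all()
        assert (np.diff(curve["tn"]) >= 0).all()

    def test_single_class_labels_rejected(self):
        with pytest.raises(EvaluationError):
            threshold_sweep([0.1, 0.9], [1, 1])


class TestAUC:
    def test_perfect_separation_is_one(self):
        labels = np.array([0, 1, 0, 1])
        report = threshold_sweep(np.array([0.1, 0.9, 0.2, 0.8]), labels)
        assert report.auc == pytest.approx(1.0)

    def test_chance_level_for_uninformative_scores(self, rng):
        probs = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        report = threshold_sweep(probs, labels)
        assert 0.45 <= report.auc <= 0.55

    def test_matches_mann_whitney_oracle(self, rng):
        # grid-aligned scores so discretization cannot exceed 0.01
        probs = rng.integers(0, 101, 200) / 100.0
        labels = rng.integers(0, 2, 200)
        report = threshold_sweep(probs, labels)
        u = stats.mannwhitneyu(probs[labels == 1], probs[labels == 0]).statistic
        auc_rank = u / (labels.sum() * (1 - labels).sum())
        assert abs(report.auc - auc_rank) <= 0.01


class TestCategoryBreakdown:
    def test_published_cnn_nursing_specificity(self):
        probs, labels, cats = synthesize_scores(CATEGORY_COUNTS["cnn"]["combined"])
        table = category_breakdown(probs, labels, cats, 0.5).set_index("category")
        row = table.loc["nursing"]
        assert (row["predicted_no_biting"], row["predicted_biting"]) == (701, 7)
        assert round(100 * row["specificity"], 2) == 99.01

    def test_absent_category_omitted(self):
        table = category_breakdown([0.9, 0.1], [1, 0],
                                   ["tail_biting", "no_event"], 0.5)
        assert set(table["category"]) == {"tail_biting", "no_event"}

    def test_rows_partition_total_confusion(self, rng):
        probs = rng.random(200)
        labels = rng.integers(0, 2, 200)
        cats = np.where(
            labels == 1, "tail_biting",
            rng.choice(["no_event", "nursing", "negative_social"], 200),
        ).astype(object)
        table = category_breakdown(probs, labels, cats, 0.5)
        c = confusion_at(probs, labels, 0.5)
        assert table["predicted_biting"].sum() == c.tp + c.fp
        assert table["predicted_no_biting"].sum() == c.tn + c.fn

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            category_breakdown([0.5], [0], ["grooming"], 0.5)
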