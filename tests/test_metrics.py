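"""Confusion metrics against brute-force re-derivations and library cross-checks."""

import numpy as np
import pytest
import sklearn.metrics as skm

from wavemri import (
    ConfusionCounts,
    MetricReport,
    UndefinedMetricError,
    cohen_kappa,
    fp_rate,
    kappa_from_rates,
    precision,
    recall,
    roc_auc,
)


def kappa_oracle(tp, fp, tn, fn):
    """Independent po/pe arithmetic, written out longhand."""
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    pe = ((tp + fp) / n) * ((tp + fn) / n) + ((tn + fn) / n) * ((tn + fp) / n)
    return (po - pe) / (1 - pe)


def auc_oracle(scores, labels):
    """Pairwise Mann-Whitney comparison: wins + half-ties over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestPrecisionRecall:
    def test_worked_values(self):
        assert precision(ConfusionCounts(tp=9, fp=1, tn=0, fn=0)) == pytest.approx(0.9)
        assert recall(ConfusionCounts(tp=99, fp=0, tn=0, fn=1)) == pytest.approx(0.99)

    def test_no_false_alarms_and_no_misses(self):
        c = ConfusionCounts(tp=5, fp=0, tn=7, fn=0)
        assert precision(c) == 1.0 and recall(c) == 1.0

    def test_table_implied_precision(self):
        # counts implied by the published rates at class sizes 2045/2055
        assert precision(ConfusionCounts(tp=2024, fp=4, tn=2051, fn=21)) == (
            pytest.approx(0.998, abs=5e-4)
        )

    def test_recall_of_swapped_problem_equals_specificity(self, rng):
        tp, fp, tn, fn = rng.integers(1, 50, size=4)
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        swapped = ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp)
        assert recall(swapped) == pytest.approx(1 - fp_rate(c))

    def test_undefined_cases(self):
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(tp=0, fp=1, tn=3, fn=0))

    def test_both_perfect_iff_diagonal(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 5, size=4)
            tp, tn = tp + 1, tn + 1  # keep denominators alive
            c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
            both_one = precision(c) == 1.0 and recall(c) == 1.0
            assert both_one == (fp == 0 and fn == 0)


class TestCohenKappa:
    def test_perfect_classifier(self):
        assert cohen_kappa(ConfusionCounts(tp=10, fp=0, tn=20, fn=0)) == 1.0

    def test_chance_level_balanced_independence(self):
        # predictions independent of labels at balanced marginals
        assert cohen_kappa(ConfusionCounts(tp=25, fp=25, tn=25, fn=25)) == (
            pytest.approx(0.0, abs=1e-15)
        )

    def test_against_brute_force_oracle(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 200, size=4) + 1
            got = cohen_kappa(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert got == pytest.approx(kappa_oracle(tp, fp, tn, fn), abs=1e-12)

    def test_against_sklearn_on_label_vectors(self, rng):
        y_true = rng.integers(0, 2, size=300)
        y_pred = np.where(rng.random(300) < 0.8, y_true, 1 - y_true)
        c = ConfusionCounts.from_labels(y_true, y_pred)
        assert cohen_kappa(c) == pytest.approx(
            skm.cohen_kappa_score(y_true, y_pred), abs=1e-12
        )

    def test_invariant_under_class_relabeling(self, rng):
        tp, fp, tn, fn = rng.integers(1, 100, size=4)
        a = cohen_kappa(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        b = cohen_kappa(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_one_cell_matrix(self):
        with pytest.raises(UndefinedMetricError):
            cohen_kappa(ConfusionCounts(tp=10, fp=0, tn=0, fn=0))


class TestKappaFromRates:
    def test_published_rate_reconstruction(self):
        """The printed sensitivity 0.99 / FP rate 0.0020 at class sizes
        2045/2055 imply kappa 0.9880 to 4 decimals."""
        assert round(kappa_from_rates(0.99, 0.0020, 2045, 2055), 4) == 0.9880

    def test_perfect_rates(self):
        assert kappa_from_rates(1.0, 0.0, 123, 456) == pytest.approx(1.0)

    @pytest.mark.parametrize("r", [0.1, 0.5, 0.9])
    def test_equal_rates_are_chance(self, r):
        assert kappa_from_rates(r, r, 50, 50) == pytest.approx(0.0, abs=1e-12)

    def test_balanced_closed_form_is_rate_difference(self, rng):
        # with n_pos == n_neg, pe = 1/2 exactly, so kappa = tpr - fpr
        for _ in range(20):
            tpr, fpr = rng.random(2)
            assert kappa_from_rates(tpr, fpr, 80, 80) == pytest.approx(
                tpr - fpr, abs=1e-12
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kappa_from_rates(1.2, 0.0, 10, 10)
        with pytest.raises(ValueError):
            kappa_from_rates(0.5, 0.5, 0, 10)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == pytest.approx(0.5)

    def test_against_pairwise_oracle(self, rng):
        for _ in range(100):
            n = 20
            labels = np.concatenate([np.ones(8, dtype=int), np.zeros(12, dtype=int)])
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            got = roc_auc(scores, labels)
            assert got == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_against_sklearn(self, rng):
        labels = rng.integers(0, 2, size=200)
        labels[:2] = [0, 1]
        scores = rng.random(200)
        assert roc_auc(scores, labels) == pytest.approx(
            skm.roc_auc_score(labels, scores), abs=1e-12
        )

    def test_complement_identity_for_tie_free_scores(self, rng):
        labels = np.array([0, 1] * 15)
        scores = rng.permutation(30) / 30.0
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [1, 1])


class TestMetricReport:
    def test_from_scores_and_column_names(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.6, 0.7, 0.9]
        rep = MetricReport.from_scores(labels, scores)
        d = rep.to_dict()
        assert set(d) == {
            "Kappa Statistics", "TP Rate", "FP Rate", "ROC",
            "Recall", "Precision", "Accuracy",
        }
        assert d["TP Rate"] == 1.0 and d["FP Rate"] == 0.5
        assert d["ROC"] == 1.0
        assert d["Accuracy"] == 0.75
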