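"""Partitioning, cross-validation, bootstrap, and the metric panel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mlpcalr import (
    ConfusionMatrix,
    auc,
    bootstrap_validate,
    confusion,
    cross_validate,
    metrics,
    round_half_up,
    select_parsimonious,
    stratified_kfold,
    stratified_split,
)
from mlpcalr.classify import mlpcalr_trainer
from mlpcalr.validation import MetricsReport

STRATUM = ("micronir", "skull")


class TestStratifiedSplit:
    def test_study_partition_counts(self):
        """33 historical + 26 modern into 40 training: 22/18 train, 11/8 test."""
        y = np.array([1] * 33 + [0] * 26)
        train, test = stratified_split(y, 40, seed=0)
        assert np.sum(y[train] == 1) == 22 and np.sum(y[train] == 0) == 18
        assert np.sum(y[test] == 1) == 11 and np.sum(y[test] == 0) == 8
        assert np.array_equal(np.sort(np.r_[train, test]), np.arange(59))

    def test_small_symmetric_split(self):
        y = np.array([1, 1, 0, 0])
        train, _ = stratified_split(y, 2, seed=5)
        assert np.sum(y[train] == 1) == 1 and np.sum(y[train] == 0) == 1

    def test_seed_determinism(self):
        y = np.array([1] * 10 + [0] * 8)
        t1, _ = stratified_split(y, 12, seed=7)
        t2, _ = stratified_split(y, 12, seed=7)
        t3, _ = stratified_split(y, 12, seed=8)
        assert np.array_equal(t1, t2)
        assert np.sum(y[t3] == 1) == np.sum(y[t1] == 1)  # same counts regardless

    def test_emptying_a_class_errors(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([1, 0, 0, 0, 0, 0, 0, 0]), 7, seed=0)


class TestStratifiedKfold:
    def test_study_fold_counts(self):
        y = np.array([1] * 22 + [0] * 18)
        folds = stratified_kfold(y, k=10, seed=0)
        assert all(len(f) == 4 for f in folds)
        assert all(np.sum(y[f] == 1) in (2, 3) for f in folds)

    def test_leave_one_out(self):
        y = np.array([1, 0, 1, 0, 1])
        folds = stratified_kfold(y, k=5, seed=1)
        assert sorted(len(f) for f in folds) == [1] * 5

    def test_partition_contract(self):
        y = np.array([1] * 13 + [0] * 9)
        folds = stratified_kfold(y, k=4, seed=3)
        joined = np.concatenate(folds)
        assert np.array_equal(np.sort(joined), np.arange(22))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([1, 0]), k=3)


class TestConfusionAndMetrics:
    def test_scanner_mandible_test_panel(self):
        """Panel on the 11+8-specimen external-test confusion matrix."""
        rep = metrics(ConfusionMatrix(tp=10, fn=1, fp=3, tn=5))
        assert round_half_up(rep.accuracy) == 0.79
        assert round_half_up(rep.sensitivity) == 0.91
        assert round_half_up(rep.specificity) == 0.63
        assert round_half_up(rep.precision) == 0.77
        assert round_half_up(rep.npv) == 0.83
        assert round_half_up(rep.fpr) == 0.38

    def test_micronir_mandible_cv_panel(self):
        rep = metrics(ConfusionMatrix(tp=20, fn=2, fp=0, tn=18))
        assert round_half_up(rep.accuracy) == 0.95
        assert round_half_up(rep.sensitivity) == 0.91
        assert rep.specificity == 1.0 and rep.precision == 1.0
        assert round_half_up(rep.npv) == 0.90
        assert rep.fpr == 0.0 and round_half_up(rep.fnr) == 0.09

    def test_perfect_classifier(self):
        rep = metrics(confusion([1, 1, 0, 0], [1, 1, 0, 0]))
        assert (
            rep.accuracy == rep.sensitivity == rep.specificity
            == rep.precision == rep.npv == 1.0
        )
        assert rep.fpr == rep.fnr == 0.0

    def test_undefined_metrics_flagged_not_zeroed(self):
        rep = metrics(ConfusionMatrix(tp=0, fn=0, fp=2, tn=3))
        assert rep.sensitivity is None and rep.fnr is None
        assert rep.specificity is not None

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion([], [])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_metric_identities(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        rep = metrics(ConfusionMatrix(tp, fn, fp, tn))
        if rep.sensitivity is not None:
            assert rep.sensitivity + rep.fnr == pytest.approx(1.0)
        if rep.specificity is not None:
            assert rep.specificity + rep.fpr == pytest.approx(1.0)
        p_count, n_count = tp + fn, fp + tn
        if p_count and n_count:
            assert rep.accuracy == pytest.approx(
                (rep.sensitivity * p_count + rep.specificity * n_count) / (p_count + n_count)
            )


class TestAuc:
    def test_worked_example(self):
        assert auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)

    def test_extremes(self):
        assert auc([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0
        assert auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.3])

    def test_equals_brute_force_pairwise(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            prob = np.round(rng.uniform(size=n), 2)  # rounded to force ties
            pos, neg = prob[y == 1], prob[y == 0]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
            assert auc(y, prob) == pytest.approx(np.mean(pairs))


class TestSelectParsimonious:
    def _reports(self, accs, aucs=None):
        out = {}
        for p, a in accs.items():
            out[p] = MetricsReport(accuracy=a, auc=(aucs or {}).get(p))
        return out

    def test_smallest_at_max_accuracy(self):
        assert select_parsimonious(self._reports({1: 0.8, 2: 1.0, 3: 1.0})) == 2

    def test_all_equal_gives_one(self):
        assert select_parsimonious(self._reports({1: 0.9, 2: 0.9, 3: 0.9})) == 1

    def test_auc_breaks_accuracy_ties(self):
        # 2 and 3 tie on accuracy; 3 has the higher AUC
        reports = self._reports({1: 0.8, 2: 1.0, 3: 1.0}, {1: 1.0, 2: 0.99, 3: 1.0})
        assert select_parsimonious(reports) == 3
        # but a non-tied accuracy wins regardless of AUC
        reports = self._reports({2: 1.0, 3: 0.9}, {2: 0.99, 3: 1.0})
        assert select_parsimonious(reports) == 2


class TestCrossValidate:
    def test_separated_stratum_perfect_from_two_components(self, small_stratum):
        cv = cross_validate(
            mlpcalr_trainer(), small_stratum, STRATUM, p_grid=[1, 2, 3], k=5, seed=0
        )
        assert cv[2].accuracy >= 0.95
        assert cv[3].accuracy >= 0.9

    def test_deterministic_given_seed(self, small_stratum):
        a = cross_validate(mlpcalr_trainer(), small_stratum, STRATUM, p_grid=[2], k=5, seed=4)
        b = cross_validate(mlpcalr_trainer(), small_stratum, STRATUM, p_grid=[2], k=5, seed=4)
        assert a[2].accuracy == b[2].accuracy and a[2].auc == b[2].auc


class TestBootstrap:
    def test_single_iteration_reproducible(self, small_stratum):
        a = bootstrap_validate(mlpcalr_trainer(), small_stratum, STRATUM, p=2, B=1, seed=9)
        b = bootstrap_validate(mlpcalr_trainer(), small_stratum, STRATUM, p=2, B=1, seed=9)
        assert a.accuracy == b.accuracy
        assert a.n_effective["accuracy"] == 1

    def test_oob_fraction_near_classical_limit(self, small_stratum):
        rep = bootstrap_validate(mlpcalr_trainer(), small_stratum, STRATUM, p=2, B=60, seed=2)
        n = 20
        assert abs(rep.oob_fraction_mean - (1 - 1 / n) ** n) < 0.06

    def test_mean_accuracy_close_to_external_test(self, small_stratum):
        rep = bootstrap_validate(mlpcalr_trainer(), small_stratum, STRATUM, p=2, B=60, seed=2)
        assert rep.accuracy >= 0.85
        assert set(rep.std) >= {"accuracy"}
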