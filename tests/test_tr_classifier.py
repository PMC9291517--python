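"""Splitting, Borderline-SMOTE balancing, lasso stability selection and
logistic classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvshape import tr_classifier as tc


def make_cohort(n_healthy=6, n_control=27, n_tr=21, n_modes=8, seed=0,
                signal=0.0):
    """Gaussian loadings; optional mean shift of mode 1 for the TR group."""
    rng = np.random.default_rng(seed)
    groups = (["healthy"] * n_healthy + ["control"] * n_control
              + ["tr"] * n_tr)
    g = np.array(groups)
    s = rng.normal(size=(len(g), n_modes))
    s[g == "tr", 0] += signal
    return tc.LabeledCohort(s, (g == "tr").astype(int), g)


class TestSplit:
    def test_floor_convention_54_subjects(self):
        cohort = make_cohort()
        train, test = tc.split_train_test(cohort, 0.8, seed=1)
        assert len(train) == 43 and len(test) == 11

    def test_partition_disjoint_and_exhaustive(self):
        cohort = make_cohort()
        train, test = tc.split_train_test(cohort, 0.8, seed=2)
        ids = sorted(train.subject_ids + test.subject_ids)
        assert ids == sorted(cohort.subject_ids)
        assert not set(train.subject_ids) & set(test.subject_ids)

    def test_deterministic_given_seed(self):
        cohort = make_cohort()
        a = tc.split_train_test(cohort, 0.8, seed=3)
        b = tc.split_train_test(cohort, 0.8, seed=3)
        assert a[0].subject_ids == b[0].subject_ids

    def test_stratified_by_label(self):
        cohort = make_cohort()
        train, test = tc.split_train_test(cohort, 0.8, seed=4)
        # 21/54 positives: train should hold ~0.8 * 21 = 16.8 of them
        assert train.y.sum() in (16, 17)
        assert test.y.sum() in (4, 5)

    def test_degenerate_fraction_errors(self):
        cohort = make_cohort()
        with pytest.raises(ValueError):
            tc.split_train_test(cohort, 1.0, seed=0)


class TestBorderlineSMOTE:
    def test_balanced_input_unchanged(self):
        cohort = make_cohort(5, 5, 5)
        out = tc.borderline_smote(cohort, seed=0)
        assert len(out) == len(cohort)
        assert np.allclose(out.s, cohort.s)

    def test_minorities_upsampled_to_majority(self):
        cohort = make_cohort(5, 20, 8)
        out = tc.borderline_smote(cohort, seed=0)
        for g in ("healthy", "control", "tr"):
            assert (out.group3 == g).sum() == 20
        # originals retained unchanged, in order
        assert np.allclose(out.s[: len(cohort)], cohort.s)

    def test_synthetic_points_are_convex_combinations(self):
        cohort = make_cohort(4, 15, 6, seed=5)
        out = tc.borderline_smote(cohort, seed=1)
        new = out.s[out.synthetic]
        new_g = out.group3[out.synthetic]
        for x, g in zip(new, new_g):
            orig = cohort.s[cohort.group3 == g]
            best = np.inf
            for i in range(len(orig)):
                for j in range(len(orig)):
                    if i == j:
                        continue
                    a, b = orig[i], orig[j]
                    seg = b - a
                    u = np.dot(x - a, seg) / np.dot(seg, seg)
                    if 0.0 < u < 1.0:
                        best = min(best,
                                   np.linalg.norm(x - (a + u * seg)))
            assert best < 1e-9

    def test_synthetic_labels_follow_class(self):
        cohort = make_cohort(3, 12, 5)
        out = tc.borderline_smote(cohort, seed=2)
        assert np.array_equal(out.y, (out.group3 == "tr").astype(int))

    def test_tiny_minority_errors(self):
        cohort = make_cohort(1, 8, 4)
        with pytest.raises(ValueError):
            tc.borderline_smote(cohort, seed=0)


class TestLassoDominance:
    def test_informative_mode_dominates(self):
        cohort = make_cohort(0, 20, 0, n_modes=6, seed=7)
        # y determined by mode 1 threshold, other modes pure noise
        s = cohort.s
        y = (s[:, 0] > np.median(s[:, 0])).astype(int)
        g = np.where(y == 1, "tr", "control")
        cohort = tc.LabeledCohort(s, y, g)
        res = tc.lasso_dominance(cohort, n_repeats=50, seed=1)
        assert res.dominance[0] >= 0.95
        assert res.dominance[0] == res.dominance.max()

    def test_null_labels_low_dominance(self):
        rng = np.random.default_rng(0)
        doms = []
        for seed in range(10):
            s = rng.normal(size=(24, 6))
            y = np.array([0, 1] * 12)
            g = np.where(y == 1, "tr", "control")
            cohort = tc.LabeledCohort(s, y, g)
            res = tc.lasso_dominance(cohort, n_repeats=25, seed=seed)
            doms.append(res.dominance.max())
        assert np.mean(doms) < 0.5

    def test_repeat_count_echoed(self):
        cohort = make_cohort(0, 10, 10, n_modes=4, signal=2.0)
        res = tc.lasso_dominance(cohort, n_repeats=20, seed=0)
        assert res.n_repeats == 20

    def test_constant_column_excluded(self):
        cohort = make_cohort(0, 10, 10, n_modes=4, signal=2.0)
        cohort.s[:, 2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = tc.lasso_dominance(cohort, n_repeats=10, seed=0)
        assert res.dominance[2] == 0.0


class TestSelectTopModes:
    def test_top_four_by_dominance(self):
        res = tc.LassoSelectionResult(
            np.array([0.9, 0.1, 0.8, 0.7, 0.6]), 100)
        assert list(tc.select_top_modes(res, 4)) == [0, 2, 3, 4]

    def test_tie_breaks_to_lower_index(self):
        res = tc.LassoSelectionResult(np.array([0.9, 0.8, 0.8, 0.1]), 100)
        assert list(tc.select_top_modes(res, 2)) == [0, 1]

    def test_insufficient_nonzero_modes_error(self):
        res = tc.LassoSelectionResult(np.array([0.9, 0.0, 0.0, 0.0]), 100)
        with pytest.raises(ValueError, match="dominance"):
            tc.select_top_modes(res, 4)


class TestClassifier:
    def test_separable_data_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(30, 2))
        y = (s[:, 0] > 0).astype(int)
        s[:, 0] += np.where(y == 1, 3.0, -3.0)
        g = np.where(y == 1, "tr", "control")
        cohort = tc.LabeledCohort(s, y, g)
        clf = tc.fit_classifier(cohort, [0, 1], seed=0)
        rep = tc.evaluate(clf, cohort)
        assert rep.accuracy == 1.0

    def test_probability_monotone_in_informative_mode(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(40, 1))
        # overlapping classes: noisy threshold keeps coefficients finite
        y = (s[:, 0] + rng.normal(size=40) > 0).astype(int)
        g = np.where(y == 1, "tr", "control")
        clf = tc.fit_classifier(tc.LabeledCohort(s, y, g), [0], seed=0)
        grid = np.linspace(-3, 3, 21)[:, None]
        p = clf.predict_proba(grid)[:, 1]
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_permuted_labels_auc_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = rng.normal(size=(40, 3))
            y = rng.permutation([0, 1] * 20)
            g = np.where(y == 1, "tr", "control")
            cohort = tc.LabeledCohort(s, y, g)
            tr_c, te_c = tc.split_train_test(cohort, 0.8, seed)
            clf = tc.fit_classifier(tr_c, [0, 1, 2], seed=seed)
            aucs.append(tc.evaluate(clf, te_c).auc)
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_single_class_training_errors(self):
        s = np.zeros((5, 2))
        cohort = tc.LabeledCohort(s, np.ones(5, dtype=int),
                                  np.array(["tr"] * 5))
        with pytest.raises(ValueError):
            tc.fit_classifier(cohort, [0], seed=0)


class _FixedClassifier:
    """Deterministic stub emitting prescribed probabilities."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, x):
        return np.column_stack([1 - self.probs, self.probs])


class TestEvaluate:
    def test_hand_built_confusion_matrix_metrics(self):
        # TP=9, FN=2, TN=9, FP=1
        y = np.array([1] * 11 + [0] * 10)
        probs = np.array([0.9] * 9 + [0.1] * 2 + [0.2] * 9 + [0.8])
        g = np.where(y == 1, "tr", "control")
        test = tc.LabeledCohort(np.zeros((21, 1)), y, g)
        rep = tc.evaluate(_FixedClassifier(probs), test)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (9, 2, 9, 1)
        assert rep.recall == pytest.approx(9 / 11)
        assert rep.precision == pytest.approx(0.9)
        assert rep.accuracy == pytest.approx(18 / 21)
        expect_f1 = 2 * rep.recall * rep.precision / (rep.recall
                                                      + rep.precision)
        assert rep.f1 == pytest.approx(expect_f1)

    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1])
        g = np.where(y == 1, "tr", "control")
        test = tc.LabeledCohort(np.zeros((4, 1)), y, g)
        rep = tc.evaluate(_FixedClassifier([0.1, 0.2, 0.8, 0.9]), test)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) \
            == (1.0, 1.0, 1.0, 1.0)
        assert rep.auc == pytest.approx(1.0)

    def test_all_positive_predictor_on_balanced_test(self):
        y = np.array([0, 1] * 5)
        g = np.where(y == 1, "tr", "control")
        test = tc.LabeledCohort(np.zeros((10, 1)), y, g)
        rep = tc.evaluate(_FixedClassifier([0.9] * 10), test)
        assert rep.recall == 1.0
        assert rep.precision == pytest.approx(0.5)
        assert rep.accuracy == pytest.approx(0.5)

    def test_roc_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 10)
        g = np.where(y == 1, "tr", "control")
        test = tc.LabeledCohort(np.zeros((20, 1)), y, g)
        rep = tc.evaluate(_FixedClassifier(rng.uniform(size=20)), test)
        assert tuple(rep.roc[0]) == (0.0, 0.0)
        assert tuple(rep.roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(rep.roc[:, 0]) >= 0)

    def test_single_class_test_metrics_defined_auc_nan(self):
        y = np.ones(5, dtype=int)
        test = tc.LabeledCohort(np.zeros((5, 1)), y, np.array(["tr"] * 5))
        rep = tc.evaluate(_FixedClassifier([0.9, 0.9, 0.9, 0.1, 0.9]), test)
        assert rep.recall == pytest.approx(0.8)
        assert np.isnan(rep.auc)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(tp=st.integers(0, 25), fn=st.integers(0, 25),
       tn=st.integers(0, 25), fp=st.integers(0, 25))
def test_metrics_match_count_ratios_for_any_confusion(tp, fn, tn, fp):
    """Every reachable confusion matrix yields metrics equal to their
    defining count ratios, with empty denominators reported as 0."""
    if tp + fn + tn + fp == 0:
        return
    y = np.array([1] * (tp + fn) + [0] * (tn + fp))
    probs = np.array([0.9] * tp + [0.1] * fn + [0.1] * tn + [0.9] * fp)
    g = np.where(y == 1, "tr", "control")
    test = tc.LabeledCohort(np.zeros((len(y), 1)), y, g)

    class Fixed:
        def predict_proba(self, x):
            return np.column_stack([1 - probs, probs])

    rep = tc.evaluate(Fixed(), test)
    assert (rep.tp, rep.fn, rep.tn, rep.fp) == (tp, fn, tn, fp)
    assert rep.accuracy == pytest.approx((tn + tp) / (tn + tp + fn + fp))
    assert rep.precision == pytest.approx(
        tp / (tp + fp) if tp + fp else 0.0)
    assert rep.recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
    denom = rep.recall + rep.precision
    assert rep.f1 == pytest.approx(
        2 * rep.recall * rep.precision / denom if denom else 0.0)
    assert 0.0 <= min(rep.accuracy, rep.precision, rep.recall, rep.f1)
    assert max(rep.accuracy, rep.precision, rep.recall, rep.f1) <= 1.0


class TestEndToEnd:
    def test_smote_never_reaches_test_set(self):
        cohort = make_cohort(signal=2.0, seed=9)
        train, test = tc.split_train_test(cohort, 0.8, seed=0)
        balanced = tc.borderline_smote(train, seed=0)
        assert not test.synthetic.any()
        assert set(test.subject_ids).isdisjoint(
            np.array(balanced.subject_ids)[balanced.synthetic]
        )

    def test_classify_cohort_recovers_strong_signal(self):
        cohort = make_cohort(signal=4.0, seed=13)
        rep = tc.classify_cohort(cohort, n_repeats=25, seed=3)
        assert rep.recall >= 0.8
        assert rep.precision >= 0.8
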