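"""Classification machinery: grouped folds, weighted SVM, ROC oracle, operating point."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ramanmargin.classify import (
    MODEL_DICHOTOMIES,
    ModelSpec,
    make_grouped_folds,
    grid_search_cv,
    operating_point,
    roc_curve,
    run_model,
    train_weighted_svm,
)


def brute_force_auc(p, y):
    """Pairwise concordance with ties counted one half."""
    p, y = np.asarray(p, dtype=float), np.asarray(y)
    pos, neg = p[y == 1], p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestGroupedFolds:
    def test_twenty_patients_five_folds_even(self):
        ids = np.repeat([f"P{i}" for i in range(20)], 3)
        folds = make_grouped_folds(ids, k=5, seed=0)
        per_fold_patients = [len(set(ids[folds == k])) for k in range(5)]
        assert per_fold_patients == [4] * 5

    def test_no_patient_spans_two_folds(self):
        rng = np.random.default_rng(0)
        ids = rng.choice([f"P{i}" for i in range(11)], size=100)
        folds = make_grouped_folds(ids, k=5, seed=1)
        for pid in set(ids):
            assert len(set(folds[ids == pid])) == 1

    def test_deterministic_under_seed(self):
        ids = np.repeat([f"P{i}" for i in range(10)], 2)
        np.testing.assert_array_equal(
            make_grouped_folds(ids, seed=5), make_grouped_folds(ids, seed=5)
        )

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="patients"):
            make_grouped_folds(["P1", "P2", "P3"], k=5)


class TestWeightedSVM:
    def test_separable_toy_fits_exactly(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        model = train_weighted_svm(X, y, C=1.0)
        assert np.array_equal((model.posterior(X) >= 0.5).astype(int), y)

    def test_posteriors_bounded_and_monotone_in_decision(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=80) > 0).astype(int)
        model = train_weighted_svm(X, y, C=0.5)
        d = model.decision(X)
        p = model.posterior(X)
        assert np.all((p >= 0) & (p <= 1))
        order = np.argsort(d)
        assert np.all(np.diff(p[order]) >= -1e-12)

    def test_minority_recall_non_decreasing_in_gamma(self):
        rng = np.random.default_rng(1)
        recalls = {1.0: [], 10.0: []}
        for trial in range(20):
            n_maj, n_min = 90, 10
            X = np.vstack([
                rng.normal(0.0, 1.0, size=(n_maj, 2)),
                rng.normal(1.4, 1.0, size=(n_min, 2)),
            ])
            y = np.array([0] * n_maj + [1] * n_min)
            for gamma in recalls:
                model = train_weighted_svm(X, y, C=0.1, gamma=gamma)
                pred = model.posterior(X) >= 0.5
                recalls[gamma].append(pred[y == 1].mean())
        assert np.mean(recalls[10.0]) >= np.mean(recalls[1.0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            train_weighted_svm(np.ones((4, 2)), np.zeros(4))


class TestROC:
    def test_perfect_ranking_gives_unit_auc(self):
        roc = roc_curve([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0, abs=1e-12)

    def test_half_concordant_example(self):
        # pairs: (.9,.6) ok, (.9,.5) ok, (.3,.6) no, (.3,.5) no -> AUC 0.5
        roc = roc_curve([0.9, 0.3, 0.6, 0.5], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.5, abs=1e-12)

    def test_random_posteriors_near_half(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=2000)
        y = rng.integers(0, 2, size=2000)
        assert abs(roc_curve(p, y).auc - 0.5) < 0.03

    def test_trapezoid_equals_brute_force_concordance_with_ties(self):
        rng = np.random.default_rng(1)
        for n in (10, 37, 200):
            p = rng.integers(0, 8, size=n) / 7.0  # coarse grid forces ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            assert roc_curve(p, y).auc == pytest.approx(brute_force_auc(p, y), abs=1e-10)

    @given(st.integers(0, 2**32 - 1))
    def test_auc_matches_concordance_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        p = np.round(rng.uniform(size=n), 2)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert roc_curve(p, y).auc == pytest.approx(brute_force_auc(p, y), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.5, 0.6], [1, 1])


class TestOperatingPoint:
    def test_brute_force_corner_distance(self):
        # curve visits exactly (FPR, TPR) = (0,0), (0.1,0.9), (1,1);
        # distances to the corner are 1, sqrt(0.02)~0.141, 1
        p = np.array([0.9] * 9 + [0.05] + [0.9] + [0.05] * 9)
        y = np.array([1] * 10 + [0] * 10)
        roc = roc_curve(p, y)
        lam, sens, spec, acc = operating_point(roc)
        assert sens == pytest.approx(0.9)
        assert spec == pytest.approx(0.9)

    def test_perfect_classifier_hits_corner(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        lam, sens, spec, acc = operating_point(roc)
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_tie_broken_toward_higher_sensitivity(self):
        # two curve points at the same corner distance 0.1: (sens 0.9, spec 1.0)
        # and (sens 1.0, spec 0.9); the declared tie-break favours sensitivity
        p = np.array([0.9] * 9 + [0.2] + [0.8] + [0.1] * 9)
        y = np.array([1] * 10 + [0] * 10)
        roc = roc_curve(p, y)
        lam, sens, spec, acc = operating_point(roc)
        assert sens == pytest.approx(1.0)
        assert spec == pytest.approx(0.9)

    def test_metrics_agree_with_confusion_matrix(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        y = (p + rng.normal(0, 0.3, 100) > 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        roc = roc_curve(p, y)
        lam, sens, spec, acc = operating_point(roc)
        (tn, fp), (fn, tp) = roc.confusion
        assert sens == pytest.approx(tp / (tp + fn), abs=1e-10)
        assert spec == pytest.approx(tn / (tn + fp), abs=1e-10)
        assert acc == pytest.approx((tp + tn) / 100, abs=1e-10)


class TestGridSearch:
    @staticmethod
    def _toy(n_patients=10, per=6, seed=0):
        rng = np.random.default_rng(seed)
        X, y, g = [], [], []
        for p in range(n_patients):
            cls = p % 2
            for _ in range(per):
                X.append(rng.normal(cls * 2.0, 1.0, size=2))
                y.append(cls)
                g.append(f"P{p}")
        return np.array(X), np.array(y), np.array(g)

    def test_single_point_grid_selected(self):
        X, y, g = self._toy()
        spec = ModelSpec(c_grid=(0.1,), gamma_grid=(2.0,), seed=0)
        res = grid_search_cv(X, y, g, spec)
        assert (res.best_c, res.best_gamma) == (0.1, 2.0)

    def test_report_has_k_times_grid_entries(self):
        X, y, g = self._toy()
        spec = ModelSpec(c_grid=(0.01, 0.1, 1.0), gamma_grid=(1.0, 5.0), seed=0)
        res = grid_search_cv(X, y, g, spec)
        assert len(res.report) == 5 * 3 * 2

    def test_separated_classes_reach_high_auc(self):
        X, y, g = self._toy(seed=3)
        res = grid_search_cv(X, y, g, ModelSpec(seed=0))
        assert res.best_mean_auc > 0.95

    def test_no_patient_leakage_at_any_grid_point(self):
        X, y, g = self._toy(seed=4)
        spec = ModelSpec(seed=1)
        res = grid_search_cv(X, y, g, spec)
        for k in range(spec.n_folds):
            train_patients = set(g[res.folds != k])
            test_patients = set(g[res.folds == k])
            assert not train_patients & test_patients

    def test_c_grid_outside_interval_rejected(self):
        with pytest.raises(ValueError, match="within"):
            ModelSpec(c_grid=(10.0,))


class TestRunModel:
    def test_all_dichotomies_defined(self):
        assert set(MODEL_DICHOTOMIES) == {"A", "B", "C", "FAT"}
        assert MODEL_DICHOTOMIES["A"] == ("cancer", ("normal", "fat"))
        assert MODEL_DICHOTOMIES["FAT"] == ("fat", ("cancer", "normal"))

    def test_report_schema_and_quality_on_clean_cohort(self, small_clean_spec):
        from ramanmargin.cohort import build_dataset
        from ramanmargin.preprocess import fit_calibration
        from ramanmargin.synthetic import generate_cohort
        from ramanmargin.workflow import make_references

        acqs, manifest = generate_cohort(small_clean_spec)
        standard, poly = make_references(small_clean_spec)
        bundle = build_dataset(acqs, manifest, standard, fit_calibration(poly))
        report = run_model(bundle.features, "B", spec=ModelSpec(seed=0))
        assert report["auc"] > 0.9
        assert 1 <= len(report["retained_bands"]) <= 9
        assert report["confusion"] is not None
        assert 0 <= report["operating_threshold"] <= 1
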