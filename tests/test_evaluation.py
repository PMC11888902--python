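"""Metrics against hand computations and independent oracles; split contracts."""

import numpy as np
import pytest
from scipy import stats as spstats
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from bcgkit import (
    ConfusionMatrix,
    basic_metrics,
    cohens_kappa,
    compare_models,
    confusion,
    evaluate_model,
    holdout_split,
    kfold_cv,
    mcnemar_test,
    roc_auc,
)
from bcgkit.evaluation import parse_scheme
from bcgkit.models import make_model, EnsembleConfig

Y8_TRUE = np.array([1, 1, 1, 0, 0, 0, 0, 0])
Y8_PRED = np.array([1, 1, 0, 1, 0, 0, 0, 0])


def rank_auc(y, s):
    """Oracle: Mann-Whitney AUC by pair enumeration (ties count one half)."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_complement_prediction(self):
        cm = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert cm.tp == 0 and cm.tn == 0 and cm.fp == 2 and cm.fn == 2

    def test_hand_count(self):
        cm = confusion(Y8_TRUE, Y8_PRED)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 4)

    def test_validation(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])


class TestBasicMetrics:
    def test_hand_derived_values(self):
        m = basic_metrics(ConfusionMatrix(tp=2, fn=1, fp=1, tn=4))
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["jaccard"] == pytest.approx(0.5)

    def test_perfect_prediction_all_ones(self):
        m = basic_metrics(ConfusionMatrix(tp=3, tn=5, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_zero_convention(self):
        with pytest.warns(UserWarning):
            m = basic_metrics(ConfusionMatrix(tp=0, tn=2, fp=1, fn=1))
        assert m["f1"] == 0.0
        assert m["jaccard"] == 0.0

    def test_sensitivity_specificity_swap_under_class_flip(self, rng):
        y = rng.integers(0, 2, 100)
        p = rng.integers(0, 2, 100)
        m = basic_metrics(confusion(y, p))
        m_flipped = basic_metrics(confusion(1 - y, 1 - p))
        assert m["sensitivity"] == pytest.approx(m_flipped["specificity"])
        assert m["specificity"] == pytest.approx(m_flipped["sensitivity"])


class TestCohensKappa:
    def test_identical_vectors(self):
        assert cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_hand_computed_marginals(self):
        """P_o = 0.75, P_e = 0.53125 -> kappa = 0.4667."""
        k = cohens_kappa(Y8_TRUE, Y8_PRED)
        assert k == pytest.approx(0.4667, abs=5e-5)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        p = rng.integers(0, 2, 10_000)
        assert abs(cohens_kappa(y, p)) < 0.1

    def test_agrees_with_sklearn(self, rng):
        for _ in range(200):
            n = rng.integers(4, 50)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            if len(set(y)) < 2 and len(set(p)) < 2:
                continue
            assert cohens_kappa(y, p) == pytest.approx(
                cohen_kappa_score(y, p), abs=1e-12)

    def test_degenerate_single_category(self):
        with pytest.warns(UserWarning):
            assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0
        with pytest.warns(UserWarning):
            assert cohens_kappa([0, 0, 0], [0, 0, 0]) == 1.0


class TestMcNemar:
    def test_symmetric_errors_give_unit_p(self):
        y = np.array([1, 1, 0, 0])
        a = np.array([1, 0, 0, 0])  # one error
        b = np.array([1, 1, 0, 1])  # one error, different sample
        chi2, p = mcnemar_test(y, a, b)
        assert chi2 == 0.0
        assert p == 1.0

    def test_ten_discordant_one_way(self):
        """b=10, c=0 -> chi2 = 10, p = sf(10; 1) ~ 0.00157."""
        y = np.zeros(20, int)
        a = np.zeros(20, int)
        b = np.r_[np.ones(10, int), np.zeros(10, int)]  # wrong on 10 samples
        chi2, p = mcnemar_test(y, a, b)
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(float(spstats.chi2.sf(10.0, 1)), rel=1e-12)
        assert p == pytest.approx(0.00157, abs=2e-5)

    def test_model_order_symmetry(self, rng):
        y = rng.integers(0, 2, 60)
        a = rng.integers(0, 2, 60)
        b = rng.integers(0, 2, 60)
        assert mcnemar_test(y, a, b)[0] == pytest.approx(mcnemar_test(y, b, a)[0])

    def test_no_disagreement(self):
        y = np.array([1, 0, 1])
        a = np.array([1, 0, 0])
        chi2, p = mcnemar_test(y, a, a)
        assert (chi2, p) == (0.0, 1.0)

    def test_continuity_correction(self):
        y = np.zeros(20, int)
        a = np.zeros(20, int)
        b = np.r_[np.ones(10, int), np.zeros(10, int)]
        chi2, _ = mcnemar_test(y, a, b, correction=True)
        assert chi2 == pytest.approx(81.0 / 10.0)

    def test_compare_models_counts(self):
        y = np.array([1, 1, 0, 0, 1])
        a = np.array([1, 1, 0, 0, 0])
        b = np.array([1, 0, 0, 1, 0])
        result = compare_models(y, a, b)
        assert result["b"] == 2  # A right, B wrong
        assert result["c"] == 0
        assert result["both_wrong"] == 1


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_all_tied_scores(self):
        auc, points = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_enumerated_pairs_example(self):
        """3 of 4 positive-negative pairs concordant -> AUC 0.75."""
        auc, _ = roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        _, pts = roc_auc(y, s)
        assert np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)

    def test_trapezoid_equals_rank_statistic_with_ties(self, rng):
        for _ in range(100):
            n = rng.integers(4, 40)
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            auc, _ = roc_auc(y, s)
            assert auc == pytest.approx(rank_auc(y, s), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])


class TestSplits:
    def test_holdout_sizes_and_balance(self):
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        train, test = holdout_split(y, test_fraction=0.25, group_aware=False, seed=0)
        assert len(test) == 25
        assert abs(y[test].mean() - 0.5) <= 0.06
        assert len(np.intersect1d(train, test)) == 0

    def test_group_aware_keeps_recordings_together(self):
        groups = np.repeat([f"g{i}" for i in range(10)], 10)
        y = np.repeat([0, 1] * 5, 10)
        train, test = holdout_split(y, groups, test_fraction=0.25, seed=1)
        assert set(groups[train]).isdisjoint(set(groups[test]))

    def test_holdout_seed_determinism(self):
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        a = holdout_split(y, test_fraction=0.5, group_aware=False, seed=3)
        b = holdout_split(y, test_fraction=0.5, group_aware=False, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_kfold_partition_properties(self):
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        folds = kfold_cv(y, k=5, group_aware=False, seed=0)
        assert len(folds) == 5
        all_test = np.concatenate([te for _, te in folds])
        assert len(all_test) == 100
        assert len(np.unique(all_test)) == 100
        for _, te in folds:
            assert len(te) == 20
            # stratified: per-fold positive fraction close to global 0.5
            assert abs(y[te].mean() - 0.5) < 2 / len(te)

    def test_group_kfold_each_group_tested_once(self):
        groups = np.repeat([f"g{i}" for i in range(20)], 5)
        y = np.repeat([0, 1] * 10, 5)
        folds = kfold_cv(y, groups, k=10, seed=0)
        seen = []
        for train, test in folds:
            test_groups = set(groups[test])
            assert test_groups.isdisjoint(set(groups[train]))
            seen.extend(test_groups)
        assert sorted(seen) == sorted(set(groups))

    def test_k_exceeding_group_count_rejected(self):
        groups = np.repeat(["a", "b", "c"], 4)
        y = np.tile([0, 1], 6)
        with pytest.raises(ValueError):
            kfold_cv(y, groups, k=4)

    def test_parse_scheme(self):
        assert parse_scheme("holdout:0.25") == ("holdout", 0.25)
        assert parse_scheme("cv:10") == ("cv", 10)
        with pytest.raises(ValueError):
            parse_scheme("bootstrap:3")


class TestEvaluateModel:
    @staticmethod
    def _factory():
        return make_model("xgb", ensemble_cfg=EnsembleConfig(n_estimators=10, seed=0))

    def test_separable_data_perfect_on_every_fold(self, rng):
        X = np.vstack([rng.normal(-5, 0.2, (50, 4)), rng.normal(5, 0.2, (50, 4))])
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        # voting ensemble: RF/GB midpoint split thresholds generalize the
        # wide class gap, unlike a lone histogram-binned booster
        factory = lambda: make_model(
            "voting", ensemble_cfg=EnsembleConfig(n_estimators=10, seed=0))
        report = evaluate_model(factory, X, y, scheme="cv:5", seed=0,
                                group_aware=False)
        assert len(report.splits) == 5
        assert report.mean["accuracy"] == 1.0
        assert report.mean["auc"] == 1.0

    def test_label_shuffled_data_near_chance(self, rng):
        X = rng.normal(size=(200, 6))
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        report = evaluate_model(self._factory, X, y, scheme="cv:5", seed=0,
                                group_aware=False)
        assert abs(report.mean["accuracy"] - 0.5) <= 0.1

    def test_report_fields_populated_and_in_range(self, rng):
        X = np.vstack([rng.normal(-1, 1, (40, 4)), rng.normal(1, 1, (40, 4))])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        report = evaluate_model(self._factory, X, y, scheme="holdout:0.25",
                                seed=0, group_aware=False)
        assert len(report.splits) == 1
        split = report.splits[0]
        for metric in ("accuracy", "precision", "sensitivity", "specificity",
                       "f1", "jaccard", "auc"):
            assert 0.0 <= split[metric] <= 1.0
        assert -1.0 <= split["kappa"] <= 1.0
        assert split["n_test"] == 20
        frame = report.to_frame()
        assert list(frame["split"]) == [0, "mean"]
        text = report.to_json()
        assert '"auc"' in text
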