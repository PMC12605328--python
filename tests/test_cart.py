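"""CART correctness: Gini, oracle-equivalent splits, growth rules, CV."""

import itertools

import numpy as np
import pandas as pd
import pytest

from seqqc.cart import (
    CartClassifier,
    Split,
    best_split,
    cross_validate,
    gini,
    grow,
    published_tree,
    stratified_kfold_indices,
)
from seqqc.synthetic_data import generate_rule_cohort

FEATURES = ["fovx_mm", "fovy_mm", "cnr", "fwhm_mm"]


def brute_force_best_split(X, y, min_child):
    """Independent oracle: enumerate every (feature, midpoint) pair."""
    y = np.asarray(y)
    n = y.size

    def _gini(labels):
        if labels.size == 0:
            return 0.0
        _, counts = np.unique(labels, return_counts=True)
        return 1.0 - float(np.sum((counts / labels.size) ** 2))

    parent = _gini(y)
    best = None
    for feature in X.columns:
        x = X[feature].to_numpy(float)
        uniq = sorted(set(x))
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            thr = (lo + hi) / 2.0
            left = x <= thr
            nl, nr = int(left.sum()), int((~left).sum())
            if nl < min_child or nr < min_child:
                continue
            imp = parent - (nl * _gini(y[left]) + nr * _gini(y[~left])) / n
            if best is None or imp > best[2]:
                best = (feature, thr, imp)
    return best


class TestGini:
    def test_pure_node_is_zero(self):
        assert gini(["good"] * 10) == 0.0

    def test_balanced_binary_is_half(self):
        assert gini(["good"] * 5 + ["poor"] * 5) == pytest.approx(0.5)

    def test_cohort_class_counts(self):
        # 95 good / 27 poor: 1 - (95/122)^2 - (27/122)^2
        g = gini(["good"] * 95 + ["poor"] * 27)
        assert g == pytest.approx(1 - (95 / 122) ** 2 - (27 / 122) ** 2)
        assert g == pytest.approx(0.34467, abs=1e-4)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            gini([])


class TestBestSplit:
    def test_perfectly_separable_threshold_at_midpoint(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0] * 4})
        y = np.array((["good"] * 3 + ["poor"] * 3) * 4)
        sp = best_split(X, y, min_parent=20, min_child=3)
        assert sp.threshold == pytest.approx(6.5)
        assert sp.improvement == pytest.approx(0.5)

    def test_parent_below_min_parent_returns_none(self):
        X = pd.DataFrame({"x": np.arange(19.0)})
        y = np.array(["good"] * 10 + ["poor"] * 9)
        assert best_split(X, y, min_parent=20) is None

    def test_small_improvement_gated(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.random(200)})
        y = np.array(["good"] * 100 + ["poor"] * 100)
        assert best_split(X, y, min_improvement=0.4) is None

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for trial in range(200):
            n = int(rng.integers(8, 51))
            X = pd.DataFrame(
                rng.choice(rng.normal(size=6), size=(n, 4)) + rng.normal(size=(n, 4)) * 0.1,
                columns=FEATURES,
            )
            y = rng.choice(["good", "poor"], size=n)
            sp = best_split(X, y, min_parent=4, min_child=2, min_improvement=0.0)
            oracle = brute_force_best_split(X, y, min_child=2)
            if oracle is None:
                assert sp is None
            else:
                assert sp.feature == oracle[0]
                assert sp.threshold == pytest.approx(oracle[1])
                assert sp.improvement == pytest.approx(oracle[2], abs=1e-12)

    def test_duplicate_feature_tie_broken_by_column_order(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0] * 5)
        y = np.array((["good"] * 3 + ["poor"] * 3) * 5)
        X = pd.DataFrame({"b_second": x, "a_first": x})  # order, not name, decides
        sp = best_split(X, y, min_parent=20, min_child=3)
        assert sp.feature == "b_second"


class TestGrow:
    def test_recovers_planted_two_predictor_rule(self):
        iqm, labels = generate_rule_cohort(200, seed=17)
        X = iqm[FEATURES]
        est = grow(X, labels.to_numpy())
        root = est.tree_
        assert root.feature == "fovx_mm"
        assert root.right.feature == "cnr"
        # thresholds within one inter-point gap of the planted cutoffs
        fovx = np.sort(X["fovx_mm"].to_numpy())
        lo = fovx[fovx < 150].max()
        hi = fovx[fovx >= 150].min()
        assert lo <= root.threshold <= hi
        cnr_right = np.sort(X.loc[X["fovx_mm"] > root.threshold, "cnr"].to_numpy())
        lo_c = cnr_right[cnr_right < 3.1].max()
        hi_c = cnr_right[cnr_right >= 3.1].min()
        assert lo_c <= root.right.threshold <= hi_c
        assert root.left.prediction == "poor"

    def test_labels_independent_of_features_gives_root_leaf(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.random((300, 4)), columns=FEATURES)
        y = rng.choice(["good", "poor"], size=300, p=[0.8, 0.2])
        est = grow(X, y)
        assert est.tree_.is_leaf
        assert est.tree_.prediction == "good"

    def test_constant_features_give_root_leaf(self):
        X = pd.DataFrame(np.ones((50, 4)), columns=FEATURES)
        y = np.array(["good"] * 30 + ["poor"] * 20)
        assert grow(X, y).tree_.is_leaf

    def test_growth_constraints_hold_on_trained_tree(self):
        iqm, labels = generate_rule_cohort(150, seed=23)
        est = grow(iqm[FEATURES], labels.to_numpy())
        assert est.tree_.depth() <= 2
        assert all(imp >= 0.02 for imp in est.split_improvements_)

        def _check(node):
            if node.is_leaf:
                return
            n = sum(node.counts.values())
            assert n >= 20
            for child in (node.left, node.right):
                assert sum(child.counts.values()) >= 3
                assert sum(child.counts.values()) <= n
            assert sum(node.left.counts.values()) + sum(node.right.counts.values()) == n
            _check(node.left)
            _check(node.right)

        _check(est.tree_)

    def test_monotone_feature_transform_preserves_predictions(self):
        iqm, labels = generate_rule_cohort(120, seed=31)
        X = iqm[FEATURES]
        base = grow(X, labels.to_numpy()).predict(X)
        Xt = X.copy()
        Xt["fovx_mm"] = np.exp(X["fovx_mm"] / 50.0)  # strictly increasing
        trans = grow(Xt, labels.to_numpy()).predict(Xt)
        assert (base == trans).all()

    def test_matches_sklearn_tree_on_separable_data(self):
        from sklearn.tree import DecisionTreeClassifier

        iqm, labels = generate_rule_cohort(200, seed=41)
        X = iqm[FEATURES]
        mine = grow(X, labels.to_numpy()).predict(X)
        sk = DecisionTreeClassifier(
            criterion="gini", max_depth=2, min_samples_split=20,
            min_samples_leaf=3, random_state=0,
        ).fit(X.to_numpy(), labels.to_numpy())
        theirs = sk.predict(X.to_numpy())
        assert (mine == theirs).all()


class TestPredictAndSerialize:
    def test_training_points_in_pure_leaves_predict_their_own_class(self):
        iqm, labels = generate_rule_cohort(200, seed=17)
        est = grow(iqm[FEATURES], labels.to_numpy())
        pred = est.predict(iqm[FEATURES])
        assert (pred == labels.to_numpy()).all()  # rule cohort is separable

    def test_prediction_ignores_features_outside_the_tree(self):
        est = published_tree()
        row = {"fovx_mm": 200.0, "fovy_mm": 230.0, "cnr": 4.0, "fwhm_mm": 3.0}
        a = est.predict(pd.DataFrame([row]))
        row["fovy_mm"], row["fwhm_mm"] = -1e6, 1e6
        b = est.predict(pd.DataFrame([row]))
        assert a[0] == b[0]

    def test_batch_predict_equals_per_row_predict(self):
        iqm, labels = generate_rule_cohort(60, seed=2)
        est = grow(iqm[FEATURES], labels.to_numpy(), min_parent=10)
        X = iqm[FEATURES]
        batch = est.predict(X)
        singles = [est.predict(X.iloc[[i]])[0] for i in range(len(X))]
        assert list(batch) == singles

    def test_missing_feature_is_an_error(self):
        est = published_tree()
        with pytest.raises(ValueError, match="fovx_mm|cnr"):
            est.predict(pd.DataFrame([{"cnr": 4.0}]))

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        iqm, labels = generate_rule_cohort(100, seed=13)
        est = grow(iqm[FEATURES], labels.to_numpy())
        path = tmp_path / "tree.json"
        est.to_json(path)
        loaded = CartClassifier.from_json(str(path))
        assert (loaded.predict(iqm[FEATURES]) == est.predict(iqm[FEATURES])).all()


class TestPublishedTree:
    @pytest.mark.parametrize(
        "fovx, cnr, expected",
        [
            (200.0, 4.0, "good"),   # adequate FOVx and CNR: passes QC
            (140.0, 4.5, "poor"),   # narrow FOVx despite good CNR
            (220.0, 2.5, "poor"),   # acceptable FOVx, CNR clearly below cutoff
            (150.0, 4.0, "poor"),   # boundary FOVx falls on the risk side
            (200.0, 3.147, "poor"), # boundary CNR falls on the risk side
        ],
    )
    def test_reference_cases(self, fovx, cnr, expected):
        X = pd.DataFrame([{"fovx_mm": fovx, "fovy_mm": 230.0, "cnr": cnr, "fwhm_mm": 3.0}])
        assert published_tree().predict(X)[0] == expected


class TestCrossValidation:
    def test_folds_are_stratified_and_disjoint(self):
        y = np.array(["good"] * 80 + ["poor"] * 20)
        folds = stratified_kfold_indices(y, 5, seed=3)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(100))
        for f in folds:
            assert (y[f] == "poor").sum() == 4

    def test_separable_data_with_wide_margin_scores_100(self):
        # wide class margins so every training split places its threshold
        # inside the gap and no held-out point is misplaced
        rng = np.random.default_rng(6)
        n = 200
        poor = rng.random(n) < 0.3
        fovx = np.where(poor, rng.uniform(125, 140, n), rng.uniform(180, 260, n))
        X = pd.DataFrame(
            {"fovx_mm": fovx, "fovy_mm": rng.normal(230, 20, n),
             "cnr": rng.normal(4.0, 0.5, n), "fwhm_mm": rng.normal(3.4, 0.3, n)}
        )
        y = np.where(poor, "poor", "good")
        cv = cross_validate(X, y, seed=1)
        assert cv["cv_metrics"]["accuracy_pct"] == pytest.approx(100.0)

    def test_label_permutation_drops_to_majority_rate(self):
        rng = np.random.default_rng(8)
        iqm, labels = generate_rule_cohort(200, seed=55)
        perm = rng.permutation(labels.to_numpy())
        cv = cross_validate(iqm[FEATURES], perm, seed=1)
        majority = 100.0 * max(np.mean(perm == "good"), np.mean(perm == "poor"))
        # binomial CI around the majority rate at n=200 is roughly +/- 9 points
        assert abs(cv["cv_metrics"]["accuracy_pct"] - majority) < 10.0

    def test_same_seed_reproduces_folds_and_metrics(self):
        iqm, labels = generate_rule_cohort(150, seed=3)
        a = cross_validate(iqm[FEATURES], labels.to_numpy(), seed=7)
        b = cross_validate(iqm[FEATURES], labels.to_numpy(), seed=7)
        for key in a["cv_metrics"]:
            if key == "undefined":
                assert a["cv_metrics"][key] == b["cv_metrics"][key]
            else:
                np.testing.assert_equal(a["cv_metrics"][key], b["cv_metrics"][key])
        assert a["per_fold"] == b["per_fold"]
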