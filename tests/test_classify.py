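"""Learner catalogs, expected improvement, Bayesian HPO and training."""

import numpy as np
import pytest
from scipy.stats import norm

from discslice.classify import (
    HPOConfig,
    Param,
    SoftmaxClassifier,
    bayes_optimize,
    expected_improvement,
    fc_catalog,
    get_learner,
    learner_catalog,
    make_estimator,
    predict,
    train_fc,
    train_learner,
)


def stratified_ei_estimate(mu, sigma, best, n=10 ** 5):
    """Quasi-Monte-Carlo EI oracle on a stratified normal grid."""
    z = norm.ppf((np.arange(n) + 0.5) / n)
    return float(np.mean(np.maximum(best - (mu + sigma * z), 0.0)))


class TestCatalog:
    def test_twenty_ml_learners(self):
        cat = learner_catalog()
        assert len(cat) == 20
        assert len({s.id for s in cat}) == 20

    def test_fgsvm_kernel_scale_range(self):
        space = {p.name: p for p in get_learner("FGSVM").space}
        assert (space["kernel_scale"].low, space["kernel_scale"].high) == \
            (10.0, 40.0)
        assert (space["cost"].low, space["cost"].high) == (0.001, 1000.0)

    def test_knn_neighbor_ranges(self):
        for lid, lo, hi in [("FKNN", 1, 10), ("MKNN", 10, 100),
                            ("CKNN", 100, 1000)]:
            p = {q.name: q for q in get_learner(lid).space}["n_neighbors"]
            assert (p.low, p.high) == (lo, hi)

    def test_tree_split_and_ensemble_ranges(self):
        for lid, lo, hi in [("CTREE", 4, 20), ("MTREE", 20, 100),
                            ("FTREE", 100, 1000)]:
            p = {q.name: q for q in get_learner(lid).space}["max_splits"]
            assert (p.low, p.high) == (lo, hi)
        bag = {q.name: q for q in get_learner("BAG").space}
        assert (bag["n_cycles"].low, bag["n_cycles"].high) == (10, 50)
        assert (bag["max_splits"].low, bag["max_splits"].high) == (3500, 4500)
        boost = {q.name: q for q in get_learner("BOOST").space}
        assert (boost["learning_rate"].low,
                boost["learning_rate"].high) == (0.001, 0.1)

    def test_gaussian_kernel_scale_bands(self):
        for lid, lo, hi in [("FGSVM", 10, 40), ("MGSVM", 40, 80),
                            ("CGSVM", 80, 160)]:
            p = {q.name: q for q in get_learner(lid).space}["kernel_scale"]
            assert (p.low, p.high) == (lo, hi)

    def test_three_fc_optimizers(self):
        cat = fc_catalog()
        assert [s.optimizer for s in cat] == ["SGDM", "RMSP", "ADAM"]
        for s in cat:
            assert s.fixed["max_epochs"] == 30
            assert s.fixed["validation_frequency"] == 3
            names = {p.name: p for p in s.space}
            assert (names["batch_size"].low, names["batch_size"].high) == \
                (10, 20)
            assert (names["learning_rate"].low,
                    names["learning_rate"].high) == (0.001, 0.1)
            assert (names["l2"].low, names["l2"].high) == (1e-10, 1e-2)
            assert (names["momentum"].low, names["momentum"].high) == \
                (0.8, 0.98)


class TestExpectedImprovement:
    def test_zero_uncertainty_at_incumbent(self):
        assert expected_improvement(1.0, 0.0, 1.0) == 0.0

    def test_closed_form_worked_example(self):
        assert expected_improvement(0.5, 1.0, 1.0) == \
            pytest.approx(0.6978, abs=1e-3)

    def test_hopeless_candidate_vanishes(self):
        assert expected_improvement(10.0, 1e-9, 0.0) == pytest.approx(0.0)

    def test_matches_quasi_monte_carlo(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mu = rng.uniform(-1, 1)
            sigma = rng.uniform(0.05, 1.5)
            best = rng.uniform(-1, 1)
            assert expected_improvement(mu, sigma, best) == pytest.approx(
                stratified_ei_estimate(mu, sigma, best), abs=1e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(0.0, -1.0, 0.0)


class TestBayesOptimize:
    def test_quadratic_minimum_located(self):
        space = (Param("x", "float", -5.0, 5.0),)
        best, _, hist = bayes_optimize(
            space, lambda p: (p["x"] - 1.7) ** 2,
            HPOConfig(budget=25, seed=0))
        assert abs(best["x"] - 1.7) < 0.2
        assert len(hist) == 25

    def test_constant_objective(self):
        space = (Param("x", "float", 0.0, 1.0),)
        _, val, _ = bayes_optimize(space, lambda p: 0.42,
                                   HPOConfig(budget=6, seed=1))
        assert val == 0.42

    def test_categorical_improvement_found(self):
        space = (Param("c", "cat", options=("A", "B")),)
        best, _, _ = bayes_optimize(
            space, lambda p: 0.1 if p["c"] == "B" else 0.5,
            HPOConfig(budget=8, seed=0))
        assert best["c"] == "B"

    def test_incumbent_non_increasing(self):
        space = (Param("x", "float", -3.0, 3.0),)
        _, _, hist = bayes_optimize(space, lambda p: np.sin(3 * p["x"]),
                                    HPOConfig(budget=15, seed=2))
        incumbent = np.minimum.accumulate([v for _, v in hist])
        assert np.all(np.diff(incumbent) <= 0)

    def test_failing_evaluations_penalized_not_fatal(self):
        space = (Param("x", "float", 0.0, 1.0),)

        def objective(p):
            if p["x"] < 0.5:
                raise RuntimeError("boom")
            return p["x"]

        best, val, hist = bayes_optimize(space, objective,
                                         HPOConfig(budget=10, seed=0))
        assert best["x"] >= 0.5
        assert len(hist) == 10


class TestTrainLearner:
    def test_separable_blobs_linear_svm_perfect(self, blobs_4class):
        X, y = blobs_4class
        clf = train_learner("LSVM", X, y, HPOConfig(budget=6, seed=0, folds=3))
        assert np.mean(predict(clf, X) == y) == 1.0

    def test_chosen_hyperparameters_inside_declared_space(self, blobs_4class):
        X, y = blobs_4class
        spec = get_learner("FGSVM")
        clf = train_learner(spec, X, y, HPOConfig(budget=6, seed=1, folds=3))
        declared = {p.name: p for p in spec.space}
        for name, value in clf.hyperparameters.items():
            assert declared[name].contains(value)

    def test_xor_needs_the_short_gaussian_kernel(self):
        rng = np.random.default_rng(0)
        per = 40
        quads = [(1, 1, "p"), (-1, -1, "p"), (1, -1, "n"), (-1, 1, "n")]
        X, y = [], []
        for sx, sy, lab in quads:
            pts = rng.uniform(0.1, 1.0, (per, 2)) * [sx, sy]
            X.append(pts)
            y.extend([lab] * per)
        X = np.vstack(X) * 20  # kernel scales 10-40 are "short" at this spread
        y = np.array(y)
        hpo = HPOConfig(budget=10, seed=0, folds=3)
        fg_err = min(v for _, v in train_learner("FGSVM", X, y, hpo).history)
        ls_err = min(v for _, v in train_learner("LSVM", X, y, hpo).history)
        assert 1 - fg_err >= 0.95
        assert 1 - ls_err <= 0.6

    def test_one_neighbor_knn_memorizes_training_set(self, blobs_4class):
        X, y = blobs_4class
        est = make_estimator("FKNN", {"n_neighbors": 1})
        est.fit(X, y)
        assert np.all(est.predict(X) == y)

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            train_learner("LSVM", rng.random((10, 3)), np.zeros(10),
                          HPOConfig(budget=5, seed=0))


class TestPredict:
    def test_empty_input_gives_empty_output(self, blobs_4class):
        X, y = blobs_4class
        clf = train_learner("FKNN", X, y, HPOConfig(budget=5, seed=0, folds=3))
        assert len(predict(clf, np.empty((0, X.shape[1])))) == 0

    def test_row_permutation_permutes_predictions(self, blobs_4class):
        X, y = blobs_4class
        clf = train_learner("FTREE", X, y,
                            HPOConfig(budget=5, seed=0, folds=3))
        perm = np.random.default_rng(1).permutation(len(X))
        assert np.all(predict(clf, X)[perm] == predict(clf, X[perm]))


class TestSoftmaxClassifier:
    @pytest.mark.parametrize("optimizer", ["SGDM", "RMSP", "ADAM"])
    def test_separable_blobs_trained(self, optimizer, blobs_4class):
        X, y = blobs_4class
        clf = SoftmaxClassifier(optimizer=optimizer, random_state=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95

    def test_l2_extremes_order_weight_norms(self, blobs_4class):
        X, y = blobs_4class
        hi = SoftmaxClassifier(l2=1e-2, random_state=0).fit(X, y)
        lo = SoftmaxClassifier(l2=1e-10, random_state=0).fit(X, y)
        assert hi.weight_norm_ < lo.weight_norm_

    def test_fixed_seed_identical_weights(self, blobs_4class):
        X, y = blobs_4class
        a = SoftmaxClassifier(random_state=3).fit(X, y)
        b = SoftmaxClassifier(random_state=3).fit(X, y)
        assert np.array_equal(a.coef_, b.coef_)

    def test_train_fc_end_to_end(self, blobs_4class):
        X, y = blobs_4class
        clf = train_fc("ADAM", X, y, HPOConfig(budget=5, seed=0, folds=3))
        assert np.mean(predict(clf, X) == y) >= 0.95


class TestRUSBoost:
    def test_fits_imbalanced_data(self, rng):
        X = np.vstack([rng.normal(0, 1, (8, 4)), rng.normal(4, 1, (60, 4))])
        y = np.array(["minor"] * 8 + ["major"] * 60)
        est = make_estimator("RUS", {"n_cycles": 12, "learning_rate": 0.05,
                                     "max_splits": 3500})
        est.fit(X, y)
        pred = est.predict(X)
        assert set(pred) <= {"minor", "major"}
        assert np.mean(pred == y) >= 0.9
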