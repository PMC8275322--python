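import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from rawms.classify import (
    apply_scaler,
    compute_metrics,
    default_grid,
    fit_minmax,
    grid_search,
    make_classifier,
    roc_auc,
    stratified_split,
    train_and_evaluate,
)
from rawms.errors import CVError, SplitError, ValidationError
from rawms.features import FeatureMatrix
from rawms.util import derive_seed


class TestSplit:
    def test_per_class_rounding(self):
        labels = [1] * 10 + [0] * 10
        split = stratified_split(labels, 0.3, seed=0)
        labels = np.asarray(labels)
        assert (labels[split.test_idx] == 1).sum() == 3
        assert (labels[split.test_idx] == 0).sum() == 3
        assert len(split.train_idx) + len(split.test_idx) == 20
        assert not set(split.train_idx) & set(split.test_idx)

    def test_unbalanced_rounding(self):
        labels = [1] * 7 + [0] * 13
        split = stratified_split(np.array(labels), 0.3, seed=1)
        labels = np.asarray(labels)
        assert (labels[split.test_idx] == 1).sum() == round(7 * 0.3)
        assert (labels[split.test_idx] == 0).sum() == round(13 * 0.3)

    def test_deterministic(self):
        labels = [0, 1] * 15
        a = stratified_split(labels, 0.3, seed=42)
        b = stratified_split(labels, 0.3, seed=42)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_zero_fraction_rejected(self):
        with pytest.raises(SplitError):
            stratified_split([0, 0, 1, 1], 0.0, seed=0)

    def test_tiny_class_rejected(self):
        with pytest.raises(SplitError):
            stratified_split([0, 0, 0, 1], 0.3, seed=0)


class TestMinMax:
    def test_train_column_maps_to_unit_interval(self):
        scaler = fit_minmax(np.array([[2.0], [4.0], [6.0]]))
        out = apply_scaler(scaler, np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_test_values_not_clipped(self):
        scaler = fit_minmax(np.array([[2.0], [4.0], [6.0]]))
        assert apply_scaler(scaler, np.array([[8.0]]))[0, 0] == pytest.approx(1.5)

    def test_constant_column_maps_everything_to_zero(self):
        scaler = fit_minmax(np.array([[5.0], [5.0]]))
        assert apply_scaler(scaler, np.array([[7.0]]))[0, 0] == 0.0
        assert apply_scaler(scaler, np.array([[5.0]]))[0, 0] == 0.0

    def test_scaler_ignores_test_rows(self, rng):
        """Leakage guard: scaler parameters depend only on the training rows."""
        train = rng.normal(size=(10, 4))
        scaler = fit_minmax(train)
        test = rng.normal(size=(6, 4))
        before = apply_scaler(scaler, test)
        permuted = test[rng.permutation(6)]
        after = apply_scaler(fit_minmax(train), permuted)
        np.testing.assert_array_equal(np.sort(before, axis=0), np.sort(after, axis=0))
        np.testing.assert_array_equal(scaler.minimum, fit_minmax(train).minimum)


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 0.0),
            ([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_worked_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 200))
    def test_rank_auc_equals_trapezoidal(self, seed, n):
        """Mann-Whitney AUC equals ROC trapezoid integration (sklearn)."""
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[: max(1, n // 3)]] = 1
        if labels.sum() in (0, n):
            return
        scores = np.round(rng.normal(size=n), 2)  # induces ties
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(20) + rng.uniform(0, 0.1, 20)  # tie-free
        labels = np.array([0, 1] * 10)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(
            1.0, abs=1e-12
        )


class TestMetrics:
    def test_perfect_probabilistic_classifier(self):
        m = compute_metrics([2.0, 1.0, -1.0, -2.0], [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.auc == 1.0
        assert m.accuracy == 1.0
        assert m.youden == 1.0
        assert m.brier == pytest.approx(np.mean([0.01, 0.04, 0.04, 0.01]))

    def test_probability_floor_in_log_loss(self):
        m = compute_metrics([1.0, -1.0], [1.0, 0.0], [1, 0])
        assert np.isfinite(m.log_loss)
        assert m.log_loss == pytest.approx(0.0, abs=1e-12)

    def test_youden_dominates_half_threshold(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        probs = rng.uniform(0, 1, 40)
        m = compute_metrics(probs, probs, labels)
        fixed_threshold_j = m.recall + m.specificity - 1
        assert m.youden >= fixed_threshold_j - 1e-12


class TestGridSearch:
    def separable(self, n=36, p=4, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, p)) + 8.0 * y[:, None]
        return X, y

    def test_single_point_matches_independent_fold_loop(self):
        """Mean CV AUC equals an independently coded 6-fold x 2-repeat loop."""
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 12)
        X = rng.normal(size=(24, 3)) + 0.8 * y[:, None]
        grid = [{"C": 1}]
        _, mean_auc = grid_search(X, y, "logreg", grid=grid, seed=11)

        fold_aucs = []
        k = 0
        for r in range(2):
            skf = StratifiedKFold(6, shuffle=True, random_state=derive_seed(11, f"cv-repeat-{r}"))
            for tr, va in skf.split(X, y):
                model = make_classifier("logreg", {"C": 1}, derive_seed(11, f"cv-fit-{k}"))
                model.fit(X[tr], y[tr])
                fold_aucs.append(roc_auc_score(y[va], model.decision_function(X[va])))
                k += 1
        assert mean_auc == pytest.approx(np.mean(fold_aucs), abs=1e-12)

    def test_duplicate_grid_point_first_wins(self):
        X, y = self.separable()
        grid = [{"C": 1}, {"C": 1}]
        best, _ = grid_search(X, y, "logreg", grid=grid, seed=3)
        assert best == {"C": 1}

    def test_separable_data_gives_unit_cv_auc(self):
        X, y = self.separable()
        for c in (0.1, 1, 10, 100):
            _, auc = grid_search(X, y, "logreg", grid=[{"C": c}], seed=0)
            assert auc == 1.0

    def test_small_class_raises_cv_error(self):
        y = np.array([0] * 4 + [1] * 20)
        X = np.random.default_rng(0).normal(size=(24, 2))
        with pytest.raises(CVError, match="folds"):
            grid_search(X, y, "logreg", seed=0)

    def test_declared_grids(self):
        assert default_grid("logreg") == [{"C": c} for c in (0.1, 1, 10, 100)]
        assert len(default_grid("svc")) == 12
        assert default_grid("random_forest") == [
            {"n_estimators": 100},
            {"n_estimators": 500},
        ]
        assert default_grid("gradient_boosted_trees") == [
            {"n_estimators": 100},
            {"n_estimators": 500},
        ]


class TestTrainAndEvaluate:
    def matrix(self, shift, n=60, p=6, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = rng.normal(size=(n, p)) + shift * y[:, None]
        return FeatureMatrix([f"s{i}" for i in range(n)], y, X)

    def test_separated_cohort_high_auc(self):
        result = train_and_evaluate(self.matrix(6.0), classifier="logreg", seed=1)
        assert result.metrics.auc >= 0.95
        assert result.best_params in default_grid("logreg")

    def test_null_labels_near_chance(self):
        result = train_and_evaluate(self.matrix(0.0), classifier="logreg", seed=2)
        assert 0.25 <= result.metrics.auc <= 0.75

    def test_reproducible(self):
        m = self.matrix(1.0)
        a = train_and_evaluate(m, classifier="logreg", seed=5)
        b = train_and_evaluate(m, classifier="logreg", seed=5)
        assert a.as_dict() == b.as_dict()

    @pytest.mark.parametrize("classifier", ["svc", "random_forest", "gradient_boosted_trees"])
    def test_other_classifiers_run(self, classifier):
        grid = default_grid(classifier)[:1]
        result = train_and_evaluate(
            self.matrix(6.0, n=40), classifier=classifier, grid=grid, seed=3
        )
        assert result.metrics.auc >= 0.9
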