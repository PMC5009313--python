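import itertools

import numpy as np
import pytest

from arraybsa.dfa import (
    DFAConfig,
    case_matrix,
    classify,
    fit_classification_functions,
    partial_f,
    reciprocal_cross_validate,
    stepwise_select,
    wilks_lambda,
)
from arraybsa.errors import DegenerateDataError
from arraybsa.stats import independent_t_test

Y4 = np.array(["a", "a", "b", "b"], dtype=object)


class TestWilksLambda:
    def test_equal_group_means_give_one(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        assert wilks_lambda(X, Y4, [0]) == pytest.approx(1.0)

    def test_hand_computed_single_feature(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        assert wilks_lambda(X, Y4, [0]) == pytest.approx(0.2)

    def test_zero_within_variance_distinct_means(self):
        X = np.array([[1.0], [1.0], [2.0], [2.0]])
        assert wilks_lambda(X, Y4, [0]) == pytest.approx(0.0, abs=1e-12)

    def test_empty_subset_is_one(self):
        X = np.zeros((4, 1))
        assert wilks_lambda(X, Y4, []) == 1.0

    def test_constant_feature_is_degenerate(self):
        X = np.ones((4, 1))
        with pytest.raises(DegenerateDataError):
            wilks_lambda(X, Y4, [0])


class TestPartialF:
    def test_first_entry_hand_value(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        F, p = partial_f(X, Y4, [], 0)
        assert F == pytest.approx(8.0)

    def test_single_feature_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 10)
            a = rng.normal(size=n)
            b = rng.normal(loc=rng.normal(), size=n)
            X = np.concatenate([a, b])[:, None]
            y = np.array(["a"] * n + ["b"] * n, dtype=object)
            F, _ = partial_f(X, y, [], 0)
            t = independent_t_test(a, b, variant="pooled").t
            assert F == pytest.approx(t**2, rel=1e-9)

    def test_no_between_group_effect_gives_p_near_one(self):
        # candidate with equal group means, orthogonal within groups to
        # the entered feature: its partial F is exactly zero
        strong = np.array([0.0, 1, 2, 3, 10, 11, 12, 13])
        inert = np.array([1.0, -1, -1, 1, 1, -1, -1, 1])
        X = np.column_stack([strong, inert])
        y = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        F, p = partial_f(X, y, [0], 1)
        assert F == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)


class TestStepwise:
    def test_perfect_feature_entered_first(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(24, 8))
        X[:12, 5] += 10
        y = np.array(["DN1"] * 12 + ["SD"] * 12, dtype=object)
        selected, trace = stepwise_select(X, y)
        assert selected[0] == "f5"

    def test_duplicated_feature_never_entered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        X[:10, 0] += 5
        X = np.column_stack([X, X[:, 0]])  # exact copy of a strong feature
        y = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        selected, _ = stepwise_select(X, y)
        assert "f0" in selected and "f3" not in selected

    def test_first_entry_matches_exhaustive_minimum_lambda(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, p = 16, 5
            X = rng.normal(size=(n, p))
            X[: n // 2] += rng.normal(scale=1.2, size=p)
            y = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
            selected, _ = stepwise_select(X, y)
            if not selected:
                continue
            lams = [wilks_lambda(X, y, [j]) for j in range(p)]
            assert selected[0] == f"f{int(np.argmin(lams))}"

    def test_lambda_trace_is_monotone_decreasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 10))
        X[:15, :3] += 1.5
        y = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        _, trace = stepwise_select(X, y)
        lams = [r.wilks_lambda for r in trace if r.action == "enter"]
        assert len(lams) >= 1
        assert all(l2 < l1 for l1, l2 in zip(lams, lams[1:]))

    def test_affine_rescaling_leaves_selection_unchanged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(24, 6))
        X[:12, 2] += 2
        y = np.array(["a"] * 12 + ["b"] * 12, dtype=object)
        sel0, _ = stepwise_select(X, y)
        X2 = X * np.array([1e3, 1.0, 1e-4, 7.0, 1.0, 42.0])
        sel1, _ = stepwise_select(X2, y)
        assert sel0 == sel1


class TestClassification:
    def _functions(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]])
        y = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        return X, y, fit_classification_functions(X, y)

    def test_centroid_classified_to_own_group(self):
        X, y, f = self._functions()
        mu_a = X[:3].mean(axis=0)
        assert classify(f, mu_a[None, :])[0] == "a"

    def test_midpoint_tie_goes_to_first_label(self):
        X, y, f = self._functions()
        mid = (X[:3].mean(axis=0) + X[3:].mean(axis=0)) / 2
        assert classify(f, mid[None, :])[0] == "a"

    def test_1d_boundary_at_midpoint_of_means(self):
        X = np.array([[0.0], [1.0], [2.0], [4.0], [5.0], [6.0]])
        y = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        f = fit_classification_functions(X, y)
        assert classify(f, np.array([[2.99]]))[0] == "a"
        assert classify(f, np.array([[3.01]]))[0] == "b"

    def test_matches_sklearn_lda_predictions(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 4))
        X[:20] += [1.0, 0.5, 0, 0]
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        f = fit_classification_functions(X, y)
        ours = classify(f, X)
        lda = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        np.testing.assert_array_equal(ours, lda.predict(X))

    def test_singular_pooled_covariance_raises(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        y = np.array(["a", "a", "b", "b"], dtype=object)
        with pytest.raises(DegenerateDataError):
            fit_classification_functions(X, y)


def _replicate_matrix(rng, n_features=6, shift=0.0, copy_bio=False):
    """Small two-bulk matrix with 2 bio x 3 tech replicates."""
    from arraybsa.io import FeatureAnnotation
    from conftest import make_matrix

    layout = [FeatureAnnotation(f"F{i}", "subtracted") for i in range(n_features)]
    layout.append(FeatureAnnotation("SPIKE1", "spike_in"))
    values, design = {}, {"target": [], "biological_replicate": [], "technical_replicate": []}
    base = {}
    for b in ("DN1", "SD"):
        for i in (1, 2):
            for j in (1, 2, 3):
                v = rng.normal(10, 1, n_features)
                if b == "DN1":
                    v[0] += shift
                if copy_bio and i == 2:
                    v = base[(b, j)]
                else:
                    base[(b, j)] = v
                values[f"{b}_b{i}_t{j}"] = list(v) + [50.0]
                design["target"].append(b)
                design["biological_replicate"].append(i)
                design["technical_replicate"].append(j)
    return make_matrix(values, layout, design)


class TestReciprocalValidation:
    def test_copied_biological_replicate_reproduces_training_accuracy(self):
        rng = np.random.default_rng(7)
        m = _replicate_matrix(rng, shift=6.0, copy_bio=True)
        res = reciprocal_cross_validate(m, ("DN1", "SD"))
        assert res.test_accuracy_percent == res.training_accuracy_percent

    def test_linearly_separable_training_accuracy_100(self):
        rng = np.random.default_rng(8)
        m = _replicate_matrix(rng, shift=8.0)
        res = reciprocal_cross_validate(m, ("DN1", "SD"))
        assert res.training_accuracy_percent == 100.0
        assert res.selected[0] == "F0"

    def test_case_matrix_drops_masked_features(self):
        rng = np.random.default_rng(9)
        m = _replicate_matrix(rng, shift=5.0)
        m.mask.loc["F3", "DN1_b1_t2"] = True
        X, y, bio, kept = case_matrix(m, ("DN1", "SD"), [f"F{i}" for i in range(6)])
        assert "F3" not in kept and X.shape == (12, 5)
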