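"""Kernels, one-against-one SVM voting, evaluation metrics and McNemar's
paired test."""

from math import comb

import numpy as np
import pytest
from sklearn.metrics.pairwise import chi2_kernel as sk_chi2
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

import pulmotex.classify as cl


class TestKernels:
    def test_linear_examples(self):
        assert cl.linear_kernel([1, 2, 3], [4, 5, 6]) == 32.0
        x = np.array([1.0, -2.0, 0.5])
        assert cl.linear_kernel(x, x) == pytest.approx(np.sum(x**2))
        assert cl.linear_kernel([1, 0], [0, 1]) == 0.0

    def test_chi2_examples(self):
        assert cl.chi2_kernel([0.3, 0.7], [0.3, 0.7], alpha=2.0) == 1.0
        assert cl.chi2_kernel([1, 0], [0, 1], alpha=1.0) == pytest.approx(np.exp(-2.0))
        # alpha -> 0 limit: kernel -> 1 for every pair
        assert cl.chi2_kernel([1, 0, 0], [0, 0.5, 0.5], alpha=1e-12) == pytest.approx(1.0)

    def test_chi2_zero_bin_convention_and_bounds(self, rng):
        # bins empty in both histograms contribute 0, not NaN
        assert cl.chi2_kernel([0, 1], [0, 1], alpha=1.0) == 1.0
        for _ in range(20):
            a, b = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
            v = cl.chi2_kernel(a, b, alpha=0.7)
            assert 0.0 < v <= 1.0
            assert v == cl.chi2_kernel(b, a, alpha=0.7)  # symmetry

    def test_chi2_matches_sklearn(self, rng):
        A = rng.uniform(0, 1, (5, 6))
        B = rng.uniform(0, 1, (4, 6))
        ours = np.array([[cl.chi2_kernel(a, b, alpha=0.8) for b in B] for a in A])
        np.testing.assert_allclose(ours, sk_chi2(A, B, gamma=0.8), atol=1e-12)

    def test_kernel_input_validation(self):
        with pytest.raises(ValueError, match="lengths differ"):
            cl.linear_kernel([1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="nonnegative"):
            cl.chi2_kernel([-1, 2], [1, 2])


def toy_descriptors(rng, n_per=8, n_classes=3, spread=0.05):
    centers = np.eye(n_classes) * 4.0
    X, y = [], []
    for c in range(n_classes):
        X.append(centers[c] + rng.normal(0, spread, (n_per, n_classes)))
        y += [f"class{c}"] * n_per
    return np.vstack(X), y


class TestSvm:
    def test_six_classes_give_fifteen_machines(self, rng):
        X = np.abs(rng.uniform(0.1, 1, (24, 4)))
        y = list(np.repeat(list("ABCDEF"), 4))
        model = cl.train_classifier(X, [f"c{v}" for v in y], kernel="linear", C=1.0)
        assert model.n_machines == 6 * 5 // 2

    @pytest.mark.parametrize("kernel", ["linear", "chi2"])
    def test_separable_toy_perfect_training_accuracy(self, rng, kernel):
        X, y = toy_descriptors(rng)
        X = np.abs(X)  # chi2 requires nonnegative histograms
        model = cl.train_classifier(X, y, kernel=kernel, C=100.0, alpha=1.0)
        assert cl.predict(model, X) == y

    def test_training_point_classified_as_its_class(self, rng):
        X, y = toy_descriptors(rng)
        model = cl.train_classifier(X, y, C=100.0)
        assert cl.predict(model, X[3:4]) == [y[3]]

    def test_deterministic(self, rng):
        X, y = toy_descriptors(rng, spread=1.5)
        p1 = cl.predict(cl.train_classifier(X, y, C=1.0), X)
        p2 = cl.predict(cl.train_classifier(X, y, C=1.0), X)
        assert p1 == p2

    def test_empty_predict_and_validation(self, rng):
        X, y = toy_descriptors(rng)
        model = cl.train_classifier(X, y)
        assert cl.predict(model, []) == []
        with pytest.raises(ValueError, match="at least two classes"):
            cl.train_classifier(X[:8], y[:8])
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cl.train_classifier(bad, y)
        with pytest.raises(ValueError, match="features"):
            cl.predict(model, np.zeros((2, 7)))


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = ["CON", "GGO", "NOR"] * 4
        rep = cl.evaluate(labels, labels)
        assert rep.accuracy == 1.0
        assert set(rep.sensitivity.values()) == {1.0}
        assert set(rep.specificity.values()) == {1.0}

    def test_degenerate_single_prediction(self):
        truth = ["CON"] * 5 + ["NOR"] * 5
        preds = ["CON"] * 10
        rep = cl.evaluate(preds, truth)
        assert rep.accuracy == 0.5
        assert rep.sensitivity["CON"] == 1.0 and rep.sensitivity["NOR"] == 0.0
        assert rep.specificity["CON"] == 0.0 and rep.specificity["NOR"] == 1.0

    def test_hand_built_three_class_case(self):
        # confusion: A->A 3, A->B 1 ; B->B 2, B->C 2 ; C->C 4
        truth = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        preds = ["A", "A", "A", "B", "B", "B", "C", "C", "C", "C", "C", "C"]
        rep = cl.evaluate(preds, truth)
        assert rep.accuracy == pytest.approx(9 / 12)
        assert rep.sensitivity["A"] == pytest.approx(3 / 4)
        assert rep.sensitivity["B"] == pytest.approx(2 / 4)
        assert rep.sensitivity["C"] == pytest.approx(4 / 4)
        assert rep.specificity["A"] == pytest.approx(8 / 8)
        assert rep.specificity["B"] == pytest.approx(7 / 8)
        assert rep.specificity["C"] == pytest.approx(6 / 8)
        assert rep.confusion.to_numpy().sum() == 12
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), [4, 4, 4])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cl.evaluate(["A"], ["A", "B"])


class TestMcNemar:
    def test_identical_predictions_p_one(self):
        truth = ["A", "B"] * 5
        preds = ["A", "A"] * 5
        r = cl.mcnemar_test(preds, preds, truth)
        assert r.b == r.c == 0
        assert r.p_exact == 1.0

    def test_ten_two_discordance_exact_value(self):
        truth = ["A"] * 12
        pa = ["A"] * 10 + ["B"] * 2
        pb = ["B"] * 10 + ["A"] * 2
        r = cl.mcnemar_test(pa, pb, truth)
        assert (r.b, r.c) == (10, 2)
        expected = 2 * sum(comb(12, i) for i in range(3)) / 2**12
        assert r.p_exact == pytest.approx(expected, abs=1e-12)

    def test_symmetric_discordance_p_one(self):
        truth = ["A"] * 8
        pa = ["A"] * 4 + ["B"] * 4
        pb = ["B"] * 4 + ["A"] * 4
        r = cl.mcnemar_test(pa, pb, truth)
        assert r.b == r.c == 4
        assert r.p_exact == pytest.approx(1.0)

    def test_matches_statsmodels_exact(self, rng):
        # independent oracle over random discordance tables
        for _ in range(20):
            b, c = rng.integers(0, 12, size=2)
            if b + c == 0:
                continue
            n_conc = 5
            truth = ["A"] * (b + c + n_conc)
            pa = ["A"] * b + ["B"] * c + ["A"] * n_conc
            pb = ["B"] * b + ["A"] * c + ["A"] * n_conc
            r = cl.mcnemar_test(pa, pb, truth)
            table = [[n_conc, r.b], [r.c, 0]]
            ref = sm_mcnemar(table, exact=True)
            assert r.p_exact == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cl.mcnemar_test(["A"], ["A", "B"], ["A", "B"])
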