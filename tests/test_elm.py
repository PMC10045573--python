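import numpy as np
import pytest
from scipy.special import expit

from cootseg import (
    CoaParams,
    ELMModel,
    LabeledSet,
    coa_elm_train,
    compare_coa_vs_plain,
    elm_predict,
    elm_train,
    hidden_output,
    load_model,
    save_model,
)
from cootseg.elm import _stratified_split
from cootseg.exceptions import ShapeError, StateError


class TestHiddenOutput:
    def test_zero_weights_give_half(self):
        m = ELMModel(W=np.zeros((3, 2)), b=np.zeros(3), activation="sigmoid")
        H = hidden_output(m, np.random.default_rng(0).random((5, 2)))
        np.testing.assert_allclose(H, 0.5)

    def test_single_unit_single_sample(self):
        m = ELMModel(W=np.array([[1.0]]), b=np.array([0.0]))
        np.testing.assert_allclose(hidden_output(m, np.array([[0.0]])), [[0.5]])

    def test_matches_naive_double_loop(self, rng):
        W = rng.uniform(-1, 1, (6, 3))
        b = rng.uniform(-1, 1, 6)
        X = rng.random((7, 3))
        m = ELMModel(W=W, b=b, activation="tanh")
        H = hidden_output(m, X)
        for j in range(7):
            for i in range(6):
                assert H[j, i] == pytest.approx(np.tanh(W[i] @ X[j] + b[i]), abs=1e-12)

    def test_feature_mismatch(self):
        m = ELMModel(W=np.zeros((2, 3)), b=np.zeros(2))
        with pytest.raises(ShapeError):
            hidden_output(m, np.zeros((4, 5)))


class TestTraining:
    def test_interpolation_when_L_equals_N(self, rng):
        for seed in range(10):
            g = np.random.default_rng(seed)
            X = g.random((12, 5))
            T = g.random((12, 2))
            m = elm_train(LabeledSet(X, T), L=12, seed=seed, ridge=0.0)
            H = hidden_output(m, X)
            assert np.linalg.norm(H @ m.beta - T) < 1e-6

    def test_xor_memorized(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        T = np.array([[1, 0], [0, 1], [0, 1], [1, 0]], dtype=float)
        m = elm_train(LabeledSet(X, T), L=10, seed=0, ridge=0.0)
        np.testing.assert_array_equal(elm_predict(m, X), [0, 1, 1, 0])

    def test_scalar_pseudoinverse_case(self):
        X = np.array([[2.0]])
        T = np.array([[0.8]])
        m = elm_train(LabeledSet(X, T), L=1, seed=1, ridge=0.0)
        g = expit(m.W[0, 0] * 2.0 + m.b[0])
        assert m.beta[0, 0] == pytest.approx(0.8 / g, rel=1e-10)

    def test_normal_equations_residual(self, rng):
        X = rng.random((30, 4))
        T = rng.random((30, 3))
        m = elm_train(LabeledSet(X, T), L=8, seed=2, ridge=0.0)
        H = hidden_output(m, X)
        lhs = H.T @ H @ m.beta
        rhs = H.T @ T
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-8

    def test_beta_minimizes_squared_cost(self, rng):
        X = rng.random((20, 3))
        T = rng.random((20, 1))
        m = elm_train(LabeledSet(X, T), L=5, seed=3, ridge=0.0)
        H = hidden_output(m, X)
        best = np.linalg.norm(H @ m.beta - T) ** 2
        for _ in range(100):
            other = rng.normal(size=m.beta.shape)
            assert best <= np.linalg.norm(H @ other - T) ** 2 + 1e-9


class TestPredict:
    def test_untrained_model_raises(self):
        m = ELMModel(W=np.zeros((2, 2)), b=np.zeros(2))
        with pytest.raises(StateError):
            elm_predict(m, np.zeros((1, 2)))

    def test_interpolated_training_labels_recovered(self, rng):
        X = rng.random((10, 4))
        labels = rng.integers(0, 2, 10)
        m = elm_train(LabeledSet(X, labels.astype(float)), L=10, seed=4, ridge=0.0)
        np.testing.assert_array_equal(elm_predict(m, X), labels)

    def test_binary_tie_goes_to_one(self):
        m = ELMModel(W=np.zeros((1, 1)), b=np.zeros(1), beta=np.array([[1.0]]))
        # sigmoid(0) * 1.0 = 0.5 exactly -> label 1
        assert elm_predict(m, np.array([[0.0]]))[0] == 1

    def test_row_permutation_equivariance(self, rng):
        X = rng.random((8, 3))
        m = elm_train(LabeledSet(X, rng.integers(0, 2, 8).astype(float)), L=6, seed=5)
        perm = rng.permutation(8)
        np.testing.assert_array_equal(elm_predict(m, X[perm]), elm_predict(m, X)[perm])


class TestCoaElm:
    def test_split_sizes(self):
        labels = np.array([0] * 5 + [1] * 5)
        train, val = _stratified_split(labels, 0.2, np.random.default_rng(0))
        assert len(val) == 2 and len(train) == 8
        # stratified: one validation sample per class
        assert sorted(labels[val]) == [0, 1]

    def test_zero_budget_equals_plain_elm(self, rng):
        data = LabeledSet(rng.random((20, 3)), rng.integers(0, 2, 20).astype(float))
        m1 = coa_elm_train(data, L=5, coa_params=CoaParams(iter_max=0, seed=9), seed=9)
        m2 = elm_train(data, L=5, seed=9)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_allclose(m1.beta, m2.beta)

    def test_deterministic(self, rng):
        data = LabeledSet(rng.random((24, 3)), rng.integers(0, 2, 24).astype(float))
        p = CoaParams(n_coots=8, iter_max=5, seed=1)
        m1 = coa_elm_train(data, L=4, coa_params=p, seed=1)
        m2 = coa_elm_train(data, L=4, coa_params=p, seed=1)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_paired_comparison_selection_wins(self):
        from cootseg.phantom import two_gaussian_set

        wins = 0
        for seed in range(5):
            data = two_gaussian_set(seed=seed)
            coa_acc, plain_acc = compare_coa_vs_plain(
                data, L=25, coa_params=CoaParams(n_coots=10, iter_max=8, seed=seed), seed=seed
            )
            wins += coa_acc >= plain_acc
        assert wins >= 4


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng):
        data = LabeledSet(rng.random((15, 4)), rng.integers(0, 2, 15).astype(float))
        m = elm_train(data, L=7, seed=0)
        p = tmp_path / "model.elm"
        save_model(m, p)
        back = load_model(p)
        np.testing.assert_array_equal(back.W, m.W)
        np.testing.assert_array_equal(back.beta, m.beta)
        assert back.activation == m.activation
        np.testing.assert_array_equal(elm_predict(back, data.X), elm_predict(m, data.X))
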