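import itertools

import numpy as np
import pytest

from lcmcs.anfis import ANFISRegressor, TrainConfig, bell_membership, fit_hybrid


class TestBellMembership:
    def test_unit_at_center(self):
        assert bell_membership(3.0, a=2.0, b=1.7, c=3.0) == 1.0

    @pytest.mark.parametrize("b", [0.5, 1.0, 2.0, 7.3])
    def test_half_at_center_plus_minus_a(self, b):
        assert bell_membership(5.0, 2.0, b, 3.0) == pytest.approx(0.5, abs=1e-14)
        assert bell_membership(1.0, 2.0, b, 3.0) == pytest.approx(0.5, abs=1e-14)

    def test_reference_point(self):
        # 1/(1 + 2^4) evaluated exactly
        assert bell_membership(2.0, 1.0, 2.0, 0.0) == pytest.approx(1 / 17, abs=1e-15)

    def test_positivity_constraints(self):
        with pytest.raises(ValueError):
            bell_membership(0.0, -1.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            bell_membership(0.0, 1.0, 0.0, 0.0)


class TestForward:
    def test_single_rule_is_plain_linear_function(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, -2.0, 0.5] + 4.0
        m = ANFISRegressor(mfs_per_input=1, epochs=1).fit(X, y)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)
        wbar = m.normalized_firing_strengths(X)
        np.testing.assert_allclose(wbar, 1.0, atol=1e-12)

    def test_normalized_firing_sums_to_one(self, rng):
        X = rng.normal(size=(100, 4))
        m = ANFISRegressor(epochs=1).fit(X, rng.normal(size=100))
        wbar = m.normalized_firing_strengths(rng.normal(size=(1000, 4)) * 3)
        np.testing.assert_allclose(wbar.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_unrolled_two_input_network(self):
        # 2 inputs x 2 MFs: spell out every layer of the forward pass by hand
        m = ANFISRegressor(mfs_per_input=2, epochs=1)
        X = np.array([[0.3, -0.8]])
        m.fit(np.array([[0.0, -1.0], [1.0, 1.0], [0.5, 0.0]]), np.array([1.0, 2.0, 1.5]))
        m.a_ = np.array([[1.0, 2.0], [0.5, 1.5]])
        m.b_ = np.array([[2.0, 1.0], [3.0, 2.0]])
        m.c_ = np.array([[0.0, 1.0], [-1.0, 0.5]])
        m.consequent_ = np.array(
            [[1.0, 0.0, 0.5], [0.0, 1.0, -0.5], [2.0, -1.0, 0.0], [0.5, 0.5, 1.0]]
        )
        x1, x2 = X[0]
        mu1 = [1 / (1 + ((x1 - c) / a) ** (2 * b)) for a, b, c in
               zip(m.a_[0], m.b_[0], m.c_[0])]
        mu2 = [1 / (1 + ((x2 - c) / a) ** (2 * b)) for a, b, c in
               zip(m.a_[1], m.b_[1], m.c_[1])]
        w = [mu1[i] * mu2[j] for i, j in itertools.product(range(2), repeat=2)]
        wbar = np.array(w) / sum(w)
        f = [p * x1 + q * x2 + r for p, q, r in m.consequent_]
        expected = float(np.dot(wbar, f))
        assert m.predict(X)[0] == pytest.approx(expected, abs=1e-12)

    def test_rule_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 2))
        y = X[:, 0] * X[:, 1] + rng.normal(size=30) * 0.1
        m = ANFISRegressor(epochs=5, random_state=0).fit(X, y)
        Xt = rng.normal(size=(10, 2))
        base = m.predict(Xt)
        perm = rng.permutation(m.rules_.shape[0])
        m.rules_ = m.rules_[perm]
        m.consequent_ = m.consequent_[perm]
        np.testing.assert_allclose(m.predict(Xt), base, atol=1e-12)


class TestHybridTraining:
    @pytest.mark.parametrize("jitter_seed", [0, 1, 2])
    def test_linear_target_exact_after_first_pass(self, rng, jitter_seed):
        # the key correctness handle: any linear map is inside every rule's
        # span and the normalized firings sum to one, so one LSE pass fits
        # it to machine precision whatever the premise initialization
        X = rng.normal(size=(50, 3))
        y = X @ [2.0, -1.0, 0.3] + 5.0
        m = ANFISRegressor(
            epochs=1, init_jitter=0.3, random_state=jitter_seed
        ).fit(X, y)
        rmse = np.sqrt(np.mean((m.predict(X) - y) ** 2))
        assert rmse < 1e-8 * np.std(y)

    def test_loss_trace_non_increasing(self, rng):
        X = rng.normal(size=(150, 2))
        y = X[:, 0] * X[:, 1]
        for seed in range(5):
            m = ANFISRegressor(epochs=30, random_state=seed).fit(X, y)
            diffs = np.diff(m.loss_trace_)
            assert np.all(diffs <= 1e-12)

    def test_nonlinear_target_beats_linear_fit(self, rng):
        X = rng.uniform(-1, 1, size=(150, 2))
        y = np.exp(X[:, 0]) + X[:, 1] ** 2
        m = ANFISRegressor(epochs=40, random_state=0).fit(X, y)
        Xe = np.column_stack([X, np.ones(len(X))])
        beta, *_ = np.linalg.lstsq(Xe, y, rcond=None)
        lin_rmse = np.sqrt(np.mean((Xe @ beta - y) ** 2))
        anfis_rmse = np.sqrt(np.mean((m.predict(X) - y) ** 2))
        assert anfis_rmse < 0.5 * lin_rmse

    def test_duplicated_rows_leave_model_unchanged(self, rng):
        X = rng.normal(size=(40, 2))
        y = X[:, 0] ** 2 + rng.normal(size=40) * 0.05
        m1 = ANFISRegressor(epochs=10, random_state=0).fit(X, y)
        m2 = ANFISRegressor(epochs=10, random_state=0).fit(
            np.vstack([X, X]), np.concatenate([y, y])
        )
        np.testing.assert_allclose(m1.consequent_, m2.consequent_, atol=1e-6)
        Xt = rng.normal(size=(10, 2))
        np.testing.assert_allclose(m1.predict(Xt), m2.predict(Xt), atol=1e-6)

    def test_premise_parameters_stay_positive(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.sin(X[:, 0]) + rng.normal(size=60) * 0.1
        m = ANFISRegressor(epochs=50, learning_rate=0.5, random_state=1).fit(X, y)
        assert np.all(m.a_ > 0) and np.all(m.b_ > 0)

    def test_functional_wrapper(self, rng):
        X = rng.normal(size=(30, 2))
        y = X[:, 0] + 1.0
        m = fit_hybrid(X, y, TrainConfig(epochs=2, seed=0))
        assert np.sqrt(np.mean((m.predict(X) - y) ** 2)) < 1e-8


class TestConfigValidation:
    def test_bad_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_bad_learning_rate(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1.0)
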