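import math

import numpy as np
import pytest

from dnabind import (
    BaseLearnerSpec,
    TrainingSet,
    default_registry,
    initial_weights,
    load_model,
    sample_negatives,
    save_model,
    train,
    update_weights,
    weight_factor,
)
from dnabind.ensemble import BoostingRound, EnsembleModel, build_learner


def toy_training_set(n_pos=20, n_neg=100, seed=0, shift=2.0):
    """Two Gaussian blobs in 5-D, negatives dominant."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(shift, 1.0, (n_pos, 5)), rng.normal(0.0, 1.0, (n_neg, 5))]
    )
    y = np.concatenate([np.ones(n_pos, int), -np.ones(n_neg, int)])
    return TrainingSet(X, y)


class TestWeights:
    def test_initial_uniform(self):
        np.testing.assert_allclose(initial_weights(4), [0.25] * 4)
        np.testing.assert_allclose(initial_weights(1), [1.0])
        assert initial_weights(37).sum() == pytest.approx(1.0, abs=1e-12)

    def test_initial_zero_is_error(self):
        with pytest.raises(ValueError):
            initial_weights(0)

    def test_update_no_misclassified_is_identity(self):
        w = initial_weights(5)
        np.testing.assert_allclose(update_weights(w, [], 3.0), w)

    def test_update_all_misclassified_is_identity(self):
        w = np.array([0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(update_weights(w, [0, 1, 2, 3], 7.0), w)

    def test_update_worked_case(self):
        np.testing.assert_allclose(
            update_weights(np.array([0.5, 0.5]), [0], 3.0), [0.75, 0.25]
        )

    def test_update_preserves_normalization(self):
        rng = np.random.default_rng(3)
        w = rng.dirichlet(np.ones(50))
        out = update_weights(w, rng.choice(50, 20, replace=False), 2.5)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= 0)

    def test_monotone_focus(self):
        # misclassified weight grows relative to correctly classified ones
        w = np.full(10, 0.1)
        out = update_weights(w, [2, 3], 1.8)
        ratio = out / w
        assert ratio[2] == pytest.approx(ratio[3])
        assert ratio[2] > ratio[0]


class TestWeightFactor:
    def test_fixed_point_at_half(self):
        assert weight_factor(0.5, 100) == pytest.approx(1.0, abs=1e-15)

    def test_worked_value(self):
        assert weight_factor(0.25, 100) == pytest.approx(
            math.log(300) / math.log(100), abs=1e-12
        )

    def test_sign_property(self):
        assert weight_factor(0.1, 200) > 1
        assert weight_factor(0.9, 200) < 1

    def test_clamping_keeps_factor_finite(self):
        for eps in (0.0, 1.0):
            f = weight_factor(eps, 100)
            assert math.isfinite(f)
        assert weight_factor(0.0, 100) == pytest.approx(
            weight_factor(1.0 / 200, 100)
        )

    def test_strictly_decreasing_in_eps(self):
        grid = np.linspace(0.01, 0.99, 50)
        values = [weight_factor(e, 500) for e in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_degenerate_size_is_error(self):
        with pytest.raises(ValueError):
            weight_factor(0.3, 1)


class TestSampling:
    def test_degenerate_distribution(self):
        X = np.arange(20.0).reshape(10, 2)
        w = np.zeros(10)
        w[3] = 1.0
        rows = sample_negatives(X, w, 5, seed=0)
        assert rows.shape == (5, 2)
        np.testing.assert_allclose(rows, np.tile(X[3], (5, 1)))

    def test_uniform_draws_in_range(self):
        X = np.arange(30.0).reshape(15, 2)
        rows = sample_negatives(X, initial_weights(15), 15, seed=1)
        assert rows.shape == (15, 2)
        assert set(rows[:, 0]).issubset(set(X[:, 0]))

    def test_empirical_frequencies_match_weights(self):
        rng = np.random.default_rng(11)
        w = rng.dirichlet(np.ones(8))
        X = np.arange(8.0).reshape(8, 1)
        draws = sample_negatives(X, w, 100_000, seed=11)[:, 0].astype(int)
        freq = np.bincount(draws, minlength=8) / 100_000
        se = np.sqrt(w * (1 - w) / 100_000)
        assert np.all(np.abs(freq - w) <= 3 * se + 1e-12)

    def test_zero_draws_is_error(self):
        with pytest.raises(ValueError):
            sample_negatives(np.zeros((3, 1)), initial_weights(3), 0, seed=0)


class TestRegistry:
    def test_default_roster_has_twenty_kinds(self):
        registry = default_registry()
        assert len(registry) == 20
        assert len({spec.kind for spec in registry}) == 20
        # the three nearest-neighbour variants lead the roster
        assert [s.kind for s in registry[:3]] == ["knn1", "knn5", "knn15"]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            BaseLearnerSpec("weka_j48")

    def test_every_kind_fits_and_predicts(self):
        data = toy_training_set(10, 10, seed=4)
        for spec in default_registry():
            learner = build_learner(spec, seed=0)
            learner.fit(data.X, data.y)
            pred = learner.predict(data.X)
            assert set(np.unique(pred)).issubset({-1, 1})


class TestTrain:
    def test_single_round_equals_base_learner(self):
        data = toy_training_set(seed=1)
        registry = [BaseLearnerSpec("tree_depth3")]
        model = train(data, registry=registry, rounds=1, seed=5)
        assert model.n_rounds == 1
        labels, _ = model.predict(data.X)
        np.testing.assert_array_equal(labels, model.rounds[0].learner.predict(data.X))

    def test_weight_history_shape_and_conservation(self):
        data = toy_training_set(seed=2)
        model = train(data, rounds=6, seed=3)
        assert model.weight_history.shape == (model.n_rounds + 1, data.n_negatives)
        np.testing.assert_allclose(model.weight_history.sum(axis=1), 1.0, atol=1e-9)

    def test_round_audit_quantities(self):
        data = toy_training_set(seed=2)
        model = train(data, rounds=4, seed=3)
        for r in model.rounds:
            assert 0.0 <= r.eps <= 1.0
            assert math.isfinite(r.factor) and r.factor > 0
            assert 0.0 <= r.alpha <= 10.0

    def test_determinism_bitwise(self):
        data = toy_training_set(seed=6)
        a = train(data, rounds=5, seed=42)
        b = train(data, rounds=5, seed=42)
        assert np.array_equal(a.weight_history, b.weight_history)
        la, sa = a.predict(data.X)
        lb, sb = b.predict(data.X)
        assert np.array_equal(la, lb) and np.array_equal(sa, sb)

    def test_different_seed_changes_history(self):
        data = toy_training_set(seed=6)
        a = train(data, rounds=5, seed=1)
        b = train(data, rounds=5, seed=2)
        assert not np.array_equal(a.weight_history, b.weight_history)

    def test_single_class_is_error(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="both classes"):
            train(TrainingSet(X, np.ones(5, int)))

    def test_registry_cycles_in_order(self):
        data = toy_training_set(seed=7)
        registry = [BaseLearnerSpec("stump"), BaseLearnerSpec("gaussian_nb")]
        model = train(data, registry=registry, rounds=5, seed=0)
        assert [r.kind for r in model.rounds] == [
            "stump", "gaussian_nb", "stump", "gaussian_nb", "stump",
        ]


class TestPredict:
    def _manual_model(self, alphas, votes):
        class Fixed:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.full(len(X), self.label)

        rounds = [
            BoostingRound(Fixed(v), "fixed", a, 0.5, 1.0, 0.5)
            for a, v in zip(alphas, votes)
        ]
        return EnsembleModel(rounds, np.ones((1, 1)), n_features=2)

    def test_exact_tie_goes_negative(self):
        model = self._manual_model([2.0, 1.0, 1.0], [1, -1, -1])
        labels, scores = model.predict(np.zeros((1, 2)))
        assert scores[0] == 0.0 and labels[0] == -1

    def test_unanimous_vote(self):
        model = self._manual_model([1.0, 2.0], [1, 1])
        labels, scores = model.predict(np.zeros((3, 2)))
        assert np.all(labels == 1) and np.allclose(scores, 1.0)

    def test_all_zero_alphas_fall_back_to_uniform(self):
        model = self._manual_model([0.0, 0.0, 0.0], [1, 1, -1])
        labels, scores = model.predict(np.zeros((1, 2)))
        assert labels[0] == 1 and scores[0] == pytest.approx(1 / 3)

    def test_dimension_mismatch_names_sizes(self):
        model = self._manual_model([1.0], [1])
        with pytest.raises(ValueError, match="expects 2, got 3"):
            model.predict(np.zeros((1, 3)))


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        data = toy_training_set(seed=8)
        model = train(data, rounds=3, seed=9)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.n_rounds == model.n_rounds
        np.testing.assert_array_equal(loaded.weight_history, model.weight_history)
        la, sa = loaded.predict(data.X)
        lb, sb = model.predict(data.X)
        assert np.array_equal(la, lb) and np.array_equal(sa, sb)

    def test_load_rejects_foreign_file(self, tmp_path):
        import joblib

        path = tmp_path / "other.joblib"
        joblib.dump({"something": 1}, path)
        with pytest.raises(ValueError, match="model archive"):
            load_model(path)
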