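"""GA-BP classifier: coding, forward pass, evolution, training, persistence."""

import numpy as np
import pytest

from enose import gabp
from enose.gabp import (
    BpConfig,
    Chromosome,
    GaConfig,
    NetworkParams,
    NetworkSpec,
    chromosome_length,
    decode,
    encode,
    evolve,
    fit_gabp,
    fitness,
    forward,
    predict,
    train_bp,
)


def naive_forward(params, X):
    """Independent loop-based oracle for the network forward pass."""

    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    w1, b1, w2, b2 = params
    out = np.zeros((len(X), len(b2)))
    for r, x in enumerate(X):
        hidden = [sig(sum(w1[h][i] * x[i] for i in range(len(x))) + b1[h])
                  for h in range(len(b1))]
        for o in range(len(b2)):
            out[r, o] = sig(sum(w2[o][h] * hidden[h] for h in range(len(hidden))) + b2[o])
    return out


def random_params(spec, rng):
    return NetworkParams(
        rng.normal(size=(spec.n_hidden, spec.n_input)),
        rng.normal(size=spec.n_hidden),
        rng.normal(size=(spec.n_output, spec.n_hidden)),
        rng.normal(size=spec.n_output),
    )


class TestCoding:
    def test_chromosome_length_formula(self, toy_spec):
        assert chromosome_length(toy_spec) == 2 * 5 + 5 + 5 * 3 + 3

    def test_encode_decode_round_trip(self, toy_spec):
        params = random_params(toy_spec, np.random.default_rng(0))
        rebuilt = decode(encode(params, toy_spec), toy_spec)
        for a, b in zip(params, rebuilt):
            np.testing.assert_array_equal(a, b)

    def test_zero_chromosome_decodes_to_zero_parameters(self, toy_spec):
        params = decode(np.zeros(chromosome_length(toy_spec)), toy_spec)
        for a in params:
            assert not a.any()

    def test_short_chromosome_rejected(self, toy_spec):
        with pytest.raises(ValueError, match="genes"):
            decode(np.zeros(chromosome_length(toy_spec) - 1), toy_spec)

    def test_mismatched_parameter_shapes_rejected(self, toy_spec):
        params = random_params(NetworkSpec(n_input=3, n_hidden=5, n_output=3),
                               np.random.default_rng(1))
        with pytest.raises(ValueError, match="shapes"):
            encode(params, toy_spec)


class TestForwardAndFitness:
    def test_forward_matches_naive_loop_oracle(self):
        spec = NetworkSpec(n_input=3, n_hidden=4, n_output=3)
        rng = np.random.default_rng(2)
        params = random_params(spec, rng)
        X = rng.normal(size=(7, 3))
        np.testing.assert_allclose(forward(params, X), naive_forward(params, X), atol=1e-10)

    def test_saturated_network_reaching_targets_has_fitness_one(self):
        # huge biases saturate the sigmoids to exact 0/1 in float64
        spec = NetworkSpec(n_input=1, n_hidden=1, n_output=3)
        params = NetworkParams(
            np.zeros((1, 1)), np.zeros(1),
            np.zeros((3, 1)), np.array([60.0, -60.0, -60.0]),
        )
        X = np.zeros((4, 1))
        y = np.ones(4, dtype=int)
        assert fitness(encode(params, spec), X, y, spec) == 1.0

    def test_fitness_matches_hand_computed_sse(self, toy_spec):
        rng = np.random.default_rng(3)
        params = random_params(toy_spec, rng)
        X = rng.normal(size=(4, 2))
        y = np.array([1, 2, 3, 1])
        out = naive_forward(params, X)
        targets = np.eye(3)[y - 1]
        expected = 1.0 / (1.0 + ((out - targets) ** 2).sum())
        assert fitness(encode(params, toy_spec), X, y, toy_spec) == pytest.approx(
            expected, rel=1e-12
        )

    def test_fitness_in_unit_interval(self, toy_spec):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 2))
        y = rng.integers(1, 4, size=10)
        for _ in range(10):
            f = fitness(rng.uniform(-1, 1, chromosome_length(toy_spec)), X, y, toy_spec)
            assert 0.0 < f <= 1.0

    def test_empty_training_set_rejected(self, toy_spec):
        with pytest.raises(ValueError, match="empty"):
            fitness(np.zeros(chromosome_length(toy_spec)), np.zeros((0, 2)), np.array([]), toy_spec)


class TestEvolve:
    def test_best_fitness_trace_nondecreasing(self, blob_data, quick_ga):
        X, y = blob_data
        spec = NetworkSpec(n_input=2, n_hidden=4)
        for seed in (0, 1, 2):
            result = evolve(GaConfig(**{**quick_ga.__dict__, "seed": seed}), spec, X, y)
            assert (np.diff(result.best_fitness_trace) >= 0).all()

    def test_deterministic_under_seed(self, blob_data, quick_ga):
        X, y = blob_data
        spec = NetworkSpec(n_input=2, n_hidden=4)
        a = evolve(quick_ga, spec, X, y)
        b = evolve(quick_ga, spec, X, y)
        np.testing.assert_array_equal(a.best.genes, b.best.genes)
        assert a.best.fitness == b.best.fitness

    def test_no_variation_operators_preserve_initial_best(self, blob_data):
        X, y = blob_data
        spec = NetworkSpec(n_input=2, n_hidden=4)
        config = GaConfig(population_size=10, generations=10, crossover_prob=0.0,
                          mutation_prob=0.0, seed=6)
        result = evolve(config, spec, X, y)
        # reproduce the initial population with the same generator stream
        rng = np.random.default_rng(6)
        pop = rng.uniform(-1, 1, size=(10, chromosome_length(spec)))
        initial_best = max(fitness(ind, X, y, spec) for ind in pop)
        assert result.best.fitness == pytest.approx(initial_best, rel=1e-15)

    def test_beats_random_search_baseline_on_separable_toy(self, blob_data):
        X, y = blob_data
        spec = NetworkSpec(n_input=2, n_hidden=4)
        result = evolve(GaConfig(population_size=30, generations=40, seed=0), spec, X, y)
        rng = np.random.default_rng(99)
        random_fits = [
            fitness(rng.uniform(-1, 1, chromosome_length(spec)), X, y, spec)
            for _ in range(1000)
        ]
        assert result.best.fitness > np.mean(random_fits)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="gene_bounds"):
            GaConfig(gene_bounds=(1.0, -1.0))


class TestTrainBp:
    def test_zero_epochs_returns_initials(self, blob_data, toy_spec):
        X, y = blob_data
        init = random_params(toy_spec, np.random.default_rng(5))
        params, losses = train_bp(init, toy_spec, X, y, epochs=0)
        for a, b in zip(params, init):
            np.testing.assert_array_equal(a, b)
        assert len(losses) == 1

    def test_loss_trace_final_not_above_initial(self, blob_data, toy_spec):
        X, y = blob_data
        init = random_params(toy_spec, np.random.default_rng(6))
        _, losses = train_bp(init, toy_spec, X, y, learning_rate=0.01, epochs=300)
        assert losses[-1] <= losses[0]

    def test_plain_gradient_descent_strictly_descends_at_small_rate(self, blob_data, toy_spec):
        X, y = blob_data
        init = random_params(toy_spec, np.random.default_rng(7))
        _, losses = train_bp(init, toy_spec, X, y, epochs=50,
                             bp_config=BpConfig(learning_rate=0.001, epochs=50, adaptive=False))
        assert losses[-1] < losses[0]

    def test_separable_three_class_toy_trains_to_perfect_accuracy(self, blob_data):
        X, y = blob_data
        spec = NetworkSpec(n_input=2, n_hidden=6)
        ga = evolve(GaConfig(population_size=20, generations=20, seed=1), spec, X, y)
        params, _ = train_bp(decode(ga.best, spec), spec, X, y,
                             learning_rate=0.01, epochs=2000)
        assert (predict(params, spec, X) == y).mean() == 1.0

    def test_nonpositive_learning_rate_rejected(self, blob_data, toy_spec):
        init = random_params(toy_spec, np.random.default_rng(8))
        with pytest.raises(ValueError, match="learning_rate"):
            train_bp(init, toy_spec, *blob_data, learning_rate=0.0)


class TestPredict:
    def test_argmax_maps_to_grades(self):
        spec = NetworkSpec(n_input=1, n_hidden=1, n_output=3)
        params = NetworkParams(
            np.zeros((1, 1)), np.zeros(1), np.zeros((3, 1)),
            np.array([2.0, -2.0, -2.0]),
        )
        assert predict(params, spec, np.zeros((1, 1)))[0] == 1

    def test_exact_tie_broken_toward_lower_grade(self):
        spec = NetworkSpec(n_input=1, n_hidden=1, n_output=3)
        params = NetworkParams(
            np.zeros((1, 1)), np.zeros(1), np.zeros((3, 1)),
            np.array([1.0, 1.0, -1.0]),  # units 1 and 2 tie exactly
        )
        assert predict(params, spec, np.zeros((1, 1)))[0] == 1

    def test_predictions_match_forward_oracle(self, blob_data):
        X, _ = blob_data
        spec = NetworkSpec(n_input=2, n_hidden=3)
        params = random_params(spec, np.random.default_rng(9))
        expected = naive_forward(params, X).argmax(axis=1) + 1
        np.testing.assert_array_equal(predict(params, spec, X), expected)

    def test_dimension_mismatch_rejected(self, toy_spec):
        params = random_params(toy_spec, np.random.default_rng(10))
        with pytest.raises(ValueError, match="features"):
            predict(params, toy_spec, np.zeros((2, 3)))


class TestFitGabp:
    def test_model_round_trip_preserves_predictions(self, tmp_path, blob_data, quick_ga):
        X, y = blob_data
        model = fit_gabp(X, y, quick_ga, NetworkSpec(n_input=2, n_hidden=4),
                         BpConfig(epochs=200))
        gabp.save_model(model, tmp_path / "model.txt")
        loaded = gabp.load_model(tmp_path / "model.txt")
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))

    def test_refit_with_same_seeds_is_identical(self, blob_data, quick_ga):
        X, y = blob_data
        kwargs = dict(ga_config=quick_ga, spec=NetworkSpec(n_input=2, n_hidden=4),
                      bp_config=BpConfig(epochs=200))
        a = fit_gabp(X, y, **kwargs)
        b = fit_gabp(X, y, **kwargs)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa, pb)

    def test_ga_initialization_starts_training_at_lower_loss(self, blob_data):
        """Paired-seed comparison: the evolved chromosome hands
        backpropagation a lower starting loss than a random draw from the
        same gene bounds."""
        X, y = blob_data
        spec = NetworkSpec(n_input=2, n_hidden=4)
        wins = 0
        for seed in range(10):
            ga = evolve(GaConfig(population_size=20, generations=15, seed=seed), spec, X, y)
            _, ga_losses = train_bp(decode(ga.best, spec), spec, X, y, epochs=0)
            rng = np.random.default_rng(1000 + seed)
            random_init = decode(rng.uniform(-1, 1, chromosome_length(spec)), spec)
            _, rnd_losses = train_bp(random_init, spec, X, y, epochs=0)
            wins += ga_losses[0] <= rnd_losses[0]
        assert wins >= 9

    def test_label_outside_grades_rejected(self, blob_data, quick_ga):
        X, y = blob_data
        with pytest.raises(ValueError, match="grades"):
            fit_gabp(X, np.where(y == 3, 4, y), quick_ga,
                     NetworkSpec(n_input=2, n_hidden=4), BpConfig(epochs=10))
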