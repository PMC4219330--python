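"""Stage-one SVM sets, stacking primitives and the stage-two perceptron."""

import math

import numpy as np
import pytest

from exposloc.curation import CLASS_ORDER
from exposloc.features import SPEC_A, SPEC_C, CompositionFeaturizer
from exposloc.models import (
    COARSE_C_GRID,
    COARSE_GAMMA_GRID,
    ExposureSVMSet,
    SigmoidMLP,
    ann_forward,
    build_stack_input,
    count_connections,
    optimize_ann,
    split_stack_input,
    train_ann,
    winner_takes_all,
)
from exposloc.synthetic import GeneratorConfig, generate_corpus


def corpus_arrays(seed=3, n=40, delta=0.8):
    corpus = generate_corpus(GeneratorConfig(seed=seed, n_per_class=n, delta=delta))
    X = CompositionFeaturizer().transform(corpus.profiles)
    return X, np.asarray(corpus.labels)


class TestWinnerTakesAll:
    def test_simple_maximum(self):
        assert winner_takes_all({"N": 0.2, "Y": 0.1, "C": 0.6, "E": 0.1}) == ("C", 0.6)

    def test_tie_breaks_by_class_order(self):
        assert winner_takes_all({"N": 0.5, "Y": 0.5, "C": 0.1, "E": 0.1}) == ("N", 0.5)

    def test_global_maximum_across_vectors(self):
        a = {"N": 0.2, "Y": 0.3, "C": 0.1, "E": 0.1}
        b = {"N": 0.1, "Y": 0.2, "C": 0.9, "E": 0.0}
        assert winner_takes_all([a, b]) == ("C", 0.9)

    def test_agrees_with_argmax_oracle(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 4))
            mat = rng.uniform(0, 1, size=(k, 4))
            cls, score = winner_takes_all(mat)
            assert score == mat.max()
            assert cls == CLASS_ORDER[int(np.argmax(mat.max(axis=0)))]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            winner_takes_all([])


class TestStackInput:
    def test_zeros(self):
        z = (0.0,) * 4
        assert np.array_equal(build_stack_input(z, z, z), np.zeros(12))

    def test_layout_contract(self):
        a = {"N": 0.1, "Y": 0.2, "C": 0.3, "E": 0.4}
        b = {"N": 0.5, "Y": 0.6, "C": 0.7, "E": 0.8}
        c = {"N": 0.9, "Y": 0.1, "C": 0.2, "E": 0.3}
        x = build_stack_input(a, b, c)
        assert x[5] == 0.6  # component 5 is set B's Y score
        assert x[0] == 0.1 and x[8] == 0.9

    def test_round_trip(self, rng):
        a, b, c = rng.uniform(0, 1, (3, 4))
        x = build_stack_input(a, b, c)
        ra, rb, rc = split_stack_input(x)
        assert np.array_equal(np.concatenate([ra, rb, rc]), x)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            build_stack_input((0, 0, 0, 1.5), (0,) * 4, (0,) * 4)


class TestAnnForward:
    def _toy(self, W1, b1, W2, b2):
        mlp = SigmoidMLP()
        mlp.coefs_ = [np.asarray(W1, float), np.asarray(W2, float)]
        mlp.intercepts_ = [np.asarray(b1, float), np.asarray(b2, float)]
        return mlp

    def test_zero_weights_give_half(self):
        mlp = self._toy(np.zeros((12, 3)), np.zeros(3), np.zeros((3, 4)), np.zeros(4))
        np.testing.assert_allclose(ann_forward(mlp, np.zeros(12)), [0.5] * 4)

    def test_hand_computed_two_two_two(self):
        # 2-2-2 network, worked through by hand with math.exp
        mlp = self._toy([[1.0, -1.0], [0.5, 0.25]], [0.1, -0.2],
                        [[2.0, 0.0], [-1.0, 1.0]], [0.0, 0.5])
        x = np.array([1.0, 2.0])

        def sig(z):
            return 1.0 / (1.0 + math.exp(-z))

        h1 = sig(1.0 * 1.0 + 0.5 * 2.0 + 0.1)
        h2 = sig(-1.0 * 1.0 + 0.25 * 2.0 - 0.2)
        expected = [sig(2.0 * h1 - 1.0 * h2), sig(0.0 * h1 + 1.0 * h2 + 0.5)]
        np.testing.assert_allclose(ann_forward(mlp, x), expected, rtol=1e-12)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        mlp = self._toy(rng.normal(size=(12, 5)), rng.normal(size=5),
                        rng.normal(size=(5, 4)), rng.normal(size=4))
        out = ann_forward(mlp, rng.uniform(0, 1, (20, 12)))
        assert np.all(out > 0) and np.all(out < 1)

    def test_dimension_mismatch_rejected(self):
        mlp = self._toy(np.zeros((12, 2)), np.zeros(2), np.zeros((2, 4)), np.zeros(4))
        with pytest.raises(ValueError):
            ann_forward(mlp, np.zeros(5))


class TestCountConnections:
    @pytest.mark.parametrize("sizes,expected", [
        ((12, 28, 4), 448),
        ((4, 1, 4), 8),
        ((16, 28, 4), 560),
        ((12, 4), 48),
    ])
    def test_arithmetic(self, sizes, expected):
        assert count_connections(sizes) == expected

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            count_connections((12,))

    def test_matches_stored_weight_count(self, rng):
        X = rng.uniform(0, 1, (40, 12))
        y = np.array(list(CLASS_ORDER) * 10)
        mlp = SigmoidMLP(hidden=6, max_epochs=5, random_state=0).fit(X, y)
        assert mlp.n_connections_ == count_connections((12, 6, 4))


class TestSigmoidMLP:
    def separable_data(self, rng, n=200):
        # each class concentrates its own stack components near 1
        y = np.array([CLASS_ORDER[i % 4] for i in range(n)])
        X = rng.uniform(0, 0.2, (n, 12))
        for i, cls in enumerate(y):
            j = CLASS_ORDER.index(cls)
            X[i, [j, 4 + j, 8 + j]] = rng.uniform(0.8, 1.0, 3)
        return X, y

    def test_learns_separable_inputs(self, rng):
        X, y = self.separable_data(rng)
        mlp = train_ann(X, y, hidden=28, seed=0)
        assert np.mean(mlp.predict(X) == y) >= 0.95

    def test_identical_seed_identical_weights(self, rng):
        X, y = self.separable_data(rng, n=80)
        m1 = SigmoidMLP(hidden=8, max_epochs=200, random_state=42).fit(X, y)
        m2 = SigmoidMLP(hidden=8, max_epochs=200, random_state=42).fit(X, y)
        for w1, w2 in zip(m1.coefs_ + m1.intercepts_, m2.coefs_ + m2.intercepts_):
            np.testing.assert_array_equal(w1, w2)

    def test_degenerate_one_example_per_class(self):
        X = np.eye(4).repeat(3, axis=1)  # one distinctive input per class
        y = np.array(CLASS_ORDER)
        mlp = SigmoidMLP(hidden=8, max_epochs=2000, random_state=1).fit(X, y)
        assert list(mlp.predict(X)) == list(CLASS_ORDER)

    def test_unknown_label_rejected(self, rng):
        with pytest.raises(ValueError):
            SigmoidMLP().fit(rng.uniform(size=(4, 12)), np.array(["N", "Q", "C", "E"]))

    def test_probabilities_are_raw_sigmoids(self, rng):
        X, y = self.separable_data(rng, n=80)
        mlp = SigmoidMLP(hidden=8, max_epochs=300, random_state=0).fit(X, y)
        P = mlp.predict_proba(X)
        assert np.all((P > 0) & (P < 1))
        assert not np.allclose(P.sum(axis=1), 1.0)  # independent activations


class TestExposureSVMSet:
    def test_strong_signal_high_cv_accuracy(self):
        X, y = corpus_arrays(seed=3, n=40)
        svm = ExposureSVMSet(spec=SPEC_A, C_grid=COARSE_C_GRID,
                             gamma_grid=COARSE_GAMMA_GRID, cv=5,
                             random_state=0).fit(X, y)
        assert all(acc >= 0.90 for acc in svm.cv_accuracy_.values())
        P = svm.predict_proba(X)
        assert P.shape == (len(y), 4)
        assert np.all((P >= 0) & (P <= 1))

    def test_shuffled_labels_give_chance_cv_accuracy(self, rng):
        X, y = corpus_arrays(seed=4, n=150, delta=0.0)
        y = rng.permutation(y)
        svm = ExposureSVMSet(spec=SPEC_C, C_grid=COARSE_C_GRID,
                             gamma_grid=COARSE_GAMMA_GRID, cv=10,
                             random_state=1).fit(X, y)
        for acc in svm.cv_accuracy_.values():
            assert 0.40 <= acc <= 0.60  # balanced binary chance

    def test_deterministic_given_seed(self):
        X, y = corpus_arrays(seed=5, n=30)
        kw = dict(spec=SPEC_A, C_grid=COARSE_C_GRID, gamma_grid=COARSE_GAMMA_GRID,
                  cv=5, random_state=9)
        s1 = ExposureSVMSet(**kw).fit(X, y)
        s2 = ExposureSVMSet(**kw).fit(X, y)
        assert s1.best_params_ == s2.best_params_
        assert s1.cv_accuracy_ == s2.cv_accuracy_
        np.testing.assert_array_equal(s1.predict_proba(X[:10]),
                                      s2.predict_proba(X[:10]))

    def test_scores_peak_for_true_class(self):
        X, y = corpus_arrays(seed=6, n=40)
        svm = ExposureSVMSet(spec=SPEC_A, C_grid=COARSE_C_GRID,
                             gamma_grid=COARSE_GAMMA_GRID, cv=5,
                             random_state=0).fit(X, y)
        pred = svm.predict(X)
        assert np.mean(pred == y) >= 0.8

    def test_too_few_examples_for_folds(self):
        X, y = corpus_arrays(seed=7, n=6)
        with pytest.raises(ValueError, match="folds"):
            ExposureSVMSet(cv=10, C_grid=COARSE_C_GRID,
                           gamma_grid=COARSE_GAMMA_GRID).fit(X, y)


class TestOptimizeAnn:
    def make_inputs(self, rng, n=120):
        y = np.array([CLASS_ORDER[i % 4] for i in range(n)])
        full = rng.uniform(0, 0.3, (n, 12))
        for i, cls in enumerate(y):
            j = CLASS_ORDER.index(cls)
            full[i, j] += 0.6                      # set A alone is informative
            full[i, 4 + j] += rng.uniform(0, 0.3)  # sets B, C weakly so
        return {"A": full[:, :4], "A|B|C": full}, y

    def test_single_candidate_returned(self, rng):
        inputs, y = self.make_inputs(rng)
        best, sweep = optimize_ann({"A": inputs["A"]}, y, hidden_sizes=[4],
                                   cv_folds=3, seed=0, max_epochs=100)
        assert best["combo"] == "A" and best["hidden"] == 4
        assert len(sweep) == 1

    def test_sweep_table_covers_grid_and_stack_dominates(self, rng):
        inputs, y = self.make_inputs(rng)
        best, sweep = optimize_ann(inputs, y, hidden_sizes=[4, 8], cv_folds=3,
                                   seed=0, max_epochs=2000, weight_decay=1e-3)
        assert len(sweep) == 4  # |combos| x |hidden sizes|
        acc = sweep.groupby("combo")["accuracy"].max()
        assert acc["A|B|C"] >= acc["A"] - 0.05  # stacking does not hurt

    def test_tie_goes_to_smaller_architecture(self, rng):
        X = np.zeros((40, 4))  # no signal: all candidates tie at chance-ish
        y = np.array([CLASS_ORDER[i % 4] for i in range(40)])
        best, sweep = optimize_ann({"Z": X}, y, hidden_sizes=[16, 2], cv_folds=2,
                                   seed=0, max_epochs=10)
        ties = sweep[sweep.accuracy == sweep.accuracy.max()]
        assert best["hidden"] == int(ties["hidden"].min())
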