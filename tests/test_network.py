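import numpy as np
import pytest

from celltics.hierarchy import MaskStack
from celltics.network import (
    ModelParams,
    TrainingConfig,
    forward,
    grid_search_cv,
    init_model,
    predict,
    train,
    vote,
)


def _random_masks(rng, sizes=(6, 4, 3)):
    """Random mask stack (genes=sizes[0]) with every column non-empty."""
    masks, rows, cols = [], [], []
    layers = [[f"n{k}_{i}" for i in range(s)] for k, s in enumerate(sizes)]
    for a, b in zip(layers[:-1], layers[1:]):
        m = (rng.random((len(a), len(b))) < 0.6).astype(np.uint8)
        for j in range(m.shape[1]):
            if m[:, j].sum() == 0:
                m[int(rng.integers(len(a))), j] = 1
        masks.append(m)
        rows.append(a)
        cols.append(b)
    return MaskStack(masks=masks, row_ids=rows, col_ids=cols)


def _zero_params(masks, classes):
    return ModelParams(
        weights=[np.zeros(m.shape) for m in masks.masks],
        biases=[np.zeros(m.shape[1]) for m in masks.masks],
        head_weights=[np.zeros((m.shape[1], len(classes))) for m in masks.masks],
        head_biases=[np.zeros(len(classes)) for m in masks.masks],
        classes=list(classes),
    )


class TestInit:
    def test_deterministic_under_seed(self, rng):
        masks = _random_masks(rng)
        a = init_model(masks, ["A", "B"], seed=7)
        b = init_model(masks, ["A", "B"], seed=7)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_masked_entries_zero_and_shapes_match(self, rng):
        masks = _random_masks(rng)
        p = init_model(masks, ["A", "B", "C"], seed=0)
        for w, m in zip(p.weights, masks.masks):
            assert w.shape == m.shape
            assert (w[m == 0] == 0).all()
            assert (w[m == 1] != 0).all()
        assert all(hw.shape[1] == 3 for hw in p.head_weights)

    def test_fewer_than_two_classes_rejected(self, rng):
        with pytest.raises(ValueError):
            init_model(_random_masks(rng), ["only"], seed=0)


class TestForward:
    def test_zero_network_gives_uniform_heads(self, rng):
        masks = _random_masks(rng)
        p = _zero_params(masks, ["A", "B", "C", "D"])
        res = forward(p, masks, rng.random((5, 6)))
        for act in res.activations:
            assert (act == 0).all()
        for prob in res.probabilities:
            np.testing.assert_allclose(prob, 0.25)

    def test_single_unit_closed_form(self):
        masks = MaskStack(masks=[np.ones((1, 1), dtype=np.uint8)],
                          row_ids=[["g"]], col_ids=[["p"]])
        p = _zero_params(masks, ["A", "B"])
        p.weights[0][0, 0] = 1.0
        res = forward(p, masks, np.array([[1.0]]))
        assert res.activations[0][0, 0] == pytest.approx(np.tanh(1.0), abs=1e-5)
        np.testing.assert_allclose(res.probabilities[0][0], [0.5, 0.5], atol=1e-9)

    def test_equals_dense_oracle_with_premasked_weights(self, rng):
        masks = _random_masks(rng)
        p = init_model(masks, ["A", "B"], seed=1)
        for w in p.weights:  # perturb including masked entries
            w += rng.normal(0, 0.1, w.shape)
        for hw in p.head_weights:
            hw += rng.normal(0, 0.5, hw.shape)
        X = rng.normal(size=(8, 6))
        res = forward(p, masks, X)
        h = X
        for m, w, b, hw, hb, act, prob in zip(
            masks.masks, p.weights, p.biases, p.head_weights, p.head_biases,
            res.activations, res.probabilities,
        ):
            h = np.tanh(h @ (m * w) + b)  # dense layer with pre-masked weights
            np.testing.assert_allclose(act, h, atol=1e-6)
            z = h @ hw + hb
            e = np.exp(z - z.max(axis=1, keepdims=True))
            np.testing.assert_allclose(prob, e / e.sum(axis=1, keepdims=True), atol=1e-6)
            np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-9)

    def test_cell_permutation_equivariance(self, rng):
        masks = _random_masks(rng)
        p = init_model(masks, ["A", "B"], seed=3)
        X = rng.normal(size=(10, 6))
        perm = rng.permutation(10)
        res = predict(p, masks, X)
        res_p = predict(p, masks, X[perm])
        np.testing.assert_array_equal(res.voted[perm], res_p.voted)
        for a, b in zip(res.probabilities, res_p.probabilities):
            np.testing.assert_allclose(a[perm], b, atol=1e-12)

    def test_shape_mismatch_names_layer(self, rng):
        masks = _random_masks(rng)
        p = _zero_params(masks, ["A", "B"])
        with pytest.raises(ValueError, match="genes"):
            forward(p, masks, np.zeros((3, 5)))


class TestVote:
    def test_plurality(self):
        labels = np.array([["A", "A", "B", "A", "C"]], dtype=object).reshape(5, 1)
        probs = [np.array([[1 / 3, 1 / 3, 1 / 3]])] * 5
        assert vote(labels, probs, ["A", "B", "C"])[0] == "A"

    def test_tie_broken_by_summed_probability(self):
        labels = np.array([["A"], ["B"]], dtype=object)
        probs = [np.array([[0.6, 0.4]]), np.array([[0.7, 0.5]])]  # A sums 1.3, B 0.9
        assert vote(labels, probs, ["A", "B"])[0] == "A"
        probs = [np.array([[0.4, 0.6]]), np.array([[0.5, 0.7]])]
        assert vote(labels, probs, ["A", "B"])[0] == "B"

    def test_single_head_returns_its_labels(self):
        labels = np.array([["A", "B", "A"]], dtype=object)
        out = vote(labels, [np.ones((3, 2)) / 2], ["A", "B"])
        assert list(out) == ["A", "B", "A"]

    def test_matches_plurality_oracle_on_random_inputs(self, rng):
        classes = ["A", "B", "C"]
        for _ in range(20):
            n_heads, n_cells = int(rng.integers(1, 6)), int(rng.integers(1, 8))
            probs = [rng.dirichlet(np.ones(3), size=n_cells) for _ in range(n_heads)]
            labels = np.array(
                [[classes[p[i].argmax()] for i in range(n_cells)] for p in probs],
                dtype=object,
            )
            got = vote(labels, probs, classes)
            summed = np.sum(probs, axis=0)
            for i in range(n_cells):
                counts = {c: (labels[:, i] == c).sum() for c in classes}
                best = max(counts.values())
                tied = sorted(c for c, k in counts.items() if k == best)
                expect = max(tied, key=lambda c: summed[i, classes.index(c)])
                assert got[i] == expect


class TestTrain:
    @staticmethod
    def _separable(rng, n_per=40):
        # two marker blocks of 3 genes, one pathway each, toy two-layer net
        masks = MaskStack(
            masks=[
                np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], dtype=np.uint8),
                np.array([[1], [1]], dtype=np.uint8),
            ],
            row_ids=[[f"g{i}" for i in range(6)], ["pA", "pB"]],
            col_ids=[["pA", "pB"], ["top"]],
        )
        X = np.vstack([
            np.hstack([rng.normal(2, 0.3, (n_per, 3)), rng.normal(-2, 0.3, (n_per, 3))]),
            np.hstack([rng.normal(-2, 0.3, (n_per, 3)), rng.normal(2, 0.3, (n_per, 3))]),
        ])
        y = np.array(["A"] * n_per + ["B"] * n_per)
        return masks, X, y

    def test_separable_toy_reaches_training_accuracy_one(self, rng):
        masks, X, y = self._separable(rng)
        p0 = init_model(masks, ["A", "B"], seed=0)
        trained, trace = train(p0, masks, X, y, TrainingConfig(epochs=10, seed=0))
        res = predict(trained, masks, X)
        assert (res.voted == y).mean() == 1.0
        assert trace[-1] < trace[0]

    def test_mask_conservation_through_training(self, rng):
        masks = _random_masks(rng)
        X = rng.normal(size=(64, 6))
        y = np.array(["A", "B"] * 32)
        p0 = init_model(masks, ["A", "B"], seed=0)
        # 200 steps: batch 16 over 64 samples = 4 steps/epoch, 50 epochs
        trained, _ = train(p0, masks, X, y, TrainingConfig(batch_size=16, epochs=50, seed=0))
        for w, m in zip(trained.weights, masks.masks):
            assert np.abs(w[m == 0]).max() == 0.0

    def test_single_class_labels_rejected(self, rng):
        masks = _random_masks(rng)
        p0 = init_model(masks, ["A", "B"], seed=0)
        with pytest.raises(ValueError, match="single class"):
            train(p0, masks, rng.normal(size=(4, 6)), np.array(["A"] * 4),
                  TrainingConfig(epochs=1))

    def test_training_is_deterministic_under_seed(self, rng):
        masks, X, y = self._separable(rng, n_per=16)
        outs = []
        for _ in range(2):
            p0 = init_model(masks, ["A", "B"], seed=5)
            trained, trace = train(p0, masks, X, y, TrainingConfig(epochs=3, seed=5))
            outs.append((trained, trace))
        for wa, wb in zip(outs[0][0].weights, outs[1][0].weights):
            np.testing.assert_array_equal(wa, wb)
        assert outs[0][1] == outs[1][1]


class TestGridSearch:
    def test_singleton_grid_returned(self, rng):
        masks, X, y = TestTrain._separable(rng, n_per=10)
        cfg = TrainingConfig(epochs=2, seed=0)
        best, score, scores = grid_search_cv(X, y, masks, [cfg], folds=2, seed=0)
        assert best == cfg and len(scores) == 1

    def test_better_config_wins_on_separable_toy(self, rng):
        masks, X, y = TestTrain._separable(rng, n_per=12)
        # an absurd learning rate saturates the tanh trunk and wrecks CV score
        bad = TrainingConfig(learning_rate=10.0, epochs=1, seed=0)
        good = TrainingConfig(learning_rate=1e-3, epochs=8, seed=0)
        best, score, scores = grid_search_cv(X, y, masks, [bad, good], folds=2, seed=0)
        assert best == good
        assert scores[1] > scores[0]

    def test_folds_exceeding_class_size_rejected(self, rng):
        masks, X, y = TestTrain._separable(rng, n_per=3)
        with pytest.raises(ValueError, match="fewer folds"):
            grid_search_cv(X, y, masks, [TrainingConfig(epochs=1)], folds=5, seed=0)
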