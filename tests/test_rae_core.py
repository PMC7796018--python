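import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raetrace.rae_core import (
    RAEParams,
    RAETree,
    TrainingConfig,
    TrainingExample,
    build_greedy_tree,
    build_linear_tree,
    combined_error,
    corpus_loss,
    decode_pair,
    encode_pair,
    init_params,
    reconstruction_error,
    root_feature,
    softmax_label,
    supervised_error,
    train,
    tree_grad,
    tree_loss,
)


def _zero_params(n, K=None):
    return RAEParams(
        W1=np.zeros((n, 2 * n)), b1=np.zeros(n),
        W2=np.zeros((2 * n, n)), b2=np.zeros(2 * n),
        Wlabel=None if K is None else np.zeros((K, n)),
    )


class TestEncodeDecode:
    def test_zero_params_zero_parent(self):
        p = encode_pair(np.ones(3), np.ones(3), _zero_params(3))
        assert np.allclose(p, 0.0)

    def test_bias_only_closed_form(self):
        params = _zero_params(3)
        params.b1[:] = 0.5
        p = encode_pair(np.ones(3), -np.ones(3), params)
        assert np.allclose(p, np.tanh(0.5))

    def test_encode_matches_hand_oracle(self):
        rng = np.random.default_rng(0)
        params = init_params(3, seed=1, scale=0.2)
        c1, c2 = rng.normal(size=3), rng.normal(size=3)
        p = encode_pair(c1, c2, params)
        # elementwise recomputation
        cat = np.concatenate([c1, c2])
        expected = [np.tanh(sum(params.W1[i, j] * cat[j] for j in range(6)) + params.b1[i])
                    for i in range(3)]
        assert np.allclose(p, expected, atol=1e-12)

    def test_encode_shape_mismatch(self):
        with pytest.raises(ValueError):
            encode_pair(np.ones(3), np.ones(4), _zero_params(3))

    def test_parent_entries_in_open_interval(self):
        params = init_params(4, seed=2, scale=1.0)
        p = encode_pair(np.ones(4) * 5, np.ones(4) * -5, params)
        assert np.all(np.abs(p) < 1.0)

    def test_decode_zero_params_zero(self):
        c1, c2 = decode_pair(np.ones(3), _zero_params(3))
        assert np.allclose(c1, 0) and np.allclose(c2, 0)

    def test_decode_shapes(self):
        params = init_params(4, seed=3)
        c1, c2 = decode_pair(encode_pair(np.ones(4), np.zeros(4), params), params)
        assert c1.shape == (4,) and c2.shape == (4,)

    def test_decode_matches_hand_oracle(self):
        params = init_params(2, seed=4, scale=0.3)
        p = np.array([0.2, -0.4])
        c1, c2 = decode_pair(p, params)
        rec = params.W2 @ p + params.b2
        assert np.allclose(np.concatenate([c1, c2]), rec, atol=1e-12)


class TestErrors:
    def test_identical_vectors_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert reconstruction_error(x, x) == 0.0

    def test_quarter(self):
        assert reconstruction_error(np.array([1.0, 0, 0, 0]), np.zeros(4)) == pytest.approx(0.25)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(size=6)
        assert reconstruction_error(x, y) == pytest.approx(reconstruction_error(y, x))

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_error(np.zeros(3), np.zeros(4))


class TestSoftmax:
    def test_zero_weights_uniform(self):
        d = softmax_label(np.ones(3), _zero_params(3, K=5))
        assert np.allclose(d, 0.2)

    def test_single_label_always_one(self):
        d = softmax_label(np.ones(3), _zero_params(3, K=1))
        assert np.allclose(d, [1.0])

    def test_matches_exp_normalise_oracle(self):
        params = init_params(3, n_labels=3, seed=6, scale=0.5)
        p = np.array([0.3, -0.2, 0.8])
        d = softmax_label(p, params)
        logits = params.Wlabel @ p
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(d, expected, atol=1e-12)
        assert d.sum() == pytest.approx(1.0)

    def test_missing_wlabel_raises(self):
        with pytest.raises(ValueError):
            softmax_label(np.ones(3), _zero_params(3))


class TestSupervisedError:
    def test_perfect_prediction_near_zero(self):
        t = np.array([0.0, 1.0, 0.0])
        assert supervised_error(t, t) <= 1e-10

    def test_uniform_k4_is_ln4(self):
        d = np.full(4, 0.25)
        t = np.array([1.0, 0, 0, 0])
        assert supervised_error(d, t) == pytest.approx(np.log(4))

    def test_decreasing_in_true_class_probability(self):
        t = np.array([1.0, 0.0])
        low = supervised_error(np.array([0.3, 0.7]), t)
        high = supervised_error(np.array([0.8, 0.2]), t)
        assert high < low


class TestCombinedError:
    def test_alpha_one_is_unsupervised(self):
        assert combined_error(0.7, 123.0, 1.0) == pytest.approx(0.7)

    def test_alpha_zero_is_supervised(self):
        assert combined_error(123.0, 0.9, 0.0) == pytest.approx(0.9)

    def test_midpoint(self):
        assert combined_error(0.2, 0.4, 0.5) == pytest.approx(0.3)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            combined_error(1.0, 1.0, 1.5)


class TestLinearTree:
    def test_two_rows_one_node(self):
        params = init_params(3, seed=7)
        tree = build_linear_tree(np.eye(3)[:2], params)
        assert len(tree.nodes) == 1

    def test_25_rows_24_nodes(self):
        params = init_params(4, seed=8)
        rows = np.random.default_rng(0).normal(size=(25, 4))
        tree = build_linear_tree(rows, params)
        assert len(tree.nodes) == 24

    def test_merge_order_rightmost_first(self):
        # 4 rows: merge (x3,x4), then (x2,y1), then (x1,y2)  [0-based below]
        params = init_params(3, seed=9)
        rows = np.random.default_rng(1).normal(size=(4, 3))
        tree = build_linear_tree(rows, params)
        assert tree.structure() == [(2, 3), (1, 4), (0, 5)]

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            build_linear_tree(np.ones((1, 3)), init_params(3))

    def test_node_errors_nonnegative(self):
        params = init_params(4, seed=10, scale=0.5)
        tree = build_linear_tree(np.random.default_rng(2).normal(size=(6, 4)), params)
        assert np.all(tree.node_errors() >= 0)


class TestGreedyTree:
    @staticmethod
    def _oracle_check(rows, params):
        """Replay construction, brute-forcing the adjacent-pair argmin."""
        from raetrace.rae_core import decode_pair, encode_pair, reconstruction_error

        tree = build_greedy_tree(rows, params)
        k = rows.shape[0]
        vecs = [rows[i] for i in range(k)]
        refs = list(range(k))
        for node_i, node in enumerate(tree.nodes):
            errs = []
            for j in range(len(vecs) - 1):
                p = encode_pair(vecs[j], vecs[j + 1], params)
                c1, c2 = decode_pair(p, params)
                errs.append(reconstruction_error(
                    np.concatenate([vecs[j], vecs[j + 1]]),
                    np.concatenate([c1, c2])))
            j_star = int(np.argmin(errs))
            assert (node.left, node.right) == (refs[j_star], refs[j_star + 1])
            assert node.error == pytest.approx(min(errs), abs=1e-12)
            vecs[j_star : j_star + 2] = [node.p]
            refs[j_star : j_star + 2] = [k + node_i]
        return tree

    def test_two_tokens_single_parent(self):
        params = init_params(3, seed=11)
        tree = build_greedy_tree(np.eye(3)[:2], params)
        assert len(tree.nodes) == 1

    def test_three_tokens_argmin_merge(self):
        params = init_params(4, seed=12, scale=0.4)
        rows = np.random.default_rng(3).normal(size=(3, 4))
        self._oracle_check(rows, params)

    def test_five_tokens_four_nodes_min_at_each_level(self):
        params = init_params(4, seed=13, scale=0.4)
        rows = np.random.default_rng(4).normal(size=(5, 4))
        tree = self._oracle_check(rows, params)
        assert len(tree.nodes) == 4

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            build_greedy_tree(np.empty((0, 3)), init_params(3))

    def test_single_token_degenerate(self):
        params = init_params(3, seed=14)
        tree = build_greedy_tree(np.eye(3)[:1], params)
        assert tree.is_degenerate
        assert np.array_equal(tree.root_vector(), np.eye(3)[0])

    def test_internal_node_count_invariant(self):
        params = init_params(3, seed=15, scale=0.3)
        rng = np.random.default_rng(5)
        for k in range(2, 9):
            tree = build_greedy_tree(rng.normal(size=(k, 3)), params)
            assert len(tree.nodes) == k - 1

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_greedy_optimality_property(self, k, seed):
        rng = np.random.default_rng(seed)
        params = init_params(3, seed=seed, scale=0.5)
        rows = rng.normal(size=(k, 3))
        self._oracle_check(rows, params)


class TestRootFeature:
    def test_length_34_for_six_token_tree(self):
        params = init_params(34, seed=16)
        rows = np.eye(34)[[6, 2, 6, 2, 4, 3]]
        tree = build_greedy_tree(rows, params)
        assert root_feature(tree).shape == (34,)

    def test_degenerate_returns_leaf(self):
        tree = RAETree(leaves=np.eye(3)[:1], nodes=[])
        assert np.array_equal(root_feature(tree), np.eye(3)[0])

    def test_deterministic(self):
        params = init_params(5, seed=17, scale=0.3)
        rows = np.random.default_rng(6).normal(size=(4, 5))
        a = root_feature(build_greedy_tree(rows, params))
        b = root_feature(build_greedy_tree(rows.copy(), params))
        assert np.array_equal(a, b)


def _numeric_grads(rows, structure, params, alpha, label_index, eps=1e-6):
    grads = {}
    for key, arr in params.arrays().items():
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = tree_loss(rows, structure, params, alpha=alpha, label_index=label_index)
            arr[idx] = orig - eps
            lm = tree_loss(rows, structure, params, alpha=alpha, label_index=label_index)
            arr[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        grads[key] = num
    return grads


class TestGradients:
    @pytest.mark.parametrize("style", ["linear", "greedy"])
    @pytest.mark.parametrize("alpha,semi", [(1.0, False), (0.0, True), (0.2, True), (1.0, True)])
    def test_backprop_matches_central_differences(self, style, alpha, semi):
        rng = np.random.default_rng(42)
        n, K, k = 4, 3, 5
        params = init_params(n, K if semi else None, seed=5, scale=0.3)
        rows = rng.normal(size=(k, n))
        builder = build_linear_tree if style == "linear" else build_greedy_tree
        structure = builder(rows, params).structure()
        label = 1 if semi else None
        _, analytic = tree_grad(rows, structure, params, alpha=alpha, label_index=label)
        numeric = _numeric_grads(rows, structure, params, alpha, label)
        for key in numeric:
            scale = max(np.abs(numeric[key]).max(), 1e-8)
            assert np.abs(analytic[key] - numeric[key]).max() / scale <= 1e-4

    def test_tanh_decoder_gradients(self):
        rng = np.random.default_rng(7)
        params = init_params(3, seed=8, scale=0.4, decode_activation="tanh")
        rows = rng.normal(size=(3, 3))
        structure = build_linear_tree(rows, params).structure()
        _, analytic = tree_grad(rows, structure, params)
        numeric = _numeric_grads(rows, structure, params, 1.0, None)
        for key in numeric:
            scale = max(np.abs(numeric[key]).max(), 1e-8)
            assert np.abs(analytic[key] - numeric[key]).max() / scale <= 1e-4


class TestTraining:
    @staticmethod
    def _toy_corpus(n_examples=30, seed=0):
        rng = np.random.default_rng(seed)
        corpus = []
        for _ in range(n_examples):
            k = int(rng.integers(2, 6))
            rows = np.eye(6)[rng.integers(0, 6, size=k)]
            corpus.append(TrainingExample(rows, label_index=int(rng.integers(0, 3))))
        return corpus

    def test_zero_epochs_returns_init(self):
        corpus = self._toy_corpus()
        config = TrainingConfig(epochs=0, seed=3)
        params = train(corpus, config)
        expected = init_params(6, None, seed=3)
        for key, arr in params.arrays().items():
            assert np.array_equal(arr, expected.arrays()[key])

    @pytest.mark.parametrize("mode,style", [
        ("unsupervised", "linear"),
        ("unsupervised", "greedy"),
        ("semisupervised", "greedy"),
    ])
    def test_training_reduces_loss(self, mode, style):
        corpus = self._toy_corpus()
        config = TrainingConfig(mode=mode, alpha=0.2, epochs=10, seed=1, tree_style=style)
        init = train(corpus, TrainingConfig(mode=mode, alpha=0.2, epochs=0, seed=1,
                                            tree_style=style), n_labels=3)
        trained = train(corpus, config, n_labels=3)
        assert corpus_loss(corpus, trained, config) <= corpus_loss(corpus, init, config)

    def test_seed_determinism(self):
        corpus = self._toy_corpus()
        config = TrainingConfig(epochs=3, seed=5)
        a, b = train(corpus, config), train(corpus, config)
        for key, arr in a.arrays().items():
            assert np.array_equal(arr, b.arrays()[key])

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            train([], TrainingConfig())

    def test_semisupervised_without_labels_raises(self):
        corpus = [TrainingExample(np.eye(4)[:2])]
        with pytest.raises(ValueError):
            train(corpus, TrainingConfig(mode="semisupervised"))

    def test_alpha_one_semisup_objective_reduces_to_unsup(self):
        corpus = self._toy_corpus(10)
        params = init_params(6, n_labels=3, seed=9, scale=0.2)
        semi = TrainingConfig(mode="semisupervised", alpha=1.0, tree_style="linear")
        unsup = TrainingConfig(mode="unsupervised", tree_style="linear")
        assert corpus_loss(corpus, params, semi) == pytest.approx(
            corpus_loss(corpus, params, unsup), abs=1e-12)


class TestConfigValidation:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            TrainingConfig(alpha=1.2)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            TrainingConfig(mode="reinforcement")

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            RAEParams(W1=np.zeros((3, 5)), b1=np.zeros(3),
                      W2=np.zeros((6, 3)), b2=np.zeros(6))
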