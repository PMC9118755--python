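import numpy as np
import pytest
from hypothesis import given, strategies as st

from magcnse.io_formats import AssociationMatrix
from magcnse.representation import (
    AttentionParams,
    ConvFuser,
    EntityRepresentation,
    GcnConfig,
    LayerEmbeddingStack,
    _Side,
    channel_attention,
    cnn_fuse,
    gcn_forward,
    normalize_graph,
    reconstruction_loss,
    train_representations,
)
from magcnse.similarity import SimilarityView


def make_view(values, name="LFS"):
    values = np.asarray(values, dtype=float)
    return SimilarityView(values, [f"e{i}" for i in range(len(values))], name)


def random_view(rng, n, name):
    a = rng.random((n, n))
    a = (a + a.T) / 2 * 0.9
    np.fill_diagonal(a, 1.0)
    return SimilarityView(a, [f"e{i}" for i in range(n)], name)


class TestNormalizeGraph:
    def test_single_node(self):
        graph = normalize_graph(make_view([[1.0]]))
        assert graph.values == pytest.approx(np.array([[1.0]]))

    def test_no_off_diagonal_gives_identity(self):
        graph = normalize_graph(make_view(np.eye(3)))
        assert np.allclose(graph.values, np.eye(3), atol=1e-12)

    @given(st.integers(0, 1000))
    def test_output_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        graph = normalize_graph(random_view(rng, 4, "LSS"))
        assert np.abs(graph.values - graph.values.T).max() < 1e-12


class TestGcnForward:
    def test_zero_init_gives_zero_channels(self):
        rng = np.random.default_rng(0)
        view = random_view(rng, 4, "LFS")
        graphs = [normalize_graph(view)]
        weights = [[rng.normal(size=(3, 3)) for _ in range(2)]]
        stack = gcn_forward(graphs, weights, [np.zeros((4, 3))])
        assert all(np.all(c == 0) for c in stack.channels)

    def test_identity_graph_identity_weights_fixed_point(self):
        view = make_view(np.eye(3), "LSS")
        graph = normalize_graph(view)  # identity since S has no off-diagonal
        init = np.abs(np.random.default_rng(1).normal(size=(3, 2)))
        stack = gcn_forward([graph], [[np.eye(2), np.eye(2)]], [init])
        for channel in stack.channels:
            assert np.allclose(channel, init.T, atol=1e-12)

    def test_channel_count_is_views_times_layers(self):
        rng = np.random.default_rng(2)
        graphs = [normalize_graph(random_view(rng, 4, n)) for n in ("LFS", "LSS")]
        weights = [[rng.normal(size=(3, 3)) for _ in range(2)] for _ in graphs]
        init = [rng.normal(size=(4, 3)) for _ in graphs]
        assert gcn_forward(graphs, weights, init).n_channels == 4
        assert gcn_forward(graphs, weights, init, first_layer_only=True).n_channels == 2

    @given(st.integers(0, 1000))
    def test_matches_explicit_matrix_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, f = 5, 3
        view = random_view(rng, n, "LGS")
        graph = normalize_graph(view)
        weights = [rng.normal(size=(f, f)) for _ in range(2)]
        init = rng.normal(size=(n, f))
        stack = gcn_forward([graph], [weights], [init])
        x = init
        for layer, w in enumerate(weights):
            x = np.maximum(graph.values @ x @ w, 0.0)
            assert np.allclose(stack.channels[layer], x.T, atol=1e-10)


class TestChannelAttention:
    def params(self, c, mu=2, seed=0):
        rng = np.random.default_rng(seed)
        return AttentionParams(
            W1=rng.normal(size=(c * mu, c)), W2=rng.normal(size=(c, c * mu)), mu=mu
        )

    def test_zero_channels_get_half_gates_and_stay_zero(self):
        stack = LayerEmbeddingStack(
            [np.zeros((3, 4)), np.zeros((3, 4))], [("LFS", 1), ("LFS", 2)], list("abcd")
        )
        scaled, gates = channel_attention(stack, self.params(2))
        assert gates == pytest.approx([0.5, 0.5])
        assert all(np.all(c == 0) for c in scaled.channels)

    @given(st.integers(0, 1000))
    def test_output_is_channelwise_scaling_by_gates_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        channels = [rng.normal(size=(3, 4)) for _ in range(3)]
        stack = LayerEmbeddingStack(channels, [("LFS", 1)] * 3, list("abcd"))
        scaled, gates = channel_attention(stack, self.params(3, seed=seed))
        assert np.all((gates > 0) & (gates < 1))
        for g, before, after in zip(gates, channels, scaled.channels):
            assert np.allclose(after, g * before, atol=1e-12)


class TestCnnFuse:
    def test_zero_channels_leave_only_bias(self):
        stack = LayerEmbeddingStack([np.zeros((4, 3))], [("LFS", 1)], list("abc"))
        fuser = ConvFuser(filters=np.ones((2, 4)), biases=np.array([1.5, -2.0]))
        rep = cnn_fuse(stack, fuser)
        assert np.allclose(rep.values[0], 1.5) and np.allclose(rep.values[1], -2.0)

    def test_ones_channel_ones_filter_sums_feature_dim(self):
        stack = LayerEmbeddingStack([np.ones((4, 3))], [("LFS", 1)], list("abc"))
        fuser = ConvFuser(filters=np.ones((1, 4)), biases=np.zeros(1))
        assert np.allclose(cnn_fuse(stack, fuser).values, 4.0)

    @given(st.integers(0, 1000))
    def test_matches_double_loop_inner_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c_in, f, n, c_out = 3, 4, 5, 2
        channels = [rng.normal(size=(f, n)) for _ in range(c_in)]
        stack = LayerEmbeddingStack(channels, [("LFS", 1)] * c_in, [f"e{i}" for i in range(n)])
        fuser = ConvFuser(filters=rng.normal(size=(c_out, f)), biases=rng.normal(size=c_out))
        rep = cnn_fuse(stack, fuser)
        assert rep.values.shape == (c_out, n)
        for q in range(c_out):
            for j in range(n):
                expected = (
                    sum(channels[i][:, j] @ fuser.filters[q] for i in range(c_in))
                    + fuser.biases[q]
                )
                assert rep.values[q, j] == pytest.approx(expected, abs=1e-10)


class TestReconstructionLoss:
    def ld(self):
        return AssociationMatrix(np.array([[1, 0], [0, 1]]), ["l1", "l2"], ["d1", "d2"])

    def test_exact_reconstruction_gives_zero(self):
        x = EntityRepresentation(np.eye(2), ["l1", "l2"])
        y = EntityRepresentation(np.eye(2), ["d1", "d2"])
        assert reconstruction_loss(x, y, self.ld()) == 0.0

    def test_constant_prediction_closed_form(self):
        ld = AssociationMatrix(np.zeros((3, 4), dtype=int), list("abc"), list("wxyz"))
        a = 0.7
        x = EntityRepresentation(np.full((1, 3), 1.0), list("abc"))
        y = EntityRepresentation(np.full((1, 4), a), list("wxyz"))
        assert reconstruction_loss(x, y, ld) == pytest.approx(3 * 4 * a**2)

    def test_masking_removes_exactly_that_cells_contribution(self):
        rng = np.random.default_rng(5)
        x = EntityRepresentation(rng.normal(size=(3, 2)), ["l1", "l2"])
        y = EntityRepresentation(rng.normal(size=(3, 2)), ["d1", "d2"])
        full = reconstruction_loss(x, y, self.ld())
        mask = np.ones((2, 2))
        mask[0, 1] = 0
        diff = (x.values.T @ y.values - self.ld().values)[0, 1]
        assert reconstruction_loss(x, y, self.ld(), mask) == pytest.approx(full - diff**2)


def small_problem(seed=0, n_l=12, n_d=8):
    rng = np.random.default_rng(seed)
    views_l = [random_view(rng, n_l, name) for name in ("LFS", "LSS", "LGS")]
    views_d = [random_view(rng, n_d, name) for name in ("DSS", "DGS")]
    values = (rng.random((n_l, n_d)) < 0.3).astype(int)
    values[0, 0] = 1
    ld = AssociationMatrix(
        values, [f"e{i}" for i in range(n_l)], [f"e{i}" for i in range(n_d)]
    )
    return views_l, views_d, ld


def small_config(**kwargs):
    defaults = dict(
        embedding_size=8, num_layers=2, n_filters=6, attention_expansion=2,
        epochs=40, seed=3,
    )
    defaults.update(kwargs)
    return GcnConfig(**defaults)


class TestTraining:
    def test_loss_decreases_on_small_problem(self):
        views_l, views_d, ld = small_problem()
        _, _, trace = train_representations(views_l, views_d, ld, small_config())
        assert len(trace.values) == 40
        assert trace.values[-1] < trace.values[0]

    def test_same_seed_is_bit_identical(self):
        views_l, views_d, ld = small_problem()
        cfg = small_config()
        x1, y1, t1 = train_representations(views_l, views_d, ld, cfg)
        x2, y2, t2 = train_representations(views_l, views_d, ld, cfg)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(x1.values, x2.values)
        assert np.array_equal(y1.values, y2.values)

    def test_first_layer_only_truncates_channels(self):
        views_l, views_d, ld = small_problem()
        cfg = small_config(first_layer_only=True)
        rng = np.random.default_rng(cfg.seed)
        side = _Side(views_l, cfg, rng)
        assert side.n_channels == 3  # one channel per lncRNA view

    def test_no_cnn_fusion_outputs_feature_dim_embedding(self):
        views_l, views_d, ld = small_problem()
        x, y, _ = train_representations(
            views_l, views_d, ld, small_config(use_cnn=False, epochs=5)
        )
        assert x.values.shape[0] == 8  # embedding_size, not n_filters

    def test_mask_changes_the_objective(self):
        views_l, views_d, ld = small_problem()
        cfg = small_config(epochs=5)
        _, _, t_full = train_representations(views_l, views_d, ld, cfg)
        mask = np.ones(ld.shape)
        mask[:, 0] = 0
        _, _, t_masked = train_representations(views_l, views_d, ld, cfg, loss_mask=mask)
        assert t_masked.values[0] < t_full.values[0]

    def test_trainer_forward_matches_functional_composition(self):
        """The fused training forward equals normalize->GCN->attention->CNN."""
        views_l, _, _ = small_problem()
        cfg = small_config()
        rng = np.random.default_rng(cfg.seed)
        side = _Side(views_l, cfg, rng)
        out = side.forward()

        graphs = [normalize_graph(v) for v in views_l]
        weights = [[w.astype(np.float64) for w in vw] for vw in side.w]
        init = [x.astype(np.float64) for x in side.x0]
        stack = gcn_forward(graphs, weights, init)
        params = AttentionParams(
            W1=side.w1.astype(np.float64), W2=side.w2.astype(np.float64),
            mu=cfg.attention_expansion,
        )
        scaled, _ = channel_attention(stack, params)
        fuser = ConvFuser(
            filters=side.wf.astype(np.float64), biases=side.bf.astype(np.float64)
        )
        expected = cnn_fuse(scaled, fuser)
        assert np.allclose(out, expected.values, atol=1e-5)

    def test_view_order_mismatch_is_rejected(self):
        views_l, views_d, ld = small_problem()
        bad = SimilarityView(
            views_d[0].values, [f"x{i}" for i in range(8)], "DSS"
        )
        with pytest.raises(ValueError, match="entity order"):
            train_representations(views_l, [bad, views_d[1]], ld, small_config())
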