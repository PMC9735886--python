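"""Spatial branch: masked attention coefficients, multi-head layers,
stacking, and spatial-domain attention — each against hand evaluations."""

import math

import numpy as np
import pytest

from mganet.channel_graph import ChannelGraph, Montage, build_knn_adjacency
from mganet.exceptions import ParameterError, ValidationError
from mganet.node_attention import (
    AttentionMatrix,
    GatHeadParams,
    GatLayerParams,
    SpatialAttentionParams,
    apply_spatial_attention,
    attention_coefficients,
    gat_layer,
    init_gat_layer,
    init_spatial_attention,
    spatial_attention,
    stack_gat,
)


def _sigma(x):
    return 1.0 / (1.0 + math.exp(-x))


def _two_node_graph():
    m = Montage(("a", "b"), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    return ChannelGraph(montage=m, adjacency=np.array([[0, 1], [1, 0]]), k=1)


def _hand_head(w=1.0, a=(0.0, 0.0)):
    return GatHeadParams(W=np.array([[w]]), a_vec=np.array(a))


@pytest.fixture()
def random_graph6(rng):
    coords = rng.normal(size=(6, 3))
    return build_knn_adjacency(
        Montage(tuple(f"c{i}" for i in range(6)), coords), k=3
    )


class TestAttentionCoefficients:
    def test_single_neighbor_weight_is_one(self):
        g = _two_node_graph()
        feats = np.array([[0.3], [1.7]])
        w = attention_coefficients(_hand_head(2.0, (1.0, -1.0)), feats, g, 0)
        assert w.shape == (1,)
        assert w[0] == 1.0

    def test_two_neighbor_softmax_of_scores_1_and_2(self):
        # complete 3-node graph; weights engineered so centre 0 sees
        # post-LeakyReLU scores exactly (1.0, 2.0) for neighbours (1, 2)
        m = Montage(("a", "b", "c"), np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        g = build_knn_adjacency(m, k=2)
        feats = np.array([[0.0], [1.0], [2.0]])
        head = GatHeadParams(W=np.array([[1.0]]), a_vec=np.array([0.0, 1.0]))
        w = attention_coefficients(head, feats, g, 0)
        e1, e2 = math.exp(1.0), math.exp(2.0)
        assert np.allclose(w, [e1 / (e1 + e2), e2 / (e1 + e2)], atol=1e-10)
        assert np.allclose(w, [0.26894, 0.73106], atol=1e-5)

    def test_leaky_relu_negative_slope_is_0p2(self):
        # score -1 -> exp(-0.2), score +3 -> exp(3)
        m = Montage(("a", "b", "c"), np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]))
        g = build_knn_adjacency(m, k=2)
        feats = np.array([[0.0], [-1.0], [3.0]])
        head = GatHeadParams(W=np.array([[1.0]]), a_vec=np.array([0.0, 1.0]))
        w = attention_coefficients(head, feats, g, 0)
        em, ep = math.exp(-0.2), math.exp(3.0)
        assert np.allclose(w, [em / (em + ep), ep / (em + ep)], atol=1e-10)

    def test_weights_positive_and_sum_to_one(self, rng, random_graph6):
        layer = init_gat_layer(rng, 5, 4, 1)
        feats = rng.normal(size=(6, 5))
        for c in range(6):
            w = attention_coefficients(layer.heads[0], feats, random_graph6, c)
            assert np.all(w > 0)
            assert abs(w.sum() - 1.0) < 1e-6


class TestGatLayer:
    def test_two_node_hand_example(self):
        g = _two_node_graph()
        feats = np.array([[0.0], [2.0]])
        layer = GatLayerParams(heads=(_hand_head(),))
        out = gat_layer(layer, feats, g)
        assert np.allclose(out, [[_sigma(2.0)], [_sigma(0.0)]], atol=1e-10)
        assert np.allclose(out, [[0.88080], [0.5]], atol=1e-5)

    def test_identical_heads_equal_single_head(self, rng, random_graph6):
        feats = rng.normal(size=(6, 5))
        head = init_gat_layer(rng, 5, 4, 1).heads[0]
        one = gat_layer(GatLayerParams(heads=(head,)), feats, random_graph6)
        four = gat_layer(GatLayerParams(heads=(head,) * 4), feats, random_graph6)
        assert np.allclose(one, four, atol=1e-12)

    def test_output_in_open_unit_interval(self, rng, random_graph6):
        layer = init_gat_layer(rng, 5, 4, 8)
        out = gat_layer(layer, rng.normal(size=(6, 5)), random_graph6)
        assert np.all((out > 0) & (out < 1))

    def test_non_neighbor_perturbation_leaves_output_unchanged(self, rng, random_graph6):
        layer = init_gat_layer(rng, 5, 4, 2)
        feats = rng.normal(size=(6, 5))
        out = gat_layer(layer, feats, random_graph6, )
        adj = random_graph6.adjacency
        # find a non-adjacent pair
        pairs = [(i, j) for i in range(6) for j in range(6)
                 if i != j and adj[i, j] == 0]
        if not pairs:
            pytest.skip("random graph is complete")
        c, j = pairs[0]
        feats2 = feats.copy()
        feats2[j] += 10.0
        out2 = gat_layer(layer, feats2, random_graph6)
        assert np.allclose(out[c], out2[c], atol=1e-12)

    def test_permutation_equivariance(self, rng):
        # relabeling nodes permutes the layer output identically
        for trial in range(5):
            coords = rng.normal(size=(6, 3))
            g = build_knn_adjacency(
                Montage(tuple(f"c{i}" for i in range(6)), coords), k=3
            )
            layer = init_gat_layer(rng, 5, 4, 2)
            feats = rng.normal(size=(6, 5))
            out = gat_layer(layer, feats, g)
            perm = rng.permutation(6)
            g_perm = ChannelGraph(
                montage=Montage(
                    tuple(g.montage.channel_names[p] for p in perm),
                    g.montage.coordinates[perm],
                ),
                adjacency=g.adjacency[np.ix_(perm, perm)],
                k=3,
            )
            out_perm = gat_layer(layer, feats[perm], g_perm)
            assert np.allclose(out_perm, out[perm], atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng, random_graph6):
        layer = init_gat_layer(rng, 5, 4, 2)
        with pytest.raises(ParameterError):
            gat_layer(layer, rng.normal(size=(6, 7)), random_graph6)


class TestStackGat:
    def test_depth_one_equals_gat_layer(self, rng, random_graph6):
        layer = init_gat_layer(rng, 5, 4, 2)
        feats = rng.normal(size=(6, 5))
        assert np.allclose(
            stack_gat([layer], feats, random_graph6),
            gat_layer(layer, feats, random_graph6),
        )

    def test_depth_two_hand_oracle_with_identity_interlayer(self):
        # step-by-step: layer1 gives (sigma(2), sigma(0)); ReLU keeps both;
        # layer2 with the same hand weights swaps and squashes again
        g = _two_node_graph()
        feats = np.array([[0.0], [2.0]])
        layer = GatLayerParams(heads=(_hand_head(),))
        out = stack_gat([layer, layer], feats, g, interlayer_weights=[np.eye(1)])
        h1 = (_sigma(2.0), _sigma(0.0))
        expected = [[_sigma(h1[1])], [_sigma(h1[0])]]
        assert np.allclose(out, expected, atol=1e-10)

    def test_interlayer_relu_clips_negative_intermediates(self, rng, random_graph6):
        # a strongly negative interlayer weight zeroes the second layer input,
        # making the final output independent of the input features
        layer1 = init_gat_layer(rng, 5, 4, 1)
        layer2 = init_gat_layer(rng, 4, 3, 1)
        w_neg = -10.0 * np.eye(4)
        feats_a = rng.normal(size=(6, 5))
        feats_b = rng.normal(size=(6, 5))
        out_a = stack_gat([layer1, layer2], feats_a, random_graph6, [w_neg])
        out_b = stack_gat([layer1, layer2], feats_b, random_graph6, [w_neg])
        assert np.allclose(out_a, out_b, atol=1e-12)

    def test_wrong_interlayer_count_rejected(self, rng, random_graph6):
        layer = init_gat_layer(rng, 5, 4, 1)
        with pytest.raises(ParameterError):
            stack_gat([layer], rng.normal(size=(6, 5)), random_graph6, [np.eye(4)])


class TestSpatialAttention:
    def test_zero_bilinear_term_gives_uniform_rows(self, rng):
        n, f, t = 4, 3, 5
        params = SpatialAttentionParams(
            P_s=np.ones((n, n)), Q_s=np.zeros((n, n)),
            Q1=rng.normal(size=(f, 1)), Q2=np.zeros((1, t)),
            Q3=rng.normal(size=(t, f)),
        )
        attn = spatial_attention(params, rng.normal(size=(n, f, t)))
        assert np.allclose(attn.values, 1.0 / n, atol=1e-12)

    def test_two_node_scalar_hand_evaluation(self):
        # n=2, F=1, T=1 with scalar parameters: score_ij = q1 q2 q3 x_i x_j
        q1, q2, q3 = 0.5, 2.0, -1.0
        x = np.array([[1.0], [3.0]])
        params = SpatialAttentionParams(
            P_s=np.full((2, 2), 1.5), Q_s=np.full((2, 2), 0.25),
            Q1=np.array([[q1]]), Q2=np.array([[q2]]), Q3=np.array([[q3]]),
        )
        attn = spatial_attention(params, x)
        raw = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                raw[i, j] = 1.5 * _sigma(q1 * q2 * q3 * x[i, 0] * x[j, 0] + 0.25)
        expected = np.exp(raw) / np.exp(raw).sum(axis=1, keepdims=True)
        assert np.allclose(attn.values, expected, atol=1e-10)

    def test_rows_sum_to_one_for_random_params(self, rng):
        params = init_spatial_attention(rng, n=6, f=5, t=5)
        attn = spatial_attention(params, rng.normal(size=(6, 5, 5)))
        assert np.allclose(attn.values.sum(axis=1), 1.0, atol=1e-6)


class TestApplySpatialAttention:
    def test_identity_attention_preserves_features(self):
        feats = np.arange(12.0).reshape(4, 3)
        attn = AttentionMatrix(values=np.eye(3))
        assert np.allclose(apply_spatial_attention(feats, attn), feats)

    def test_uniform_attention_averages_columns(self):
        feats = np.arange(12.0).reshape(4, 3)
        attn = AttentionMatrix(values=np.full((3, 3), 1 / 3))
        out = apply_spatial_attention(feats, attn)
        assert np.allclose(out, np.tile(feats.mean(axis=1, keepdims=True), (1, 3)))

    def test_matches_matrix_product_oracle(self, rng):
        feats = rng.normal(size=(5, 3))
        raw = rng.uniform(0.1, 1.0, size=(3, 3))
        a = raw / raw.sum(axis=1, keepdims=True)
        attn = AttentionMatrix(values=a)
        assert np.allclose(apply_spatial_attention(feats, attn), feats @ a, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        attn = AttentionMatrix(values=np.eye(3))
        with pytest.raises(ParameterError):
            apply_spatial_attention(rng.normal(size=(5, 4)), attn)


class TestAttentionMatrixInvariants:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            AttentionMatrix(values=np.full((2, 2), 0.3))

    def test_masked_entries_must_be_zero(self):
        vals = np.array([[0.5, 0.5], [0.5, 0.5]])
        mask = np.array([[1, 0], [1, 1]])
        with pytest.raises(ValidationError):
            AttentionMatrix(values=vals, mask=mask)

    def test_valid_masked_matrix_accepted(self):
        vals = np.array([[1.0, 0.0], [0.4, 0.6]])
        mask = np.array([[1, 0], [1, 1]])
        attn = AttentionMatrix(values=vals, mask=mask)
        assert attn.n == 2
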