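"""Graph layers: scoring formulas, softmax normalization, dense-oracle parity."""

import numpy as np
import pytest

from dense_reference import (
    dense_dynamic_attention,
    dense_gcn,
    dense_static_attention,
    random_graph,
)
from dtagnn._nn import Tensor
from dtagnn.errors import ConfigError, InputError
from dtagnn.graph_layers import (
    DynamicGraphAttention,
    GraphConvolution,
    StaticGraphAttention,
    add_self_loops,
    edge_attention_scores,
    global_max_pool,
    normalize_attention,
)


def make_dynamic(in_dim, out_dim, heads=1, seed=0, **kw):
    return DynamicGraphAttention(
        in_dim, out_dim, np.random.default_rng(seed), heads=heads, **kw
    )


# -- raw scores -------------------------------------------------------------


def test_zero_attention_vector_gives_zero_scores(rng):
    layer = make_dynamic(3, 4, heads=2)
    layer.a.data[:] = 0.0
    x, edges = random_graph(rng, 6, 3)
    scores = edge_attention_scores(Tensor(x), edges, layer)
    np.testing.assert_array_equal(scores.data, 0.0)


def test_two_node_hand_computation():
    # d = d' = 1, W_left = W_right = [1], a = [1], slope 0.2, features (1, -1)
    layer = make_dynamic(1, 1, heads=1)
    layer.W_left.data[:] = 1.0
    layer.W_right.data[:] = 1.0
    layer.a.data[:] = 1.0
    x = np.array([[1.0], [-1.0]])
    edges = np.array([[0, 1], [1, 0]])  # (src, dst)
    scores = edge_attention_scores(Tensor(x), edges, layer).data[:, 0]
    # edge 0->1: LeakyReLU(d_1 + d_0) = LeakyReLU(-1 + 1) = 0
    assert scores[0] == 0.0
    # edge 1->0: LeakyReLU(d_0 + d_1) = 0 as well (symmetric features)
    assert scores[1] == 0.0
    x2 = np.array([[1.0], [2.0]])
    s2 = edge_attention_scores(Tensor(x2), edges, layer).data[:, 0]
    assert s2[0] == pytest.approx(3.0)  # LeakyReLU(2 + 1)


def test_doubling_a_doubles_raw_scores(rng):
    layer = make_dynamic(3, 4, heads=2)
    x, edges = random_graph(rng, 8, 3)
    s1 = edge_attention_scores(Tensor(x), edges, layer).data
    layer.a.data *= 2.0
    s2 = edge_attention_scores(Tensor(x), edges, layer).data
    np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-12)


def test_score_width_mismatch_raises(rng):
    layer = make_dynamic(3, 4)
    with pytest.raises(InputError):
        edge_attention_scores(Tensor(rng.normal(size=(5, 7))), np.array([[0, 1]]), layer)


# -- normalization ----------------------------------------------------------


def test_single_in_neighbor_coefficient_is_one():
    scores = Tensor(np.array([[3.7]]))
    alpha = normalize_attention(scores, np.array([[1, 0]]), 2)
    assert alpha.data[0, 0] == pytest.approx(1.0)


def test_equal_scores_give_uniform_coefficients():
    k = 5
    edges = np.stack([np.arange(1, k + 1), np.zeros(k, dtype=int)], axis=1)
    alpha = normalize_attention(Tensor(np.full((k, 1), 2.2)), edges, k + 1)
    np.testing.assert_allclose(alpha.data, 1.0 / k)


def test_softmax_matches_independent_exp_sum_oracle(rng):
    x, edges = random_graph(rng, 10, 3)
    if len(edges) == 0:
        edges = np.array([[0, 1], [1, 0]])
    raw = rng.normal(size=(len(edges), 2))
    alpha = normalize_attention(Tensor(raw), edges, 10).data
    for h in range(2):
        for i in range(10):
            mask = edges[:, 1] == i
            if not mask.any():
                continue
            expected = np.exp(raw[mask, h]) / np.exp(raw[mask, h]).sum()
            np.testing.assert_allclose(alpha[mask, h], expected, atol=1e-6)


def test_coefficients_sum_to_one_per_destination(rng):
    layer = make_dynamic(3, 4, heads=3)
    x, edges = random_graph(rng, 9, 3)
    layer(Tensor(x), edges)
    src, dst, alpha = layer.last_attention
    sums = np.zeros((9, 3))
    np.add.at(sums, dst, alpha)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)


# -- layer forward ----------------------------------------------------------


def test_single_head_equals_manual_single_head_formula(rng):
    """With H = 1 the multi-head average reduces exactly to the one-head update."""
    layer = make_dynamic(3, 4, heads=1, activation=Tensor.relu)
    x, edges = random_graph(rng, 7, 3)
    out = layer(Tensor(x), edges).data
    # manual: softmax-normalized scores weighting W_right-transformed neighbors
    aug = add_self_loops(edges, 7)
    scores = edge_attention_scores(Tensor(x), aug, layer)
    alpha = normalize_attention(scores, aug, 7).data[:, 0]
    right = x @ layer.W_right.data
    manual = np.zeros((7, 4))
    for (s, d), a in zip(aug, alpha):
        manual[d] += a * right[s]
    np.testing.assert_allclose(out, np.maximum(manual, 0.0), atol=1e-10)


def test_identical_heads_average_to_single_head(rng):
    multi = make_dynamic(3, 4, heads=3)
    single = make_dynamic(3, 4, heads=1)
    for h in range(3):
        multi.W_left.data[:, h * 4 : (h + 1) * 4] = single.W_left.data
        multi.W_right.data[:, h * 4 : (h + 1) * 4] = single.W_right.data
        multi.a.data[h] = single.a.data[0]
    x, edges = random_graph(rng, 6, 3)
    np.testing.assert_allclose(
        multi(Tensor(x), edges).data, single(Tensor(x), edges).data, atol=1e-12
    )


def test_zero_heads_rejected():
    with pytest.raises(ConfigError):
        make_dynamic(3, 4, heads=0)


@pytest.mark.parametrize("cls", [DynamicGraphAttention, StaticGraphAttention])
def test_permutation_equivariance(cls, rng):
    layer = cls(3, 5, np.random.default_rng(1), heads=2)
    x, edges = random_graph(rng, 8, 3)
    out = layer(Tensor(x), edges).data
    perm = rng.permutation(8)
    inv = np.argsort(perm)
    x_p = x[inv]  # node perm[i] of new graph = node i of old? map: new[k] = old[inv[k]]
    edges_p = perm[edges] if len(edges) else edges
    out_p = layer(Tensor(x_p), edges_p).data
    np.testing.assert_allclose(out_p[perm], out, atol=1e-6)


# -- static attention -------------------------------------------------------


def test_static_and_dynamic_coincide_in_linear_regime():
    """With all pre-activations positive the LeakyReLU is the identity and
    the two scoring orders agree for tied weights (a_L = a_R = a)."""
    rng = np.random.default_rng(2)
    stat = StaticGraphAttention(3, 4, np.random.default_rng(0), heads=1)
    dyn = make_dynamic(3, 4, heads=1)
    W = np.abs(rng.normal(size=(3, 4)))
    a = np.abs(rng.normal(size=(1, 4)))
    stat.W.data = W.copy()
    stat.a_left.data = a.copy()
    stat.a_right.data = a.copy()
    dyn.W_left.data = W.copy()
    dyn.W_right.data = W.copy()
    dyn.a.data = a.copy()
    x = np.abs(rng.normal(size=(6, 3)))  # positive features keep arguments positive
    edges = np.array([[i, j] for i in range(6) for j in range(6) if i != j])
    s_static = stat._raw_scores(Tensor(x), edges).data
    s_dynamic = edge_attention_scores(Tensor(x), edges, dyn).data
    np.testing.assert_allclose(s_static, s_dynamic, atol=1e-10)


def test_static_key_ranking_identical_across_queries(rng):
    layer = StaticGraphAttention(5, 4, np.random.default_rng(3), heads=1)
    x = rng.normal(size=(9, 5))
    edges = np.array([[i, j] for i in range(9) for j in range(9) if i != j])
    scores = layer._raw_scores(Tensor(x), edges).data[:, 0]
    table = np.full((9, 9), np.nan)
    table[edges[:, 1], edges[:, 0]] = scores
    rankings = []
    for i in range(9):
        keys = [j for j in range(9) if j != i]
        rankings.append([keys[r] for r in np.argsort([table[i, j] for j in keys])])
    # drop the (varying) query itself from each ranking; order of the rest is global
    common = [tuple(k for k in r) for r in rankings]
    reference_order = [j for j in common[0]]
    for i, r in enumerate(common[1:], start=1):
        filtered_ref = [j for j in reference_order if j != i]
        filtered_r = [j for j in r if j != 0]
        assert [j for j in filtered_r if j in filtered_ref] == filtered_ref


def test_static_single_neighbor_softmax_is_one():
    layer = StaticGraphAttention(2, 2, np.random.default_rng(0), heads=1,
                                 self_loops=False)
    x = np.array([[1.0, 0.0], [0.0, 1.0]])
    layer(Tensor(x), np.array([[1, 0]]))
    _, _, alpha = layer.last_attention
    assert alpha[0, 0] == pytest.approx(1.0)


# -- GCN --------------------------------------------------------------------


def test_gcn_edgeless_graph_is_sigma_xw(rng):
    layer = GraphConvolution(3, 4, np.random.default_rng(0), activation=Tensor.relu)
    x = rng.normal(size=(5, 3))
    out = layer(Tensor(x), np.empty((0, 2), dtype=np.int64)).data
    np.testing.assert_allclose(out, np.maximum(x @ layer.W.data, 0.0), atol=1e-12)


def test_gcn_two_node_dense_matrix_oracle():
    layer = GraphConvolution(1, 1, np.random.default_rng(0))
    layer.W.data[:] = 1.0
    x = np.array([[1.0], [0.0]])
    edges = np.array([[0, 1], [1, 0]])
    out = layer(Tensor(x), edges).data
    # Ã = [[1,1],[1,1]], D̃ = 2I → normalized = ones/2 → each node (x0+x1)/2
    np.testing.assert_allclose(out, np.array([[0.5], [0.5]]), atol=1e-12)


def test_gcn_normalized_adjacency_is_symmetric(rng):
    x, edges = random_graph(rng, 8, 1)
    n = 8
    a_tilde = np.eye(n)
    for s, d in edges:
        a_tilde[d, s] = 1.0
    d_half = np.diag(a_tilde.sum(1) ** -0.5)
    norm = d_half @ a_tilde @ d_half
    np.testing.assert_allclose(norm, norm.T, atol=1e-8)


# -- pooling ----------------------------------------------------------------


def test_global_max_pool_contract(rng):
    x = rng.normal(size=(1, 4))
    np.testing.assert_array_equal(
        global_max_pool(Tensor(x), np.array([0])).data, x
    )
    # permutation invariance
    x = rng.normal(size=(6, 4))
    member = np.zeros(6, dtype=int)
    pooled = global_max_pool(Tensor(x), member).data
    perm = rng.permutation(6)
    np.testing.assert_array_equal(
        global_max_pool(Tensor(x[perm]), member).data, pooled
    )
    # batch of two graphs vs per-graph loop oracle
    member = np.array([0, 0, 0, 1, 1, 1])
    batched = global_max_pool(Tensor(x), member).data
    np.testing.assert_array_equal(batched[0], x[:3].max(axis=0))
    np.testing.assert_array_equal(batched[1], x[3:].max(axis=0))
    with pytest.raises(InputError):
        global_max_pool(Tensor(x), member, num_graphs=3)


# -- dense-oracle equivalence ----------------------------------------------


@pytest.mark.parametrize("seed", range(8))
def test_sparse_layers_match_dense_reference(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 13))
    x, edges = random_graph(rng, n, 5)
    layer_rng = np.random.default_rng(seed + 100)
    dyn = DynamicGraphAttention(5, 4, layer_rng, heads=3, activation=Tensor.relu)
    stat = StaticGraphAttention(5, 4, layer_rng, heads=2, activation=Tensor.relu)
    gcn = GraphConvolution(5, 4, layer_rng, activation=Tensor.relu)
    np.testing.assert_allclose(
        dyn(Tensor(x), edges).data, dense_dynamic_attention(x, edges, dyn), atol=1e-5
    )
    np.testing.assert_allclose(
        stat(Tensor(x), edges).data, dense_static_attention(x, edges, stat), atol=1e-5
    )
    np.testing.assert_allclose(
        gcn(Tensor(x), edges).data, dense_gcn(x, edges, gcn), atol=1e-5
    )
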