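"""Graph neural-network layers for the drug branch.

Three layer types operate on (node features, directed edge list):

* :class:`DynamicGraphAttention` — GATv2-style attention.  The raw score of
  edge j→i is ``aᵀ · LeakyReLU(W_left dᵢ + W_right dⱼ)``: the attention
  vector ``a`` is applied *after* the nonlinearity on the joint query–key
  transform, so the induced key ranking can differ per query ("dynamic"
  attention).
* :class:`StaticGraphAttention` — classic GAT scoring
  ``LeakyReLU(a_Lᵀ(W dᵢ) + a_Rᵀ(W dⱼ))``: ``a`` acts linearly inside a
  monotone nonlinearity, so every query induces the same ranking over keys.
* :class:`GraphConvolution` — symmetric-normalized GCN propagation
  ``σ(D̃^{-1/2} Ã D̃^{-1/2} X W)`` with ``Ã = A + I``.

Conventions shared by the attention layers: each node attends over its
in-neighbourhood plus itself (a self-edge is added inside the layer, which
also keeps the softmax defined for isolated nodes); scores are normalized by
a per-destination softmax; multi-head outputs are *averaged* (not
concatenated); an optional activation is applied last.  Attention dropout,
when enabled, is applied to the normalized coefficients in training mode.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ._nn import Module, Tensor, glorot_uniform, rows, segment_max, segment_sum
from ._nn import dropout as _dropout
from .errors import ConfigError, InputError

__all__ = [
    "DynamicGraphAttention",
    "StaticGraphAttention",
    "GraphConvolution",
    "edge_attention_scores",
    "normalize_attention",
    "global_max_pool",
    "add_self_loops",
]

Activation = Callable[[Tensor], Tensor] | None


def add_self_loops(edge_index: np.ndarray, num_nodes: int) -> np.ndarray:
    """Append one (i, i) edge per node to a (E, 2) directed edge list."""
    loops = np.repeat(np.arange(num_nodes, dtype=np.int64)[:, None], 2, axis=1)
    if edge_index.size == 0:
        return loops
    return np.concatenate([edge_index, loops], axis=0)


def _check_edges(edge_index: np.ndarray, num_nodes: int) -> np.ndarray:
    edge_index = np.asarray(edge_index, dtype=np.int64)
    if edge_index.ndim != 2 or edge_index.shape[1] != 2:
        raise InputError("edge_index must have shape (E, 2)")
    if edge_index.size and (edge_index.min() < 0 or edge_index.max() >= num_nodes):
        raise InputError("edge index out of range")
    return edge_index


def edge_attention_scores(
    node_feats: Tensor, edge_index: np.ndarray, params: "DynamicGraphAttention"
) -> Tensor:
    """Raw dynamic-attention scores, one per (edge, head).

    For edge (j → i): score_h = a_hᵀ · LeakyReLU(W_left dᵢ + W_right dⱼ).
    """
    n, heads, out_dim = node_feats.shape[0], params.heads, params.out_dim
    if node_feats.shape[1] != params.in_dim:
        raise InputError(
            f"feature width {node_feats.shape[1]} != layer input width {params.in_dim}"
        )
    edge_index = _check_edges(edge_index, n)
    src, dst = edge_index[:, 0], edge_index[:, 1]
    left = (node_feats @ params.W_left).reshape(n, heads, out_dim)
    right = (node_feats @ params.W_right).reshape(n, heads, out_dim)
    joint = (rows(left, dst) + rows(right, src)).leaky_relu(params.leaky_slope)
    return (joint * params.a).sum(axis=2)  # (E, heads)


def normalize_attention(
    raw_scores: Tensor, edge_index: np.ndarray, num_nodes: int
) -> Tensor:
    """Per-destination softmax of raw scores (any trailing head axis).

    Shift-invariant softmax: the per-destination maximum is subtracted as a
    constant before exponentiation, which changes nothing mathematically but
    keeps the exponentials bounded.
    """
    dst = np.asarray(edge_index, dtype=np.int64)[:, 1]
    seg_max = np.full((num_nodes,) + raw_scores.shape[1:], -np.inf)
    np.maximum.at(seg_max, dst, raw_scores.data)
    shifted = (raw_scores - Tensor(seg_max[dst])).exp()
    denom = segment_sum(shifted, dst, num_nodes)
    return shifted / rows(denom, dst)


def global_max_pool(
    node_feats: Tensor, graph_membership: np.ndarray, num_graphs: int | None = None
) -> Tensor:
    """Coordinate-wise maximum over each graph's nodes → one row per graph."""
    graph_membership = np.asarray(graph_membership, dtype=np.int64)
    if num_graphs is None:
        num_graphs = int(graph_membership.max()) + 1 if graph_membership.size else 0
    if graph_membership.size == 0 or np.bincount(
        graph_membership, minlength=num_graphs
    ).min() == 0:
        raise InputError("global_max_pool: empty graph in batch")
    return segment_max(node_feats, graph_membership, num_graphs)


class _AttentionBase(Module):
    """Shared aggregation: softmax-normalize scores, average messages over heads."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        heads: int,
        leaky_slope: float,
        dropout_rate: float,
        self_loops: bool,
        activation: Activation,
    ):
        if heads < 1:
            raise ConfigError("number of attention heads must be >= 1")
        if not 0.0 <= dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if not 0.0 < leaky_slope < 1.0:
            raise ConfigError("leaky_slope must be in (0, 1)")
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.heads = heads
        self.leaky_slope = leaky_slope
        self.dropout_rate = dropout_rate
        self.self_loops = self_loops
        self.activation = activation
        #: (src, dst, coefficients (E, heads)) from the most recent forward pass
        self.last_attention: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def _raw_scores(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        raise NotImplementedError

    def _messages(self, x: Tensor) -> Tensor:
        """Per-node message stack (N, heads, out_dim)."""
        raise NotImplementedError

    def __call__(
        self,
        x: Tensor,
        edge_index: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        n = x.shape[0]
        edge_index = _check_edges(edge_index, n)
        if self.self_loops:
            edge_index = add_self_loops(edge_index, n)
        src, dst = edge_index[:, 0], edge_index[:, 1]
        scores = self._raw_scores(x, edge_index)
        alpha = normalize_attention(scores, edge_index, n)
        self.last_attention = (src.copy(), dst.copy(), alpha.data.copy())
        if training and self.dropout_rate > 0.0:
            if rng is None:
                raise ConfigError("training-mode attention dropout needs an rng")
            alpha = _dropout(alpha, self.dropout_rate, rng)
        msgs = rows(self._messages(x), src)  # (E, heads, out_dim)
        weighted = msgs * alpha.reshape(alpha.shape[0], self.heads, 1)
        agg = segment_sum(weighted, dst, n).mean(axis=1)  # head average
        return self.activation(agg) if self.activation else agg


class DynamicGraphAttention(_AttentionBase):
    """Multi-head dynamic (GATv2-style) graph attention layer."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        heads: int = 10,
        leaky_slope: float = 0.2,
        dropout_rate: float = 0.0,
        self_loops: bool = True,
        activation: Activation = None,
    ):
        super().__init__(
            in_dim, out_dim, heads, leaky_slope, dropout_rate, self_loops, activation
        )
        # W = [W_left | W_right] acting on [d_i ‖ d_j]; messages use W_right d_j
        self.W_left = Tensor(
            glorot_uniform(rng, in_dim, heads * out_dim), requires_grad=True
        )
        self.W_right = Tensor(
            glorot_uniform(rng, in_dim, heads * out_dim), requires_grad=True
        )
        self.a = Tensor(
            glorot_uniform(rng, out_dim, 1, shape=(heads, out_dim)), requires_grad=True
        )

    def _raw_scores(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        return edge_attention_scores(x, edge_index, self)

    def _messages(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        return (x @ self.W_right).reshape(n, self.heads, self.out_dim)


class StaticGraphAttention(_AttentionBase):
    """Classic (static) GAT layer: scoring linear in ``a`` outside the LeakyReLU.

    Because ``LeakyReLU(a_Lᵀ W dᵢ + a_Rᵀ W dⱼ)`` is monotone in the key term
    ``a_Rᵀ W dⱼ``, every query node ranks its keys identically.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        heads: int = 10,
        leaky_slope: float = 0.2,
        dropout_rate: float = 0.0,
        self_loops: bool = True,
        activation: Activation = None,
    ):
        super().__init__(
            in_dim, out_dim, heads, leaky_slope, dropout_rate, self_loops, activation
        )
        self.W = Tensor(
            glorot_uniform(rng, in_dim, heads * out_dim), requires_grad=True
        )
        # a = [a_left ‖ a_right] ∈ R^{2 out_dim} per head
        self.a_left = Tensor(
            glorot_uniform(rng, out_dim, 1, shape=(heads, out_dim)), requires_grad=True
        )
        self.a_right = Tensor(
            glorot_uniform(rng, out_dim, 1, shape=(heads, out_dim)), requires_grad=True
        )

    def _transformed(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        return (x @ self.W).reshape(n, self.heads, self.out_dim)

    def _raw_scores(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        if x.shape[1] != self.in_dim:
            raise InputError(
                f"feature width {x.shape[1]} != layer input width {self.in_dim}"
            )
        src, dst = edge_index[:, 0], edge_index[:, 1]
        wx = self._transformed(x)
        query = (wx * self.a_left).sum(axis=2)  # (N, heads)
        key = (wx * self.a_right).sum(axis=2)
        return (rows(query, dst) + rows(key, src)).leaky_relu(self.leaky_slope)

    def _messages(self, x: Tensor) -> Tensor:
        return self._transformed(x)


class GraphConvolution(Module):
    """GCN layer: ``σ(D̃^{-1/2} (A + I) D̃^{-1/2} X W)``, sparse implementation."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        activation: Activation = None,
    ):
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.activation = activation
        self.W = Tensor(glorot_uniform(rng, in_dim, out_dim), requires_grad=True)

    def __call__(
        self,
        x: Tensor,
        edge_index: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        n = x.shape[0]
        if x.shape[1] != self.in_dim:
            raise InputError(
                f"feature width {x.shape[1]} != layer input width {self.in_dim}"
            )
        edge_index = _check_edges(edge_index, n)
        aug = add_self_loops(edge_index, n)
        src, dst = aug[:, 0], aug[:, 1]
        deg = np.bincount(dst, minlength=n).astype(np.float64)  # self-looped degree
        norm = 1.0 / np.sqrt(deg[src] * deg[dst])  # (E,)
        xw = x @ self.W
        weighted = rows(xw, src) * Tensor(norm[:, None])
        out = segment_sum(weighted, dst, n)
        return self.activation(out) if self.activation else out
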