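"""Dense adjacency-matrix reference implementations of the graph layers.

These recompute each layer with explicit (N, N) matrices and plain loops,
independently of the package's sparse gather/scatter path, and serve as the
oracles in the layer-equivalence tests.
"""

import numpy as np


def _leaky(x, slope):
    return np.where(x > 0, x, slope * x)


def _adjacency(edges, n, self_loops):
    adj = np.zeros((n, n), dtype=bool)  # adj[dst, src]
    for s, d in edges:
        adj[d, s] = True
    if self_loops:
        adj |= np.eye(n, dtype=bool)
    return adj


def dense_dynamic_attention(x, edges, layer):
    """Dense recomputation of the dynamic-attention layer forward pass."""
    n = x.shape[0]
    heads, out_dim = layer.heads, layer.out_dim
    adj = _adjacency(edges, n, layer.self_loops)
    left = (x @ layer.W_left.data).reshape(n, heads, out_dim)
    right = (x @ layer.W_right.data).reshape(n, heads, out_dim)
    out = np.zeros((n, out_dim))
    for h in range(heads):
        scores = np.full((n, n), -np.inf)
        for i in range(n):
            for j in range(n):
                if adj[i, j]:
                    scores[i, j] = layer.a.data[h] @ _leaky(
                        left[i, h] + right[j, h], layer.leaky_slope
                    )
        alpha = np.zeros((n, n))
        for i in range(n):
            row = scores[i][adj[i]]
            e = np.exp(row - row.max())
            alpha[i, adj[i]] = e / e.sum()
        out += alpha @ right[:, h, :]
    out /= heads
    return np.maximum(out, 0.0) if layer.activation else out


def dense_static_attention(x, edges, layer):
    n = x.shape[0]
    heads, out_dim = layer.heads, layer.out_dim
    adj = _adjacency(edges, n, layer.self_loops)
    wx = (x @ layer.W.data).reshape(n, heads, out_dim)
    out = np.zeros((n, out_dim))
    for h in range(heads):
        q = wx[:, h, :] @ layer.a_left.data[h]
        k = wx[:, h, :] @ layer.a_right.data[h]
        scores = np.full((n, n), -np.inf)
        for i in range(n):
            for j in range(n):
                if adj[i, j]:
                    scores[i, j] = _leaky(q[i] + k[j], layer.leaky_slope)
        alpha = np.zeros((n, n))
        for i in range(n):
            row = scores[i][adj[i]]
            e = np.exp(row - row.max())
            alpha[i, adj[i]] = e / e.sum()
        out += alpha @ wx[:, h, :]
    out /= heads
    return np.maximum(out, 0.0) if layer.activation else out


def dense_gcn(x, edges, layer):
    """σ(D̃^{-1/2} (A + I) D̃^{-1/2} X W) with explicit dense matrices."""
    n = x.shape[0]
    a_tilde = np.eye(n)
    for s, d in edges:
        a_tilde[d, s] = 1.0
    d_tilde = np.diag(a_tilde.sum(axis=1) ** -0.5)
    out = d_tilde @ a_tilde @ d_tilde @ x @ layer.W.data
    return np.maximum(out, 0.0) if layer.activation else out


def random_graph(rng, n_nodes, n_feats, p_edge=0.35):
    """Random directed-symmetric simple graph + features (no self-loops)."""
    x = rng.normal(size=(n_nodes, n_feats))
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((i, j))
                edges.append((j, i))
    edge_index = (
        np.array(edges, dtype=np.int64) if edges else np.empty((0, 2), dtype=np.int64)
    )
    return x, edge_index
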