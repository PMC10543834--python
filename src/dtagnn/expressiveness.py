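"""Static- vs dynamic-attention expressiveness: the dictionary-lookup probe.

Static attention scores each edge as ``LeakyReLU(a_Lᵀ W dᵢ + a_Rᵀ W dⱼ)``.
For a fixed set of node features the key term ``a_Rᵀ W dⱼ`` is a single
scalar per key and the nonlinearity is monotone, so *every* query ranks the
keys identically — one globally preferred key dominates all attention maps.
Dynamic scoring applies the attention vector after the joint nonlinear
transform of (query, key), so the induced ranking can change per query.

The probe that separates the two is a complete bipartite dictionary-lookup
task: k query nodes each have to fetch the value carried by their assigned
key node (a fixed permutation), while the key *values* are resampled every
step.  The only policy consistent across value draws is to attend to the
assigned key, so a layer that can express query-dependent attention reaches
high query→key argmax accuracy, and a static layer cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, Linear, Tensor, rows
from .graph_layers import DynamicGraphAttention, StaticGraphAttention

__all__ = [
    "LookupResult",
    "make_lookup_instance",
    "train_dynamic_lookup",
    "static_key_rankings",
]


@dataclass
class LookupResult:
    """Outcome of one lookup-training run."""

    assignment_accuracy: float  # fraction of queries whose attention argmax is their key
    final_loss: float
    assignment: np.ndarray  # the target query → key permutation


def make_lookup_instance(
    rng: np.random.Generator, k: int, copies: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Build ``copies`` disjoint complete-bipartite lookup graphs.

    Each copy has k query nodes (one-hot block 1) and k key nodes (one-hot
    block 2 plus a value slot drawn fresh from N(0,1)); edges run key→query.
    Returns (node features (copies*2k, 2k+1), edge list).
    """
    n = 2 * k
    feats = np.zeros((copies * n, 2 * k + 1))
    edges = []
    for c in range(copies):
        off = c * n
        feats[off : off + k, :k] = np.eye(k)
        feats[off + k : off + n, k : 2 * k] = np.eye(k)
        feats[off + k : off + n, -1] = rng.normal(size=k)
        src = np.repeat(np.arange(off + k, off + n), k)
        dst = np.tile(np.arange(off, off + k), k)
        edges.append(np.stack([src, dst], axis=1))
    return feats, np.concatenate(edges)


def train_dynamic_lookup(
    seed: int,
    k: int = 8,
    steps: int = 400,
    lr: float = 0.02,
    hidden: int = 16,
    copies: int = 32,
) -> LookupResult:
    """Train a single dynamic-attention layer on the lookup task.

    Returns the attention argmax accuracy on a fresh instance: 1.0 means
    every query's strongest attention coefficient points at its assigned key.
    """
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(k)
    n = 2 * k
    layer = DynamicGraphAttention(2 * k + 1, hidden, rng, heads=1, self_loops=False)
    head = Linear(hidden, 1, rng)
    opt = Adam(layer.parameters() + head.parameters(), lr=lr)
    query_idx = np.concatenate([np.arange(c * n, c * n + k) for c in range(copies)])
    loss_value = np.inf
    for _ in range(steps):
        feats, edges = make_lookup_instance(rng, k, copies)
        targets = np.concatenate(
            [feats[c * n + k : (c + 1) * n, -1][assignment] for c in range(copies)]
        )
        opt.zero_grad()
        out = layer(Tensor(feats), edges)
        pred = head(rows(out, query_idx)).reshape(copies * k)
        loss = ((pred - Tensor(targets)) ** 2).mean()
        loss.backward()
        opt.step()
        loss_value = float(loss.data)
    feats, edges = make_lookup_instance(rng, k, copies=1)
    layer(Tensor(feats), edges)
    src, dst, alpha = layer.last_attention
    attention = np.zeros((k, k))
    attention[dst, src - k] = alpha[:, 0]
    accuracy = float(np.mean(attention.argmax(axis=1) == assignment))
    return LookupResult(accuracy, loss_value, assignment)


def static_key_rankings(
    layer: StaticGraphAttention, feats: np.ndarray, k: int
) -> np.ndarray:
    """Per-query key rankings of a static layer's raw scores on one instance.

    Returns an (k, k) array whose row i is argsort of query i's raw scores
    over the k keys; by the monotonicity of static scoring all rows are
    identical (up to ties).
    """
    n = 2 * k
    src = np.repeat(np.arange(k, n), k)
    dst = np.tile(np.arange(k), k)
    edges = np.stack([src, dst], axis=1)
    scores = layer._raw_scores(Tensor(feats), edges).data[:, 0]
    table = np.zeros((k, k))
    table[dst, src - k] = scores
    return np.argsort(table, axis=1, kind="stable")
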