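"""Protein-branch layers: embedding, Bi-LSTM, 1D convolutional encoder.

The fixed-length integer code sequence is embedded (padding code 0 maps to a
frozen zero row), run through a bidirectional LSTM whose per-position output
is the concatenation of the forward state (after reading positions 1..i) and
the backward state (after reading positions n..i), and finally condensed by
a stack of 1D convolutions with global max pooling into one fixed-width
protein vector.

Padding positions are *not* masked inside the recurrence by default; a
``mask_padding`` flag on :class:`BiLSTM` zeroes the hidden state updates at
padded positions for callers who want length-exact recurrences.
"""

from __future__ import annotations

import numpy as np

from ._nn import (
    Linear,
    Module,
    Tensor,
    concat,
    embedding_lookup,
    glorot_uniform,
    unfold1d,
)
from .errors import ConfigError
from .protseq import EncodedProtein

__all__ = ["Embedding", "BiLSTM", "ProteinConvEncoder", "embed_protein",
           "bilstm_encode", "protein_conv_encode"]


class Embedding(Module):
    """Integer-code → vector lookup table; row 0 is the (frozen-zero) padding row."""

    def __init__(self, num_codes: int, dim: int, rng: np.random.Generator):
        weight = glorot_uniform(rng, num_codes, dim, shape=(num_codes, dim))
        weight[0] = 0.0
        self.num_codes = num_codes
        self.dim = dim
        self.weight = Tensor(weight, requires_grad=True)

    def __call__(self, codes: np.ndarray) -> Tensor:
        codes = np.asarray(codes)
        if codes.size and (codes.min() < 0 or codes.max() >= self.num_codes):
            raise ConfigError("code out of embedding-table range")
        return embedding_lookup(self.weight, codes, padding_idx=0)


class _LSTMDirection(Module):
    """One direction's weights: gates ordered (input, forget, cell, output)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.Wx = Tensor(glorot_uniform(rng, in_dim, 4 * hidden), requires_grad=True)
        self.Wh = Tensor(glorot_uniform(rng, hidden, 4 * hidden), requires_grad=True)
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias starts open
        self.b = Tensor(bias, requires_grad=True)
        self.hidden = hidden


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _run_lstm(
    x: Tensor,
    params: _LSTMDirection,
    reverse: bool,
    pad_mask: np.ndarray | None = None,
) -> Tensor:
    """Run one direction's recurrence over (B, T, D) → (B, T, hidden).

    Implemented as a single fused autodiff op: the forward loop caches the
    gate activations and the backward pass is classic backpropagation
    through time, which keeps the per-position graph overhead out of the
    hot path.  Output position t always holds the state after consuming
    the sequence up to t in the direction of travel.
    """
    batch, length, in_dim = x.shape
    hd = params.hidden
    Wx, Wh, b = params.Wx, params.Wh, params.b
    steps = list(range(length - 1, -1, -1)) if reverse else list(range(length))
    # pre-project the inputs for every position in one matmul
    z_in = x.data.reshape(batch * length, in_dim) @ Wx.data
    z_in = z_in.reshape(batch, length, 4 * hd) + b.data
    h = np.zeros((batch, hd))
    c = np.zeros((batch, hd))
    out = np.empty((batch, length, hd))
    c_prev_all = np.empty((batch, length, hd))
    h_prev_all = np.empty((batch, length, hd))
    gates = np.empty((batch, length, 4 * hd))
    tanh_c = np.empty((batch, length, hd))
    for t in steps:
        z = z_in[:, t, :] + h @ Wh.data
        i = _sigmoid(z[:, :hd])
        f = _sigmoid(z[:, hd : 2 * hd])
        g = np.tanh(z[:, 2 * hd : 3 * hd])
        o = _sigmoid(z[:, 3 * hd :])
        c_prev_all[:, t, :] = c
        h_prev_all[:, t, :] = h
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if pad_mask is not None:
            keep = pad_mask[:, t : t + 1]
            c_new = keep * c_new + (1.0 - keep) * c
            h_new = keep * h_new + (1.0 - keep) * h
        gates[:, t, :] = np.concatenate([i, f, g, o], axis=1)
        tanh_c[:, t, :] = tc
        c, h = c_new, h_new
        out[:, t, :] = h

    def bw(grad_out):
        dWx = np.zeros_like(Wx.data)
        dWh = np.zeros_like(Wh.data)
        db = np.zeros_like(b.data)
        dx = np.zeros_like(x.data)
        dh = np.zeros((batch, hd))
        dc = np.zeros((batch, hd))
        for t in reversed(steps):
            dh = dh + grad_out[:, t, :]
            if pad_mask is not None:
                keep = pad_mask[:, t : t + 1]
                dh_skip = dh * (1.0 - keep)
                dc_skip = dc * (1.0 - keep)
                dh = dh * keep
                dc = dc * keep
            i = gates[:, t, :hd]
            f = gates[:, t, hd : 2 * hd]
            g = gates[:, t, 2 * hd : 3 * hd]
            o = gates[:, t, 3 * hd :]
            tc = tanh_c[:, t, :]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            dzi = dc * g * i * (1.0 - i)
            dzf = dc * c_prev_all[:, t, :] * f * (1.0 - f)
            dzg = dc * i * (1.0 - g * g)
            dzo = do * o * (1.0 - o)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            dx[:, t, :] = dz @ Wx.data.T
            dWx += x.data[:, t, :].T @ dz
            dWh += h_prev_all[:, t, :].T @ dz
            db += dz.sum(axis=0)
            dh = dz @ Wh.data.T
            dc = dc * f
            if pad_mask is not None:
                dh = dh + dh_skip
                dc = dc + dc_skip
        return dx, dWx, dWh, db

    return Tensor._op(out, (x, Wx, Wh, b), bw)


class BiLSTM(Module):
    """Bidirectional LSTM; per-position output width is ``2 * hidden``."""

    def __init__(
        self,
        in_dim: int,
        hidden: int,
        rng: np.random.Generator,
        mask_padding: bool = False,
    ):
        if hidden < 1:
            raise ConfigError("LSTM hidden size must be >= 1")
        self.in_dim = in_dim
        self.hidden = hidden
        self.mask_padding = mask_padding
        self.forward_cell = _LSTMDirection(in_dim, hidden, rng)
        self.backward_cell = _LSTMDirection(in_dim, hidden, rng)

    def __call__(self, x: Tensor, codes: np.ndarray | None = None) -> Tensor:
        """(B, T, in_dim) → (B, T, 2*hidden).

        ``codes`` (the integer sequence) is only needed when ``mask_padding``
        is on, to locate the padded positions.
        """
        pad_mask = None
        if self.mask_padding:
            if codes is None:
                raise ConfigError("mask_padding requires the integer code array")
            pad_mask = (np.asarray(codes) != 0).astype(np.float64)
        fwd = _run_lstm(x, self.forward_cell, reverse=False, pad_mask=pad_mask)
        bwd = _run_lstm(x, self.backward_cell, reverse=True, pad_mask=pad_mask)
        return concat([fwd, bwd], axis=2)


class ProteinConvEncoder(Module):
    """Stacked 1D convolutions + global max pool + linear projection.

    Defaults (32 → 64 → 96 filters, kernel width 8, ReLU, projection to 128)
    follow the convolutional protein encoders of sequence-based affinity
    models.  Raises :class:`ConfigError` when the receptive field exceeds
    the input length.
    """

    def __init__(
        self,
        in_dim: int,
        rng: np.random.Generator,
        channels: tuple[int, ...] = (32, 64, 96),
        kernel: int = 8,
        out_dim: int = 128,
    ):
        if kernel < 1 or not channels:
            raise ConfigError("conv encoder needs kernel >= 1 and >= 1 stage")
        self.kernel = kernel
        self.out_dim = out_dim
        self.stages: list[Linear] = []
        prev = in_dim
        for ch in channels:
            self.stages.append(Linear(kernel * prev, ch, rng))
            prev = ch
        self.project = Linear(prev, out_dim, rng)

    def __call__(self, p: Tensor) -> Tensor:
        """(B, T, in_dim) → (B, out_dim)."""
        min_len = len(self.stages) * (self.kernel - 1) + 1
        if p.shape[1] < min_len:
            raise ConfigError(
                f"sequence length {p.shape[1]} shorter than receptive field {min_len}"
            )
        h = p
        for stage in self.stages:
            h = stage(unfold1d(h, self.kernel)).relu()
        return self.project(h.max(axis=1))


# Thin functional forms of the three operations.


def embed_protein(protein: EncodedProtein, table: Embedding) -> Tensor:
    """Embed one encoded protein → (max_len, dim)."""
    return table(protein.codes[None, :]).reshape(protein.codes.shape[0], table.dim)


def bilstm_encode(embedded: Tensor, params: BiLSTM) -> Tensor:
    """(B, T, d_p) → P matrix (B, T, 2*hidden)."""
    return params(embedded)


def protein_conv_encode(p_matrix: Tensor, params: ProteinConvEncoder) -> Tensor:
    return params(p_matrix)
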