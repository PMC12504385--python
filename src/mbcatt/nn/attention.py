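"""Bidirectional multi-head cross-modal attention.

Each direction owns independent Query/Key/Value/output projections: the
"electrical" token sequence queries the "hemodynamic" one and vice versa.
Scaled dot-product attention is computed per head on split subspaces
(d_head = d_model / n_heads), heads are re-concatenated and linearly mixed.
Attention maps are kept for inspection after every forward pass.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Parameter


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    # [B, L, D] -> [B, H, L, D/H]
    b, l, d = x.shape
    return x.reshape(b, l, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    # [B, H, L, dh] -> [B, L, D]
    b, h, l, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, l, h * dh)


class _Projection:
    """Weight + bias acting on the last axis of a token tensor."""

    def __init__(self, d_in, d_out, rng, dtype, name):
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(d_out, d_in)).astype(dtype), f"{name}.weight")
        self.bias = Parameter(np.zeros(d_out, dtype=dtype), f"{name}.bias")

    def __call__(self, x):
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad, x):
        # grad, x: [B, L, d]; accumulate and return dx
        self.weight.grad += np.einsum("blo,bli->oi", grad, x)
        self.bias.grad += grad.sum(axis=(0, 1))
        return grad @ self.weight.data

    def parameters(self):
        return [self.weight, self.bias]


class _AttentionDirection:
    """One direction: queries from modality A attend to keys/values of B."""

    def __init__(self, d_model, n_heads, rng, dtype, name):
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = _Projection(d_model, d_model, rng, dtype, f"{name}.q")
        self.k = _Projection(d_model, d_model, rng, dtype, f"{name}.k")
        self.v = _Projection(d_model, d_model, rng, dtype, f"{name}.v")
        self.out = _Projection(d_model, d_model, rng, dtype, f"{name}.out")
        self._cache = None

    def parameters(self):
        return (self.q.parameters() + self.k.parameters()
                + self.v.parameters() + self.out.parameters())

    def forward(self, x_q, x_kv):
        qh = _split_heads(self.q(x_q), self.n_heads)
        kh = _split_heads(self.k(x_kv), self.n_heads)
        vh = _split_heads(self.v(x_kv), self.n_heads)
        scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(self.d_head)
        attn = softmax(scores, axis=-1)          # [B, H, Lq, Lk]
        ctx = attn @ vh                          # [B, H, Lq, dh]
        merged = _merge_heads(ctx)
        out = self.out(merged)
        self._cache = (x_q, x_kv, qh, kh, vh, attn, merged)
        return out, attn

    def backward(self, grad_out):
        x_q, x_kv, qh, kh, vh, attn, merged = self._cache
        dmerged = self.out.backward(grad_out, merged)
        dctx = _split_heads(dmerged, self.n_heads)
        dattn = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward, row-wise
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.d_head)
        dqh = dscores @ kh
        dkh = dscores.transpose(0, 1, 3, 2) @ qh
        dx_q = self.q.backward(_merge_heads(dqh), x_q)
        dx_kv = self.k.backward(_merge_heads(dkh), x_kv)
        dx_kv += self.v.backward(_merge_heads(dvh), x_kv)
        return dx_q, dx_kv


class CrossModalAttention(Layer):
    """Both directions with independent per-modality projections.

    forward maps (eeg_tokens, fnirs_tokens), each [B, L, d_model], to
    (eeg_attended, fnirs_attended); ``last_maps`` holds the attention
    weights [2, B, n_heads, Lq, Lk] (direction 0: EEG queries fNIRS).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d_model, self.n_heads = d_model, n_heads
        self.e2f = _AttentionDirection(d_model, n_heads, rng, dtype, "attn.e2f")
        self.f2e = _AttentionDirection(d_model, n_heads, rng, dtype, "attn.f2e")
        self.last_maps: np.ndarray | None = None

    def parameters(self):
        return self.e2f.parameters() + self.f2e.parameters()

    def forward_pair(self, eeg_tokens, fnirs_tokens):
        if eeg_tokens.shape[-1] != self.d_model or fnirs_tokens.shape[-1] != self.d_model:
            raise ValueError("token width does not match d_model")
        eeg_att, map_ef = self.e2f.forward(eeg_tokens, fnirs_tokens)
        fnirs_att, map_fe = self.f2e.forward(fnirs_tokens, eeg_tokens)
        self.last_maps = np.stack([map_ef, map_fe])
        return eeg_att, fnirs_att

    def backward_pair(self, grad_eeg_att, grad_fnirs_att):
        d_eeg_q, d_fnirs_kv = self.e2f.backward(grad_eeg_att)
        d_fnirs_q, d_eeg_kv = self.f2e.backward(grad_fnirs_att)
        return d_eeg_q + d_eeg_kv, d_fnirs_q + d_fnirs_kv
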