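"""Minimal NumPy neural-network layers with reverse-mode gradients.

Implements exactly the pieces the channel-as-token Transformer needs —
linear maps, ReLU, layer normalization, scaled dot-product and multi-head
self-attention, post-norm encoder blocks, softmax cross-entropy, and Adam.
Forward passes cache what their backward passes need; ``backward`` consumes
the gradient w.r.t. the layer output and returns the gradient w.r.t. its
input while accumulating parameter gradients in place.

Everything runs in float64: the tensors involved are small (tokens are
electrode channels, so sequence length is the channel count) and the extra
precision keeps permutation-invariance checks tight.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Linear(Module):
    """y = x W + b over the last axis (Glorot-uniform init)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.W = Param(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        d_in, d_out = self.W.value.shape
        self.W.grad += x.reshape(-1, d_in).T @ gy.reshape(-1, d_out)
        self.b.grad += gy.reshape(-1, d_out).sum(axis=0)
        return gy @ self.W.value.T


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class LayerNorm(Module):
    """Normalization over the last axis with learnable gain/offset."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Param(np.ones(dim))
        self.offset = Param(np.zeros(dim))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gain.value * self._xhat + self.offset.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gain.grad += (gy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.offset.grad += gy.reshape(-1, xhat.shape[-1]).sum(axis=0)
        gxhat = gy * self.gain.value
        m1 = gxhat.mean(axis=-1, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (gxhat - m1 - xhat * m2)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_k: int | None = None
) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V — the single-head attention map.

    Accepts 2-D (tokens x dim) or batched (..., tokens, dim) arrays; each
    row of the weight matrix is a probability vector over the keys.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"Q has {Q.shape[-1]} columns but K has {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError("K and V must have the same number of rows")
    if d_k is None:
        d_k = Q.shape[-1]
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    return softmax(scores) @ V


class MultiHeadAttention(Module):
    """h-head self-attention with learned Q/K/V projections and output map.

    d_model must divide evenly into h heads of size d_k = d_v = d_model/h.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.h = n_heads
        self.d_k = d_model // n_heads
        self.Wq = Linear(d_model, d_model, rng)
        self.Wk = Linear(d_model, d_model, rng)
        self.Wv = Linear(d_model, d_model, rng)
        self.Wo = Linear(d_model, d_model, rng)

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.h, self.d_k).transpose(0, 2, 1, 3)  # B,h,T,dk

    @staticmethod
    def _merge(x: np.ndarray) -> np.ndarray:
        b, h, t, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dk)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.Wq.forward(x))
        k = self._split(self.Wk.forward(x))
        v = self._split(self.Wv.forward(x))
        scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(self.d_k)
        attn = softmax(scores)
        self._cache = (q, k, v, attn)
        return self.Wo.forward(self._merge(attn @ v))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        g = self._split(self.Wo.backward(gy))  # grad wrt attn @ v
        g_attn = g @ np.swapaxes(v, -1, -2)
        g_v = np.swapaxes(attn, -1, -2) @ g
        # softmax Jacobian applied row-wise
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
        g_scores /= np.sqrt(self.d_k)
        g_q = g_scores @ k
        g_k = np.swapaxes(g_scores, -1, -2) @ q
        gx = self.Wq.backward(self._merge(g_q))
        gx += self.Wk.backward(self._merge(g_k))
        gx += self.Wv.backward(self._merge(g_v))
        return gx


class FeedForward(Module):
    """Position-wise two-layer network with ReLU in between."""

    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d_model, d_ff, rng)
        self.act = ReLU()
        self.lin2 = Linear(d_ff, d_model, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.lin2.forward(self.act.forward(self.lin1.forward(x)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.lin1.backward(self.act.backward(self.lin2.backward(gy)))


class EncoderLayer(Module):
    """Post-norm Transformer block: LN(x + MHA(x)), then LN(y + FFN(y))."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.mha = MultiHeadAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.ln2 = LayerNorm(d_model)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.ln1.forward(x + self.mha.forward(x))
        return self.ln2.forward(y + self.ffn.forward(y))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.ln2.backward(gy)
        g = g + self.ffn.backward(g)
        g = self.ln1.backward(g)
        return g + self.mha.backward(g)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam with the customary defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
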