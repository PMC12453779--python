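"""Neural building blocks: linear, embedding, layer norm, attention,
transformer encoder layers and the Adam optimizer.

All parameters are initialized from an explicit ``numpy.random.Generator``
so a forward pass is bit-reproducible given (seed, config, input).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .autodiff import Parameter, Tensor, concat, embedding, fused_attention

__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm",
    "scaled_dot_attention", "MultiHeadAttention", "EncoderLayer", "Adam",
]

#: Additive mask value for blocked attention logits.  Large enough that the
#: post-shift exponential underflows to exactly 0 for any realistic logit.
MASK_NEG = -1e9


class Module:
    """Minimal parameter-container base class."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            found: list[Parameter] = []
            if isinstance(value, Parameter):
                found = [value]
            elif isinstance(value, Module):
                found = value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        found.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        found.append(item)
            for p in found:
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = np.asarray(a, dtype=p.data.dtype)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float64):
        scale = math.sqrt(1.0 / d_in)
        self.W = Parameter(rng.uniform(-scale, scale, (d_in, d_out)).astype(dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    """Token embedding table; row 0 is the pad row (initialized to zero)."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator,
                 dtype=np.float64):
        table = (rng.standard_normal((n_tokens, dim)) * 0.1).astype(dtype)
        table[0] = 0.0
        self.weight = Parameter(table)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta


def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor,
                         mask: Optional[np.ndarray] = None,
                         return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V over the last two axes.

    ``mask`` is an additive array broadcastable to the logit shape
    (0 = attend, MASK_NEG = blocked).  Every softmax row sums to 1.
    """
    d_k = Q.shape[-1]
    if K.shape[-1] != d_k or K.shape[-2] != V.shape[-2]:
        raise ValueError(
            f"attention shape mismatch: Q {Q.shape}, K {K.shape}, V {V.shape}"
        )
    logits = (Q @ K.T) * (1.0 / math.sqrt(d_k))
    if mask is not None:
        logits = logits + Tensor(np.asarray(mask, dtype=logits.dtype))
    weights = logits.softmax(axis=-1)
    out = weights @ V
    if return_weights:
        return out, weights
    return out


class MultiHeadAttention(Module):
    """Multi-head attention with independent per-head projections.

    Heads are realized as a reshape of packed projections (equivalent to
    independent W_i^Q/W_i^K/W_i^V per head), concatenated and passed
    through the output projection W^O.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float64):
        if dim % n_heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.Wq = Linear(dim, dim, rng, bias=False, dtype=dtype)
        self.Wk = Linear(dim, dim, rng, bias=False, dtype=dtype)
        self.Wv = Linear(dim, dim, rng, bias=False, dtype=dtype)
        self.Wo = Linear(dim, dim, rng, bias=False, dtype=dtype)

    def _split(self, x: Tensor) -> Tensor:
        # (B, L, D) -> (B, H, L, d_head)
        B, L, D = x.shape
        return x.reshape(B, L, self.n_heads, self.d_head).swapaxes(1, 2)

    def __call__(self, q: Tensor, k: Tensor, v: Tensor,
                 key_mask: Optional[np.ndarray] = None) -> Tensor:
        """q/k/v: (B, L, D); key_mask: (B, L_k) boolean, True = real token."""
        B, Lq, D = q.shape
        Qh = self._split(self.Wq(q))
        Kh = self._split(self.Wk(k))
        Vh = self._split(self.Wv(v))
        mask = None
        if key_mask is not None:
            add = np.where(np.asarray(key_mask, bool), 0.0, MASK_NEG)
            mask = add[:, None, None, :]  # (B, 1, 1, L_k)
        out = fused_attention(Qh, Kh, Vh, mask=mask)
        out = out.swapaxes(1, 2).reshape(B, Lq, D)
        return self.Wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.fc1 = Linear(dim, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class EncoderLayer(Module):
    """Pre-norm transformer encoder layer:
    x + MHA(LN(x)); then + FFN(LN(.))."""

    def __init__(self, dim: int, n_heads: int, ffn_hidden: int,
                 rng: np.random.Generator, dtype=np.float64):
        self.ln1 = LayerNorm(dim, dtype=dtype)
        self.mha = MultiHeadAttention(dim, n_heads, rng, dtype=dtype)
        self.ln2 = LayerNorm(dim, dtype=dtype)
        self.ffn = FeedForward(dim, ffn_hidden, rng, dtype=dtype)

    def __call__(self, x: Tensor, key_mask: Optional[np.ndarray] = None) -> Tensor:
        h = self.ln1(x)
        x = x + self.mha(h, h, h, key_mask=key_mask)
        x = x + self.ffn(self.ln2(x))
        return x


class Adam:
    """Adam optimizer (first/second moment estimates, bias-corrected)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
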