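"""Neural building blocks on top of :mod:`amhf._tensor`.

Layers follow the usual conventions: Xavier-uniform initialization for
linear maps, post-layer-norm residual transformer blocks, and an AdamW
optimizer with linear learning-rate warmup and decoupled weight decay
(the "weight decay and preheating" training regime of BERT-style models).
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat, dropout, embedding

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "TextCNN",
    "AdamW",
    "sinusoidal_positions",
]


class Module:
    """Container with recursive parameter discovery and state-dict I/O."""

    def named_parameters(self, prefix: str = ""):
        for name in sorted(vars(self)):
            value = vars(self)[name]
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_xavier(rng, d_in, d_out), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator, scale: float = 1.0):
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_tokens, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self._eps).sqrt() * self.gamma + self.beta


def sinusoidal_positions(n: int, d: int) -> np.ndarray:
    """Fixed transformer positional-embedding matrix (n positions x d dims).

    Entry (pos, 2i) = sin(pos / 10000^(2i/d)); entry (pos, 2i+1) is the
    matching cosine, so row 0 alternates 0, 1, 0, 1, ...
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    if d % 2 != 0:
        raise ValueError("embedding dimension must be even")
    pos = np.arange(n)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d)
    out = np.empty((n, d))
    out[:, 0::2] = np.sin(angle)
    out[:, 1::2] = np.cos(angle)
    return out


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with padding mask and Add&Norm.

    ``last_attention`` holds the most recent (batch, heads, n, n) attention
    weights as a plain array, for inspection and the row-stochasticity
    checks.
    """

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        if d % heads != 0:
            raise ValueError(f"model dim {d} not divisible by {heads} heads")
        self.d = d
        self.heads = heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.norm = LayerNorm(d)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor, batch: int, n: int) -> Tensor:
        dh = self.d // self.heads
        return x.reshape(batch, n, self.heads, dh).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        batch, n, _ = x.shape
        if pad_mask is not None:
            pad_mask = np.asarray(pad_mask, dtype=bool)
            if (~pad_mask).all(axis=-1).any():
                raise ValueError("a sequence with no attendable position was given")
        q = self._split(self.wq(x), batch, n)
        k = self._split(self.wk(x), batch, n)
        v = self._split(self.wv(x), batch, n)
        dh = self.d // self.heads
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        if pad_mask is not None:
            key_invalid = ~pad_mask[:, None, None, :]  # (B, 1, 1, n)
            scores = scores.masked_fill(np.broadcast_to(key_invalid, scores.shape), -1e9)
        attn = scores.softmax()
        self.last_attention = attn.data.copy()
        out = attn @ v
        out = out.transpose(0, 2, 1, 3).reshape(batch, n, self.d)
        return self.norm(x + self.wo(out))


class TransformerBlock(Module):
    """Post-norm encoder block: MHSA + position-wise feed-forward."""

    def __init__(self, d: int, heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d, heads, rng)
        self.ff1 = Linear(d, d_ff, rng)
        self.ff2 = Linear(d_ff, d, rng)
        self.norm = LayerNorm(d)

    def __call__(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        x = self.attn(x, pad_mask)
        return self.norm(x + self.ff2(self.ff1(x).relu()))


class TextCNN(Module):
    """Multi-width 1-D convolutions with global max pooling.

    One convolution per filter width; each slides over positions with
    stride 1, applies ReLU and max-pools over positions.  Outputs are
    concatenated to a (batch, widths * filters) feature.
    """

    def __init__(self, d: int, widths: list[int], filters: int, rng: np.random.Generator):
        if min(widths) < 2:
            raise ValueError("filter widths must be >= 2")
        self.widths = list(widths)
        self.filters = filters
        self.convs = [Linear(w * d, filters, rng) for w in self.widths]

    def __call__(self, x: Tensor) -> Tensor:
        batch, n, d = x.shape
        if n < max(self.widths):
            raise ValueError(f"sequence length {n} shorter than max filter width {max(self.widths)}")
        outs = []
        for w, conv in zip(self.widths, self.convs):
            # width-w convolution as w shifted matmuls with slices of the
            # (w*d, F) kernel; equivalent to gathering windows, but avoids
            # materializing them
            p = n - w + 1
            acc = None
            for j in range(w):
                term = x[:, j : j + p] @ conv.weight[j * d : (j + 1) * d]
                acc = term if acc is None else acc + term
            outs.append((acc + conv.bias).relu().max(axis=1))
        return concat(outs, axis=-1)


class AdamW:
    """Adam with decoupled weight decay and linear warmup."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        warmup_steps: int = 0,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.warmup_steps = warmup_steps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        lr = self.lr
        if self.warmup_steps > 0:
            lr *= min(1.0, self.t / self.warmup_steps)
        # fold bias correction into the step size (standard Adam identity)
        lr_t = lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            np.multiply(g, g, out=g)  # grad buffer is free after this point
            v *= b2
            v += (1 - b2) * g
            np.sqrt(v, out=g)
            g += self.eps
            np.divide(m, g, out=g)
            g *= lr_t
            p.data -= g
            if self.weight_decay:
                p.data -= lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
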