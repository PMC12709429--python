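"""Neural-network layers built on the autodiff engine.

Contains exactly what the encoder/decoder need: linear and embedding
layers, layer normalization, sinusoidal positional encoding, scaled
dot-product multi-head attention (self and cross), a position-wise
feed-forward block, and an edge-aware graph-attention (GAT) layer whose
attention logits include a learned bond-type term.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, segment_softmax, segment_sum, softmax


class Module:
    """Minimal container: tracks parameter Tensors and submodules."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True):
        super().__init__()
        self.weight = xavier(rng, d_in, d_out)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Embedding(Module):
    def __init__(self, rng, num_embeddings: int, dim: int):
        super().__init__()
        self.weight = Tensor(
            rng.standard_normal((num_embeddings, dim)) / np.sqrt(dim), requires_grad=True
        )

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.int64)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Draws from the RNG passed
    at call time so one seed governs the whole training run."""

    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p <= 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    """Standard fixed sin/cos positional-encoding table, (max_len, dim)."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / dim)
    table = np.zeros((max_len, dim))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


class FeedForward(Module):
    """Position-wise two-layer ReLU block."""

    def __init__(self, rng, dim: int, hidden: int, dropout: float = 0.0):
        super().__init__()
        self.lin1 = Linear(rng, dim, hidden)
        self.lin2 = Linear(rng, hidden, dim)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        return self.lin2(self.drop(self.lin1(x).relu(), rng))


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` heads.

    ``query`` is (B, Lq, d); ``memory`` is (B, Lk, d) (equal to ``query``
    for self-attention).  ``mask`` is an additive (Lq, Lk) array with
    ``-inf``-like entries at disallowed positions (the causal mask).
    """

    def __init__(self, rng, dim: int, n_heads: int, dropout: float = 0.0):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads, self.d_head = n_heads, dim // n_heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)
        self.drop = Dropout(dropout)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, memory: Tensor, mask: np.ndarray | None = None,
                 rng=None) -> Tensor:
        B, Lq, d = query.shape
        Lk = memory.shape[1]
        q = self._split(self.wq(query), B, Lq)
        k = self._split(self.wk(memory), B, Lk)
        v = self._split(self.wv(memory), B, Lk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        if mask is not None:
            scores = scores + mask  # broadcast over batch and heads
        attn = self.drop(softmax(scores, axis=-1), rng)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Lq, d)
        return self.wo(out)


def causal_mask(L: int) -> np.ndarray:
    """(L, L) additive mask forbidding attention to future positions."""
    return np.triu(np.full((L, L), -1e9), k=1)


class GraphAttention(Module):
    """One multi-head GAT layer with bond-type-aware attention.

    For each directed edge (u -> v) and head h, the attention logit is
    ``LeakyReLU(a_src . Wh_u + a_dst . Wh_v + a_edge . e_uv)`` where
    ``e_uv`` embeds the bond-type code; logits are softmax-normalized
    over the in-edges of v and the messages ``Wh_u + e_uv`` aggregated.
    Head outputs (each of width ``dim``) are concatenated and projected
    back to ``dim``.
    """

    LEAKY_SLOPE = 0.2

    def __init__(self, rng, dim: int, n_heads: int, n_edge_types: int, dropout: float = 0.0):
        super().__init__()
        self.n_heads = n_heads
        self.w = [Linear(rng, dim, dim, bias=False) for _ in range(n_heads)]
        self.a_src = [xavier(rng, dim, 1, shape=(dim,)) for _ in range(n_heads)]
        self.a_dst = [xavier(rng, dim, 1, shape=(dim,)) for _ in range(n_heads)]
        self.a_edge = [xavier(rng, dim, 1, shape=(dim,)) for _ in range(n_heads)]
        self.edge_emb = Embedding(rng, n_edge_types, dim)
        self.proj = Linear(rng, n_heads * dim, dim)
        self.drop = Dropout(dropout)
        # parameter lists need explicit registration (they are plain lists
        # of Tensors, not Modules)
        for h in range(n_heads):
            self._params[f"a_src.{h}"] = self.a_src[h]
            self._params[f"a_dst.{h}"] = self.a_dst[h]
            self._params[f"a_edge.{h}"] = self.a_edge[h]

    def __call__(self, x: Tensor, edge_src: np.ndarray, edge_dst: np.ndarray,
                 edge_type: np.ndarray, rng=None) -> Tensor:
        n = x.shape[0]
        e_feat = self.edge_emb(edge_type)
        heads = []
        for h in range(self.n_heads):
            wh = self.w[h](x)
            wh_src, wh_dst = wh[edge_src], wh[edge_dst]
            logits = (
                (wh_src * self.a_src[h]).sum(axis=1)
                + (wh_dst * self.a_dst[h]).sum(axis=1)
                + (e_feat * self.a_edge[h]).sum(axis=1)
            ).leaky_relu(self.LEAKY_SLOPE)
            alpha = segment_softmax(logits, edge_dst, n)
            alpha = self.drop(alpha, rng)
            msg = (wh_src + e_feat) * alpha.reshape(-1, 1)
            heads.append(segment_sum(msg, edge_dst, n))
        out = heads[0] if self.n_heads == 1 else concat(heads, axis=1)
        return self.proj(out)
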