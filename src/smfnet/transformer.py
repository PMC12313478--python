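"""Transformer encoder primitives shared by the text encoder and the
multimodal token-transformer (MTT) blocks: multi-head self-attention plus an
MLP, with residual connections and layer normalization (post-norm)."""

from __future__ import annotations

import numpy as np

from .autodiff import LayerNorm, Linear, Module, Tensor, softmax


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        """x: (B, L, dim); key_mask: (B, L) bool, True where attendable."""
        B, L, _ = x.shape
        h, dh = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(B, L, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                 # (B, h, L, dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(dh))
        if key_mask is not None:
            bias = np.where(key_mask[:, None, None, :], 0.0, -1e9)
            scores = scores + Tensor(bias.astype(scores.data.dtype))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, self.dim)
        return self.proj(out)


class TransformerBlock(Module):
    """Post-norm encoder block: x + MHSA -> LN -> + MLP -> LN."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm1 = LayerNorm(dim)
        self.fc1 = Linear(dim, int(dim * mlp_ratio), rng)
        self.fc2 = Linear(int(dim * mlp_ratio), dim, rng)
        self.norm2 = LayerNorm(dim)

    def forward(self, x: Tensor, key_mask: np.ndarray | None = None) -> Tensor:
        x = self.norm1(x + self.attn(x, key_mask))
        return self.norm2(x + self.fc2(self.fc1(x).relu()))
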