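"""Multi-granularity text encoding.

A report is represented at two granularities: a fine-grained token stream and
a coarse-grained phrase stream obtained from fixed sliding windows of `w`
tokens (default w=2) over the non-pad positions.  Both streams pass through
one shared small transformer-encoder stack (embedding dim 64, 2 layers,
4 heads by default); the pooled vector is the mean of the two streams'
masked means.  An adapter hook accepts externally computed embeddings so a
pretrained multi-granularity language model can be plugged in behind the
same interface.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Embedding, Module, ModuleList, Parameter, Tensor
from .data_io import TextAnnotation
from .transformer import TransformerBlock

PAD, UNK = 0, 1
_TOKEN_RE = re.compile(r"[a-z0-9]+")


class Vocabulary:
    """Token -> id map with pad/unk specials; persisted as JSON."""

    def __init__(self, tokens: list[str]):
        self.itos = ["<pad>", "<unk>"] + list(tokens)
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self):
        return len(self.itos)

    @classmethod
    def build(cls, texts: list[str]) -> "Vocabulary":
        seen: dict[str, None] = {}
        for t in texts:
            for tok in _TOKEN_RE.findall(t.lower()):
                seen.setdefault(tok, None)
        return cls(sorted(seen))

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(self.itos[2:]))

    @classmethod
    def load(cls, path: Path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text()))


def tokenize(text: str, vocab: Vocabulary, max_len: int = 16) -> TextAnnotation:
    """Lowercase, split on non-alphanumerics, map to ids, pad to max_len."""
    if len(vocab) <= 2:
        raise ValueError("empty vocabulary")
    words = _TOKEN_RE.findall(text.lower())
    if len(words) > max_len:
        raise ValueError(f"text has {len(words)} tokens, max is {max_len}")
    ids = np.full(max_len, PAD, dtype=np.int64)
    for i, wtok in enumerate(words):
        ids[i] = vocab.stoi.get(wtok, UNK)
    return TextAnnotation(text=text, token_ids=ids, length=len(words))


def coarse_segment(length: int, w: int = 2) -> list[tuple[int, int]]:
    """Contiguous, non-overlapping [start, end) windows covering the tokens."""
    return [(s, min(s + w, length)) for s in range(0, length, w)]


@dataclass
class MultiGranularEmbedding:
    """Fine- and coarse-grained text streams plus a pooled summary vector."""

    fine: Tensor          # (B, L_f, d)
    coarse: Tensor        # (B, L_c, d)
    pooled: Tensor        # (B, d)
    fine_mask: np.ndarray    # (B, L_f) bool
    coarse_mask: np.ndarray  # (B, L_c) bool


def _masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    m = mask.astype(x.data.dtype)[..., None]
    denom = np.maximum(m.sum(axis=1), 1.0).astype(x.data.dtype)
    return (x * Tensor(m)).sum(axis=1) * Tensor(1.0 / denom)


class TextEncoder(Module):
    """Shared-stack dual-granularity encoder producing x_text."""

    def __init__(self, vocab: Vocabulary, d_text: int = 64, n_layers: int = 2,
                 heads: int = 4, mlp_ratio: float = 2.0, max_len: int = 16,
                 window: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.vocab = vocab
        self.max_len, self.window, self.d_text = max_len, window, d_text
        self.embed = Embedding(len(vocab), d_text, rng)
        self.pos = Parameter(rng.standard_normal((max_len, d_text)) * 0.02)
        self.blocks = ModuleList([TransformerBlock(d_text, heads, mlp_ratio, rng)
                                  for _ in range(n_layers)])
        # adapter hook: callable (texts -> MultiGranularEmbedding) overrides
        # the built-in encoder, allowing pretrained embeddings to be plugged in
        object.__setattr__(self, "external_embedder", None)

    def tokenize_batch(self, texts: list[str]) -> tuple[np.ndarray, np.ndarray]:
        anns = [tokenize(t, self.vocab, self.max_len) for t in texts]
        ids = np.stack([a.token_ids for a in anns])
        lengths = np.array([a.length for a in anns])
        return ids, lengths

    def _encode_stream(self, emb: Tensor, mask: np.ndarray) -> Tensor:
        x = emb
        for blk in self.blocks:
            x = blk(x, key_mask=mask)
        return x

    def forward(self, token_ids: np.ndarray, lengths: np.ndarray
                ) -> MultiGranularEmbedding:
        if self.external_embedder is not None:
            return self.external_embedder(token_ids, lengths)
        B, L = token_ids.shape
        if L > self.max_len:
            raise ValueError(f"sequence length {L} exceeds max {self.max_len}")
        fine_mask = np.arange(L)[None, :] < lengths[:, None]
        base = self.embed(token_ids) + self.pos[:L]

        # fine stream: token-level
        fine = self._encode_stream(base, fine_mask)

        # coarse stream: sliding-window group means of the base embeddings
        w = self.window
        Lc = (self.max_len + w - 1) // w
        G = np.zeros((B, Lc, L), dtype=base.data.dtype)
        coarse_mask = np.zeros((B, Lc), dtype=bool)
        for b in range(B):
            for gi, (s, e) in enumerate(coarse_segment(int(lengths[b]), w)):
                G[b, gi, s:e] = 1.0 / (e - s)
                coarse_mask[b, gi] = True
        coarse_base = Tensor(G) @ base + self.pos[:Lc]
        coarse = self._encode_stream(coarse_base, coarse_mask)

        pooled = (_masked_mean(fine, fine_mask)
                  + _masked_mean(coarse, coarse_mask)) * 0.5
        return MultiGranularEmbedding(fine=fine, coarse=coarse, pooled=pooled,
                                      fine_mask=fine_mask,
                                      coarse_mask=coarse_mask)

    def encode_texts(self, texts: list[str]) -> MultiGranularEmbedding:
        ids, lengths = self.tokenize_batch(texts)
        return self.forward(ids, lengths)
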