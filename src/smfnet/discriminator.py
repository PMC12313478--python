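"""Attention-equipped discriminator scoring (image, predicted-mask) pairs.

The two discriminators of the adversarial framework are built from this one
constructor, so their structural identity is a code-level guarantee.  The
architecture is a strided PatchGAN-style CNN: the image and the K-channel
probability map are concatenated, passed through four stride-2
Conv-LeakyReLU blocks, gated once by a MEAM attention block, globally
average-pooled and mapped to a scalar realness score in (0, 1).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Conv2d, Linear, Module, ModuleList, Tensor, concatenate
from .model import MEAM


class Discriminator(Module):
    def __init__(self, num_classes: int, rng: np.random.Generator,
                 base_channels: int = 16, n_blocks: int = 4):
        super().__init__()
        c_in = 1 + num_classes
        chans = [base_channels * (1 << i) for i in range(n_blocks)]
        blocks = []
        prev = c_in
        for c in chans:
            blocks.append(Conv2d(prev, c, 4, rng, stride=2, padding=1))
            prev = c
        self.blocks = ModuleList(blocks)
        self.attn = MEAM(prev, rng)
        self.fc = Linear(prev, 1, rng)

    def forward(self, image: Tensor, seg_probs: Tensor) -> Tensor:
        """Return per-sample realness scores, shape (B,)."""
        if image.shape[0] != seg_probs.shape[0] or image.shape[2:] != seg_probs.shape[2:]:
            raise ValueError(f"image/probs shape mismatch: {image.shape} "
                             f"vs {seg_probs.shape}")
        x = concatenate([image, seg_probs], axis=1)
        for blk in self.blocks:
            x = blk(x).leaky_relu(0.2)
        x = self.attn(x)
        pooled = x.mean(axis=(2, 3))
        return self.fc(pooled).sigmoid().reshape(x.shape[0])
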