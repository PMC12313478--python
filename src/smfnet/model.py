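"""SMF-Net: dual U-shaped segmentation network fusing image features with
multi-granularity text features.

The network runs two parallel encoders over the input image: a U-shaped CNN
pyramid (Conv-BN-ReLU blocks with max-pool downsampling) and a U-shaped
multimodal token-transformer (MTT) branch.  At every pyramid level the MTT
branch gates the image features with a broadcast text projection (CTBN:
Conv1x1-BN-ReLU on the pooled text vector), flattens the gated map to
spatial tokens, and runs a transformer-encoder block over them.  The up
path mirrors the down path; at each skip connection the CNN and MTT features
are summed and passed through a multimodal enhanced attention module (MEAM)
— parallel channel-wise average/max pooling streams combined into a sigmoid
gate that multiplies the features — before the CNN decoder consumes them.
A final 1x1 convolution produces per-class logits at full resolution.

Architecture hyperparameters (channel widths, transformer dims) follow
U-Net convention (64-128-256-512) with small presets for CPU-scale work;
`use_text` / `use_meam` / `use_mtt` flags switch the corresponding sub-paths
off for ablations without touching anything else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import (BatchNorm2d, Conv2d, Linear, Module, ModuleList,
                       Tensor, maxpool2d, maxpool3x3_s1, softmax,
                       upsample_nearest)
from .text import MultiGranularEmbedding, TextEncoder, Vocabulary
from .transformer import TransformerBlock


@dataclass
class ModelConfig:
    depth: int = 4
    base_channels: int = 64
    num_classes: int = 3
    vit_dim: int = 64
    vit_heads: int = 4
    mlp_ratio: float = 2.0
    d_text: int = 64
    text_layers: int = 2
    text_heads: int = 4
    max_text_len: int = 16
    use_text: bool = True
    use_meam: bool = True
    use_mtt: bool = True
    meam_pool_axis: str = "channel"    # or "spatial" (global-pool variant)
    mtt_skip_image: bool = True        # the +x_img term of the down chain

    def channels(self) -> list[int]:
        return [self.base_channels * (1 << i) for i in range(self.depth)]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


def tiny_config(**overrides) -> ModelConfig:
    """CPU-scale preset: 32x32 inputs, C=16, ViT dim 64, 2 attention heads."""
    cfg = ModelConfig(base_channels=16, vit_dim=64, vit_heads=2, d_text=64)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def nano_config(**overrides) -> ModelConfig:
    """Smallest preset used for repeated training studies."""
    cfg = ModelConfig(base_channels=8, vit_dim=32, vit_heads=2, d_text=32,
                      text_heads=2, text_layers=1)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def paper_config(**overrides) -> ModelConfig:
    """Full-size preset (256x256 inputs, C=64) for users with hardware."""
    cfg = ModelConfig(base_channels=64)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


PRESETS = {"tiny": tiny_config, "nano": nano_config, "paper": paper_config}


@dataclass
class SegOutput:
    """Per-pixel class scores over the image grid."""

    logits: Tensor    # (B, K, H, W)
    probs: Tensor     # softmax over K


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

class ConvBlock(Module):
    """Two Conv3x3 -> BN -> ReLU stages."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng, padding=1)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, padding=1)
        self.bn2 = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class DownCNNStage(Module):
    """One encoder step: ConvBlock (channels double) then 2x2 max-pool."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.block = ConvBlock(c_in, c_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2:]
        if h % 2 or w % 2:
            raise ValueError(f"down_cnn needs even spatial dims, got {(h, w)}")
        return maxpool2d(self.block(x), 2)


class UpConv(Module):
    """Nearest-neighbour x2 upsampling followed by Conv3x3 (checkerboard-safe)."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(upsample_nearest(x, 2))


class CTBN(Module):
    """Project the pooled text vector to C channels, broadcast it over the
    spatial grid, then Conv1x1 -> BN -> ReLU."""

    def __init__(self, d_text: int, c: int, rng):
        super().__init__()
        self.proj = Linear(d_text, c, rng)
        self.conv = Conv2d(c, c, 1, rng)
        self.bn = BatchNorm2d(c)

    def forward(self, pooled_text: Tensor, hw: tuple[int, int]) -> Tensor:
        B, _ = pooled_text.shape
        t = self.proj(pooled_text)
        t = t.reshape(B, t.shape[1], 1, 1) + Tensor(
            np.zeros((1, 1) + tuple(hw), dtype=t.data.dtype))
        return self.bn(self.conv(t)).relu()


class MEAM(Module):
    """Multimodal enhanced attention: X * sigmoid(CLAB[PM(AP)+PM(MP)+PM(AP+MP)]).

    AP/MP pool over the channel axis by default (spatial-attention style, so
    the gate broadcasts across channels); the "spatial" variant pools
    globally over the grid instead (channel-attention style).
    """

    def __init__(self, c: int, rng, pool_axis: str = "channel"):
        super().__init__()
        if pool_axis not in ("channel", "spatial"):
            raise ValueError(f"unknown MEAM pool axis {pool_axis!r}")
        self.pool_axis = pool_axis
        self.conv = Conv2d(c, c, 3, rng, padding=1)
        gate_c = 1 if pool_axis == "channel" else c
        self.clab = Conv2d(gate_c, gate_c, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        f = self.conv(x).relu()
        if self.pool_axis == "channel":
            ap = f.mean(axis=1, keepdims=True)
            mp = f.amax(axis=1, keepdims=True)
            s1 = maxpool3x3_s1(ap)
            s2 = maxpool3x3_s1(mp)
            s3 = maxpool3x3_s1(ap + mp)
        else:
            ap = f.mean(axis=(2, 3), keepdims=True)
            mp = f.amax(axis=-1, keepdims=True).amax(axis=-2, keepdims=True)
            s1, s2, s3 = ap, mp, ap + mp
        gate = self.clab(s1 + s2 + s3).sigmoid()
        return x * gate


_POS_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def sincos_position_encoding(h: int, w: int, dim: int) -> np.ndarray:
    """Fixed 2-D sine/cosine position table (h*w, dim), ViT-style: half the
    channels encode the row coordinate, half the column."""
    key = (h, w, dim)
    if key not in _POS_CACHE:
        def axis_enc(n, d):
            pos = np.arange(n)[:, None]
            i = np.arange(d // 2)[None, :]
            freq = pos / (10000.0 ** (2 * i / d))
            return np.concatenate([np.sin(freq), np.cos(freq)], axis=1)
        d2 = dim // 2
        rows = axis_enc(h, d2)                        # (h, d2)
        cols = axis_enc(w, dim - d2)                  # (w, dim - d2)
        grid = np.concatenate(
            [np.repeat(rows, w, axis=0), np.tile(cols, (h, 1))], axis=1)
        _POS_CACHE[key] = grid.astype(np.float32)
    return _POS_CACHE[key]


class MTTBlock(Module):
    """One multimodal token-transformer fusion at a pyramid level.

    Elementwise product of image features with the CTBN text map, flattened
    to h*w spatial tokens, projected to the transformer width, tagged with a
    fixed 2-D sine/cosine position encoding, passed through one encoder
    block, projected back and reshaped.
    """

    def __init__(self, c: int, d_text: int, vit_dim: int, heads: int,
                 mlp_ratio: float, rng):
        super().__init__()
        self.ctbn = CTBN(d_text, c, rng)
        self.to_tokens = Linear(c, vit_dim, rng)
        self.block = TransformerBlock(vit_dim, heads, mlp_ratio, rng)
        self.from_tokens = Linear(vit_dim, c, rng)

    def forward(self, img_feat: Tensor, text: MultiGranularEmbedding | None,
                use_text: bool) -> Tensor:
        B, C, h, w = img_feat.shape
        if use_text and text is not None:
            pooled = text.pooled
        else:
            pooled = Tensor(np.zeros((B, self.ctbn.proj.weight.shape[0]),
                                     dtype=img_feat.data.dtype))
        gate = self.ctbn(pooled, (h, w))
        z = img_feat * gate
        tokens = z.reshape(B, C, h * w).transpose(0, 2, 1)
        pos = Tensor(sincos_position_encoding(h, w, self.block.attn.dim))
        tokens = self.from_tokens(self.block(self.to_tokens(tokens) + pos))
        return tokens.transpose(0, 2, 1).reshape(B, C, h, w)


class ChannelLift(Module):
    """2x2 max-pool then Conv1x1 channel expansion (MTT down-chain step)."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(maxpool2d(x, 2))


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

class SMFNet(Module):
    """Dual U-shaped text-guided segmentation network."""

    def __init__(self, cfg: ModelConfig, vocab: Vocabulary,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        ch = cfg.channels()
        d = cfg.depth

        self.text_encoder = TextEncoder(
            vocab, d_text=cfg.d_text, n_layers=cfg.text_layers,
            heads=cfg.text_heads, mlp_ratio=cfg.mlp_ratio,
            max_len=cfg.max_text_len, rng=rng)

        self.stem = ConvBlock(1, ch[0], rng)
        self.down_cnn = ModuleList([DownCNNStage(ch[i], ch[i + 1], rng)
                                    for i in range(d - 1)])

        self.down_mtt = ModuleList([
            MTTBlock(ch[i], cfg.d_text, cfg.vit_dim, cfg.vit_heads,
                     cfg.mlp_ratio, rng) for i in range(d)])
        self.mtt_lift = ModuleList([ChannelLift(ch[i], ch[i + 1], rng)
                                    for i in range(d - 1)])

        self.up_mtt_conv = ModuleList([UpConv(ch[i + 1], ch[i], rng)
                                       for i in range(d - 1)])
        self.up_mtt_block = ModuleList([
            MTTBlock(ch[i], cfg.d_text, cfg.vit_dim, cfg.vit_heads,
                     cfg.mlp_ratio, rng) for i in range(d - 1)])

        self.meam = ModuleList([MEAM(ch[i], rng, cfg.meam_pool_axis)
                                for i in range(d)])

        self.up_cnn_conv = ModuleList([UpConv(ch[i + 1], ch[i], rng)
                                       for i in range(d - 1)])
        self.up_cnn_block = ModuleList([ConvBlock(ch[i], ch[i], rng)
                                        for i in range(d - 1)])
        self.head = Conv2d(ch[0], cfg.num_classes, 1, rng)

    # ---- pieces ----------------------------------------------------------
    def cnn_pyramid(self, x: Tensor) -> list[Tensor]:
        feats = [self.stem(x)]
        for stage in self.down_cnn:
            feats.append(stage(feats[-1]))
        return feats

    def mtt_chain(self, pyramid: list[Tensor],
                  text: MultiGranularEmbedding | None) -> list[Tensor]:
        use_text = self.cfg.use_text
        out = [self.down_mtt[0](pyramid[0], text, use_text)]
        for i in range(1, self.cfg.depth):
            carried = self.mtt_lift[i - 1](out[-1])
            x = carried + pyramid[i] if self.cfg.mtt_skip_image else carried
            out.append(self.down_mtt[i](x, text, use_text))
        return out

    def mtt_up_path(self, mtt_feats: list[Tensor],
                    text: MultiGranularEmbedding | None) -> list[Tensor]:
        d = self.cfg.depth
        up = [None] * d
        up[d - 1] = mtt_feats[d - 1]
        for i in range(d - 2, -1, -1):
            x = self.up_mtt_conv[i](up[i + 1]) + mtt_feats[i]
            up[i] = self.up_mtt_block[i](x, text, self.cfg.use_text)
        return up

    # ---- forward ---------------------------------------------------------
    def forward(self, x: Tensor, texts: list[str] | None = None,
                text_emb: MultiGranularEmbedding | None = None) -> SegOutput:
        h, w = x.shape[2:]
        if h % (1 << self.cfg.depth) or w % (1 << self.cfg.depth):
            raise ValueError(
                f"input dims {(h, w)} not divisible by 2^{self.cfg.depth}")
        if text_emb is None and texts is not None and self.cfg.use_text:
            text_emb = self.text_encoder.encode_texts(texts)

        pyramid = self.cnn_pyramid(x)

        if self.cfg.use_mtt:
            mtt_down = self.mtt_chain(pyramid, text_emb)
            mtt_up = self.mtt_up_path(mtt_down, text_emb)
            skips = [pyramid[i] + mtt_up[i] for i in range(self.cfg.depth)]
        else:
            skips = list(pyramid)

        if self.cfg.use_meam:
            skips = [self.meam[i](skips[i]) for i in range(self.cfg.depth)]

        y = skips[-1]
        for i in range(self.cfg.depth - 2, -1, -1):
            y = self.up_cnn_block[i](self.up_cnn_conv[i](y) + skips[i])
        logits = self.head(y)
        return SegOutput(logits=logits, probs=softmax(logits, axis=1))

    def predict(self, x: Tensor, texts: list[str] | None = None) -> SegOutput:
        """Evaluation-mode forward (deterministic; no graph)."""
        from .autodiff import no_grad
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                return self.forward(x, texts)
        finally:
            self.train(was_training)


# ---------------------------------------------------------------------------
# Checkpoints: single-file .npz archive holding config + vocab + parameters
# ---------------------------------------------------------------------------

def save_checkpoint(path: Path, model: SMFNet) -> None:
    state = model.state_dict()
    meta = {"config": asdict(model.cfg), "vocab": model.text_encoder.vocab.itos[2:]}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: Path) -> SMFNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"])
    vocab = Vocabulary(meta["vocab"])
    model = SMFNet(cfg, vocab, np.random.default_rng(0))
    model.load_state_dict(state)
    return model
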