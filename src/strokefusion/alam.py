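"""The image branch: patch embedding, global attention block (GAB),
local attention block (LAB), their combination (GLAM), and multi-scale
joint-feature fusion over a VGG16-style backbone, producing the image
feature vector F1.

The global block is a pre-norm transformer layer over patch tokens:

    X' = X + MHSA(LN(X))        Fg = X' + MLP(LN(X'))

The local block applies sigmoid channel attention strictly before
sigmoid spatial attention:

    F' = Att_c(F) o F           Fl = Att_s(F') o F'

GLAM runs both on the same feature map, maps the token sequence back to
a spatial map, and fuses by elementwise sum followed by a 1x1
convolutional projection (the combination rule itself is a declared
design choice; the two blocks follow the published equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, Dropout, LayerNorm, Linear,
                 Module, MultiheadSelfAttention, Tensor, concat, conv2d,
                 max_pool2x2, upsample2x)

__all__ = ["FeatureMap", "FeatureSequence", "AttentionMaps", "GlamOutput",
           "ImageBranchConfig", "PatchEmbed", "patchify", "unpatchify",
           "GlobalAttentionBlock", "LocalAttentionBlock", "Glam",
           "VggBackbone", "MultiScaleImageBranch"]


# ---------------------------------------------------------------------------
# light array-level domain types (API/test surface; modules run batched)

@dataclass
class FeatureMap:
    values: np.ndarray            # (C, H, W)
    scale_id: int = 0

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("FeatureMap expects a C x H x W array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMap contains non-finite values")


@dataclass
class FeatureSequence:
    tokens: np.ndarray            # (D, L)
    patch_size: int
    source_hw: tuple[int, int]

    def __post_init__(self):
        h, w = self.source_hw
        expect = (h * w) // self.patch_size ** 2
        if self.tokens.shape[1] != expect:
            raise ValueError(
                f"token count {self.tokens.shape[1]} != HW/P^2 = {expect}")


@dataclass
class AttentionMaps:
    channel_mask: np.ndarray      # (C, 1, 1), entries in (0, 1)
    spatial_mask: np.ndarray      # (1, H, W), entries in (0, 1)


@dataclass
class GlamOutput:
    global_feature: np.ndarray    # (D, L) token sequence Fg
    local_feature: np.ndarray     # (C, H, W) Fl
    joint_feature: np.ndarray     # (C, H, W)


# ---------------------------------------------------------------------------
# patch embedding

def _to_patches(x: Tensor, p: int) -> Tensor:
    """(N, C, H, W) -> (N, L, P*P*C) with L = HW/P^2."""
    n, c, h, w = x.shape
    if h % p:
        raise ValueError(f"height {h} not divisible by patch size {p}")
    if w % p:
        raise ValueError(f"width {w} not divisible by patch size {p}")
    x = x.reshape(n, c, h // p, p, w // p, p)
    x = x.transpose(0, 2, 4, 1, 3, 5)          # (N, h/p, w/p, C, p, p)
    return x.reshape(n, (h // p) * (w // p), c * p * p)


def _from_patches(x: Tensor, p: int, c: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`_to_patches`."""
    n = x.shape[0]
    x = x.reshape(n, h // p, w // p, c, p, p)
    x = x.transpose(0, 3, 1, 4, 2, 5)
    return x.reshape(n, c, h, w)


class PatchEmbed(Module):
    """Flatten P x P patches and project them to D dims, then add
    learnable 1-D positional embeddings."""

    def __init__(self, in_ch: int, patch_size: int, embed_dim: int,
                 n_tokens: int, rng: np.random.Generator):
        super().__init__()
        self.patch_size = patch_size
        self.proj = Linear(in_ch * patch_size ** 2, embed_dim, rng)
        self.pos = Tensor(rng.normal(0.0, 0.02, (n_tokens, embed_dim)),
                          requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        tokens = self.proj(_to_patches(x, self.patch_size))
        return tokens + self.pos


def patchify(feature: FeatureMap, patch_size: int, embed_dim: int,
             rng: np.random.Generator | None = None,
             embed: PatchEmbed | None = None) -> FeatureSequence:
    """Array-level patch embedding of one feature map (test/API surface)."""
    c, h, w = feature.values.shape
    if embed is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        embed = PatchEmbed(c, patch_size, embed_dim,
                           (h // patch_size) * (w // patch_size), rng)
    x = Tensor(feature.values[None])
    tokens = embed(x).data[0]                   # (L, D)
    return FeatureSequence(tokens=tokens.T, patch_size=patch_size,
                           source_hw=(h, w))


def unpatchify(tokens: np.ndarray, patch_size: int, channels: int,
               source_hw: tuple[int, int]) -> np.ndarray:
    """(P*P*C, L) token array -> (C, H, W); inverse of identity patchify."""
    h, w = source_hw
    t = Tensor(tokens.T[None])                  # (1, L, P*P*C)
    return _from_patches(t, patch_size, channels, h, w).data[0]


# ---------------------------------------------------------------------------
# attention blocks

class GlobalAttentionBlock(Module):
    """Pre-norm transformer block over (N, L, D) tokens."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 4, zero_sublayers: bool = False):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng,
                                           zero_out=zero_sublayers)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng,
                          zero_init=zero_sublayers)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.fc2(self.fc1(self.ln2(x)).relu())


class ChannelAttention(Module):
    """Shared bottleneck over average- and max-pooled channel
    descriptors; sigmoid output of shape (N, C, 1, 1)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))               # (N, C)
        mx = x.amax(axis=(2, 3))
        logits = (self.fc2(self.fc1(avg).relu())
                  + self.fc2(self.fc1(mx).relu()))
        n, c = logits.shape
        return logits.sigmoid().reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """7x7 convolution over channelwise mean/max maps; sigmoid output of
    shape (N, 1, H, W)."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)     # (N, 1, H, W)
        mx = x.amax(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()


class LocalAttentionBlock(Module):
    """Sequential channel-then-spatial sigmoid attention."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 16):
        super().__init__()
        self.channel = ChannelAttention(channels, rng, reduction)
        self.spatial = SpatialAttention(rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (Fl, channel mask, spatial mask)."""
        att_c = self.channel(x)
        f_prime = att_c * x
        att_s = self.spatial(f_prime)
        return att_s * f_prime, att_c, att_s


class Glam(Module):
    """Global-local attention at one scale.

    The token sequence from the global path is projected back to
    patch-pixel space and un-patchified to a (C, H, W) map, then fused
    with the local path by elementwise sum + 1x1 conv projection.
    """

    def __init__(self, channels: int, hw: tuple[int, int], patch_size: int,
                 embed_dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        h, w = hw
        self.channels, self.hw, self.patch_size = channels, hw, patch_size
        n_tokens = (h // patch_size) * (w // patch_size)
        self.embed = PatchEmbed(channels, patch_size, embed_dim, n_tokens, rng)
        self.gab = GlobalAttentionBlock(embed_dim, heads, rng)
        self.to_map = Linear(embed_dim, channels * patch_size ** 2, rng)
        self.lab = LocalAttentionBlock(channels, rng)
        self.fuse = Conv2d(channels, channels, 1, rng, padding=0)
        self._last: dict[str, Tensor] = {}

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        tokens = self.gab(self.embed(x))                    # (N, L, D)
        fg_map = _from_patches(self.to_map(tokens), self.patch_size, c, h, w)
        fl, att_c, att_s = self.lab(x)
        joint = self.fuse(fg_map + fl)
        self._last = {"tokens": tokens, "fg_map": fg_map, "fl": fl,
                      "att_c": att_c, "att_s": att_s, "joint": joint}
        return joint

    def run(self, feature: FeatureMap) -> GlamOutput:
        """Array-level single-sample forward (API/test surface)."""
        out = self.forward(Tensor(feature.values[None]))
        last = self._last
        return GlamOutput(global_feature=last["tokens"].data[0].T,
                          local_feature=last["fl"].data[0],
                          joint_feature=out.data[0])


# ---------------------------------------------------------------------------
# backbone + multi-scale branch

@dataclass(frozen=True)
class ImageBranchConfig:
    """Architecture of the image branch.

    ``stage_widths`` are the five VGG-style stage channel counts;
    ``taps`` index the stages whose (pre-pool) conv outputs feed the
    multi-scale head. With ``multiscale=False`` only the deepest tap is
    used; with ``glam=False`` the attention modules are identity.
    """

    image_size: int = 224
    stage_widths: tuple[int, ...] = (64, 128, 256, 512, 512)
    convs_per_stage: int = 2
    taps: tuple[int, ...] = (2, 3, 4)
    patch_size: int = 2
    embed_dim: int = 256
    heads: int = 4
    multiscale: bool = True
    glam: bool = True

    def tap_hw(self, stage: int) -> int:
        return self.image_size // (2 ** stage)

    def validate(self) -> None:
        for s in self.taps:
            hw = self.tap_hw(s)
            if hw < self.patch_size or hw % self.patch_size:
                raise ValueError(
                    f"stage {s} feature size {hw} incompatible with patch "
                    f"size {self.patch_size} at image size {self.image_size}")

    @property
    def feature_dim(self) -> int:
        taps = self.taps if self.multiscale else self.taps[-1:]
        return sum(self.stage_widths[s] for s in taps)


class VggBackbone(Module):
    """Stacked [Conv3x3 + ReLU] x n + MaxPool stages; exposes the conv
    output of each requested stage before its pooling layer."""

    def __init__(self, config: ImageBranchConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        in_ch = 3
        self.convs: list[list[Conv2d]] = []
        for si, width in enumerate(config.stage_widths):
            stage = []
            for ci in range(config.convs_per_stage):
                conv = Conv2d(in_ch, width, 3, rng)
                setattr(self, f"s{si}c{ci}", conv)
                stage.append(conv)
                in_ch = width
            self.convs.append(stage)

    def forward(self, x: Tensor) -> list[Tensor]:
        taps = []
        max_stage = max(self.config.taps)
        for si, stage in enumerate(self.convs[:max_stage + 1]):
            for conv in stage:
                x = conv(x).relu()
            if si in self.config.taps:
                taps.append(x)
            if si < max_stage:
                x = max_pool2x2(x)
        return taps


class MultiScaleImageBranch(Module):
    """Backbone taps -> (top-down propagation) -> GLAM per scale ->
    global average pooling -> concatenated image feature vector F1."""

    def __init__(self, config: ImageBranchConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.backbone = VggBackbone(config, rng)
        taps = config.taps if config.multiscale else config.taps[-1:]
        self.active_taps = taps
        if config.glam:
            for s in taps:
                hw = config.tap_hw(s)
                setattr(self, f"glam{s}", Glam(
                    config.stage_widths[s], (hw, hw), config.patch_size,
                    config.embed_dim, config.heads, rng))
        if config.multiscale:
            # lateral projections: deeper joint feature -> shallower width
            for deep, shallow in zip(taps[1:], taps[:-1]):
                setattr(self, f"lateral{deep}to{shallow}", Conv2d(
                    config.stage_widths[deep], config.stage_widths[shallow],
                    1, rng, padding=0))
        self.activations: dict[str, Tensor] = {}

    def forward(self, x: Tensor) -> Tensor:
        all_taps = self.backbone(x)
        by_stage = dict(zip(self.config.taps, all_taps))
        for s, t in by_stage.items():
            self.activations[f"stage{s}"] = t
        feats = {s: by_stage[s] for s in self.active_taps}

        joints: dict[int, Tensor] = {}
        for s in reversed(self.active_taps):          # deepest first
            f = feats[s]
            deeper = [d for d in self.active_taps if d > s]
            if deeper and self.config.multiscale:
                d = min(deeper)
                lateral = getattr(self, f"lateral{d}to{s}")
                f = f + lateral(upsample2x(joints[d]))
            if self.config.glam:
                joint = getattr(self, f"glam{s}")(f)
            else:
                joint = f
            joints[s] = joint
            self.activations[f"joint{s}"] = joint

        pooled = [joints[s].mean(axis=(2, 3)) for s in self.active_taps]
        return concat(pooled, axis=1) if len(pooled) > 1 else pooled[0]

    def layer_names(self) -> list[str]:
        """Valid saliency target layers: backbone stage taps and the
        per-scale joint features, shallow to deep (joints last, so the
        default deepest-joint target is the final entry)."""
        return ([f"stage{s}" for s in self.config.taps]
                + [f"joint{s}" for s in self.active_taps])
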