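"""The 3D CNN branch, 3D ViT branch and the fused multichannel classifier.

Architecture defaults match the published configuration: the CNN feature
extractor has 7 convolution blocks (conv -> ReLU -> batch-norm), the first
with kernel 3 / stride 1 and the remaining six downsampling with kernel 4 /
stride 2 at widths 16, 32, 64, 128, 256, 512, followed by global average
pooling and a fully connected layer to a 768-dim feature vector.  The ViT
encoder embeds non-overlapping 16^3 patches, prepends a learned
classification token, adds learned position embeddings, and applies 12
pre-norm transformer blocks of hidden dimension 768 with 6-head
self-attention; the classification-token embedding is the branch output.
In ``concat`` fusion both feature vectors are concatenated into a single
fully connected layer with sigmoid activation.

The stated block count (7) together with six filter widths is resolved by
letting the stride-1 stem share the first width (16) with the first
downsampling block; this reproduces both statements and yields a valid
shape chain for 256 x 256 x 64 inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import (
    AdamW, BatchNorm3d, Conv3d, GlobalAvgPool3d, Linear, Module, ReLU,
    Sequential, TransformerBlock, LayerNorm, sigmoid,
)

FUSION_MODES = ("cnn_only", "vit_only", "concat")


@dataclass
class EnsembleConfig:
    """All architecture hyperparameters; defaults are the full-scale network."""

    input_channels: int = 2
    input_shape: Tuple[int, int, int] = (256, 256, 64)
    cnn_filters: Tuple[int, ...] = (16, 32, 64, 128, 256, 512)
    cnn_first_kernel: int = 3
    cnn_down_kernel: int = 4
    cnn_feature_dim: int = 768
    vit_patch_edge: int = 16
    vit_depth: int = 12
    vit_dim: int = 768
    vit_heads: int = 6
    vit_mlp_ratio: int = 4
    fusion: str = "concat"
    #: paper block order conv->ReLU->BN; set True for the conventional conv->BN->ReLU
    bn_before_act: bool = False
    dtype: str = "float64"

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(d) for d in self.input_shape)
        self.cnn_filters = tuple(int(f) for f in self.cnn_filters)
        if self.input_channels not in (1, 2):
            raise ValueError("input_channels must be 1 or 2")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"fusion must be one of {FUSION_MODES}")
        if not self.cnn_filters or list(self.cnn_filters) != sorted(self.cnn_filters):
            raise ValueError("cnn_filters must be nonempty and ascending")
        if self.vit_dim % self.vit_heads:
            raise ValueError("vit_dim must be divisible by vit_heads")
        if self.fusion != "cnn_only":
            for d in self.input_shape:
                if d % self.vit_patch_edge:
                    raise ValueError(
                        f"input_shape {self.input_shape} not divisible by "
                        f"vit_patch_edge {self.vit_patch_edge}"
                    )
        if self.fusion != "vit_only":
            # every stride-2 block halves each axis; audit the whole chain
            for d in self.conv_shape_chain()[-1]:
                if d < 1:
                    raise ValueError(
                        f"input_shape {self.input_shape} not divisible through "
                        f"{len(self.cnn_filters)} stride-2 blocks"
                    )

    def conv_shape_chain(self) -> List[Tuple[int, int, int]]:
        """Spatial shape after the stem and after each downsampling block."""
        chain = [self.input_shape]
        cur = self.input_shape
        for _ in self.cnn_filters:
            if any(d % 2 for d in cur):
                raise ValueError(f"odd spatial shape {cur} cannot be halved")
            cur = tuple(d // 2 for d in cur)
            chain.append(cur)
        return chain

    def vit_grid(self) -> Tuple[int, int, int]:
        p = self.vit_patch_edge
        return tuple(d // p for d in self.input_shape)

    def n_tokens(self) -> int:
        """Token count including the classification token."""
        return 1 + int(np.prod(self.vit_grid()))

    def fusion_width(self) -> int:
        if self.fusion == "cnn_only":
            return self.cnn_feature_dim
        if self.fusion == "vit_only":
            return self.vit_dim
        return self.cnn_feature_dim + self.vit_dim

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BranchOutput:
    feature_vector: np.ndarray  # (B, dim)
    attentions: Optional[List[np.ndarray]] = None  # per layer, (B, heads, T, T)


class CNNBranch(Module):
    """Stem + six downsampling conv blocks, global average pool, FC head."""

    def __init__(self, cfg: EnsembleConfig, rng: np.random.Generator):
        dtype = cfg.np_dtype
        blocks = []
        c_in = cfg.input_channels
        widths = [cfg.cnn_filters[0]] + list(cfg.cnn_filters)
        kernels = [cfg.cnn_first_kernel] + [cfg.cnn_down_kernel] * len(cfg.cnn_filters)
        strides = [1] + [2] * len(cfg.cnn_filters)
        for i, (w, k, s) in enumerate(zip(widths, kernels, strides)):
            pad = 1  # keeps shape for k3/s1 and halves exactly for k4/s2
            layers = [Conv3d(c_in, w, k, s, pad, rng, dtype=dtype, name=f"conv{i}")]
            if cfg.bn_before_act:
                layers += [BatchNorm3d(w, dtype=dtype, name=f"bn{i}"), ReLU()]
            else:
                layers += [ReLU(), BatchNorm3d(w, dtype=dtype, name=f"bn{i}")]
            blocks.append(Sequential(layers))
            c_in = w
        self.blocks = blocks
        self.pool = GlobalAvgPool3d()
        self.fc = Linear(widths[-1], cfg.cnn_feature_dim, rng, dtype=dtype, name="cnn_fc")
        self.block_outputs: List[np.ndarray] = []
        self.block_grads: List[Optional[np.ndarray]] = []

    def forward(self, x, train: bool = False):
        self.block_outputs = []
        for b in self.blocks:
            x = b.forward(x, train=train)
            self.block_outputs.append(x)
        return self.fc.forward(self.pool.forward(x, train=train), train=train)

    def backward(self, dy):
        dx = self.pool.backward(self.fc.backward(dy))
        self.block_grads = [None] * len(self.blocks)
        for i in reversed(range(len(self.blocks))):
            self.block_grads[i] = dx  # grad w.r.t. block i's output feature map
            dx = self.blocks[i].backward(dx)
        return dx

    def forward_from(self, block_index: int, feature_map: np.ndarray) -> np.ndarray:
        """Re-run the head from a (possibly perturbed) block output."""
        x = feature_map
        for b in self.blocks[block_index + 1 :]:
            x = b.forward(x, train=False)
        return self.fc.forward(self.pool.forward(x, train=False), train=False)


class ViTBranch(Module):
    """3D patch embedding + class token + pre-norm transformer encoder."""

    def __init__(self, cfg: EnsembleConfig, rng: np.random.Generator):
        dtype = cfg.np_dtype
        self.cfg = cfg
        p = cfg.vit_patch_edge
        self.grid = cfg.vit_grid()
        n_patch = int(np.prod(self.grid))
        in_dim = cfg.input_channels * p**3
        self.embed = Linear(in_dim, cfg.vit_dim, rng, dtype=dtype, name="patch_embed")
        self.cls = nn.Param(
            (rng.standard_normal((1, 1, cfg.vit_dim)) * 0.02).astype(dtype),
            decay=False, name="cls_token",
        )
        self.pos = nn.Param(
            (rng.standard_normal((1, n_patch + 1, cfg.vit_dim)) * 0.02).astype(dtype),
            decay=False, name="pos_embed",
        )
        self.blocks = [
            TransformerBlock(cfg.vit_dim, cfg.vit_heads, rng,
                             mlp_ratio=cfg.vit_mlp_ratio, dtype=dtype, name=f"vit{i}")
            for i in range(cfg.vit_depth)
        ]
        self.norm = LayerNorm(cfg.vit_dim, dtype=dtype, name="vit_norm")

    def patchify(self, x: np.ndarray) -> np.ndarray:
        """(B, C, D, H, W) -> (B, n_patches, C * p^3) in grid raster order."""
        B, C, D, H, W = x.shape
        p = self.cfg.vit_patch_edge
        gd, gh, gw = D // p, H // p, W // p
        t = x.reshape(B, C, gd, p, gh, p, gw, p)
        t = t.transpose(0, 2, 4, 6, 1, 3, 5, 7)
        return t.reshape(B, gd * gh * gw, C * p**3)

    def unpatchify_grad(self, dt: np.ndarray, x_shape) -> np.ndarray:
        B, C, D, H, W = x_shape
        p = self.cfg.vit_patch_edge
        gd, gh, gw = D // p, H // p, W // p
        t = dt.reshape(B, gd, gh, gw, C, p, p, p)
        return t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(B, C, D, H, W)

    def forward(self, x, train: bool = False):
        self._x_shape = x.shape
        B = x.shape[0]
        tokens = self.embed.forward(self.patchify(x), train=train)
        cls = np.broadcast_to(self.cls.value, (B, 1, self.cfg.vit_dim))
        seq = np.concatenate([cls, tokens], axis=1) + self.pos.value
        for blk in self.blocks:
            seq = blk.forward(seq, train=train)
        seq = self.norm.forward(seq, train=train)
        self._T = seq.shape[1]
        return seq[:, 0]

    def backward(self, dy):
        B = dy.shape[0]
        dseq = np.zeros((B, self._T, self.cfg.vit_dim), dtype=dy.dtype)
        dseq[:, 0] = dy
        dseq = self.norm.backward(dseq)
        for blk in reversed(self.blocks):
            dseq = blk.backward(dseq)
        self.pos.grad += dseq.sum(axis=0, keepdims=True)
        self.cls.grad += dseq[:, :1].sum(axis=0, keepdims=True)
        dtokens = self.embed.backward(dseq[:, 1:])
        return self.unpatchify_grad(dtokens, self._x_shape)

    def attentions(self) -> List[np.ndarray]:
        """Per-layer attention tensors (B, heads, T, T) from the last forward."""
        return [blk.attn.last_attention for blk in self.blocks]


class EnsembleModel(Module):
    """CNN branch, ViT branch (per fusion mode) and the sigmoid fusion head."""

    def __init__(self, cfg: EnsembleConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.cnn = CNNBranch(cfg, rng) if cfg.fusion != "vit_only" else None
        self.vit = ViTBranch(cfg, rng) if cfg.fusion != "cnn_only" else None
        self.head = Linear(cfg.fusion_width(), 1, rng, dtype=cfg.np_dtype, name="head")

    def features(self, x, train: bool = False) -> np.ndarray:
        parts = []
        if self.cnn is not None:
            parts.append(self.cnn.forward(x, train=train))
        if self.vit is not None:
            parts.append(self.vit.forward(x, train=train))
        return np.concatenate(parts, axis=1)

    def logits(self, x, train: bool = False) -> np.ndarray:
        z = self.features(x, train=train)
        self._feat_dim_cnn = self.cfg.cnn_feature_dim if self.cnn is not None else 0
        return self.head.forward(z, train=train)[:, 0]

    def forward(self, x, train: bool = False):
        """Class-1 probability per input volume, strictly inside (0, 1)."""
        return sigmoid(self.logits(x, train=train))

    def backward(self, dlogits):
        dz = self.head.backward(dlogits[:, None])
        dx = None
        if self.cnn is not None:
            dx = self.cnn.backward(dz[:, : self._feat_dim_cnn])
        if self.vit is not None:
            dvx = self.vit.backward(dz[:, self._feat_dim_cnn :])
            dx = dvx if dx is None else dx + dvx
        return dx


# --- spec-level operation wrappers -----------------------------------------


def cnn_forward(x: np.ndarray, cfg: EnsembleConfig, seed: int = 0) -> BranchOutput:
    """Feature vector of the CNN branch for a single multichannel volume."""
    branch = CNNBranch(cfg, np.random.default_rng(seed))
    vec = branch.forward(x[None] if x.ndim == 4 else x, train=False)
    return BranchOutput(feature_vector=vec)


def vit_forward(x: np.ndarray, cfg: EnsembleConfig, seed: int = 0) -> BranchOutput:
    """Class-token embedding and per-layer attentions of the ViT branch."""
    branch = ViTBranch(cfg, np.random.default_rng(seed))
    vec = branch.forward(x[None] if x.ndim == 4 else x, train=False)
    return BranchOutput(feature_vector=vec, attentions=branch.attentions())


def classify(x: np.ndarray, cfg: EnsembleConfig, seed: int = 0,
             model: Optional[EnsembleModel] = None) -> np.ndarray:
    """Class-1 probability from a (possibly freshly initialized) ensemble."""
    model = model or EnsembleModel(cfg, seed=seed)
    return model.forward(x[None] if x.ndim == 4 else x, train=False)
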