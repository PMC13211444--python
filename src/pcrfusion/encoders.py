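"""Modality encoders.

Imaging: a volumetric patch transformer.  The single-channel volume is cut
into non-overlapping ``p x p x p`` patches, linearly embedded, prepended with
a learned CLS token, given learned positional embeddings, and passed through
pre-norm transformer blocks; the final-layer CLS state followed by LayerNorm
is the global imaging feature f_img in R^{B x C_hid}.

Clinical: a two-stage adaptive encoder.  Stage one maps the raw encoded
clinical vector to a 128-dim intermediate z1 = LayerNorm(ReLU(x W1 + b1));
stage two refines it analogously into the 256-dim representation f_clin.

No pretrained weights are used anywhere; depth/heads/patch size are
configuration, with a desk-scale default (C_hid=64, depth 2, heads 4,
patch 8) and the full-scale C_hid=768 reachable by config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, relu, softmax
from .nn import LayerNorm, Linear, Module, Parameter

__all__ = [
    "ImagingEncoderConfig",
    "ImagingEncoder",
    "ClinicalEncoderNet",
    "extract_patches",
]


@dataclass(frozen=True)
class ImagingEncoderConfig:
    patch_size: int = 8
    hidden_dim: int = 64
    depth: int = 2
    heads: int = 4
    mlp_ratio: float = 2.0
    ln_eps: float = 1e-5

    def validate(self, volume_shape: tuple[int, int, int]) -> None:
        for axis, size in zip("HWD", volume_shape):
            if size % self.patch_size:
                raise ValueError(
                    f"axis {axis} (size {size}) is not divisible by "
                    f"patch_size {self.patch_size}"
                )
        if self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")


def extract_patches(volumes: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, H, W, D) -> (B, N, p^3) non-overlapping patch matrix."""
    b, h, w, d = volumes.shape
    p = patch_size
    grid = (h // p, w // p, d // p)
    x = volumes.reshape(b, grid[0], p, grid[1], p, grid[2], p)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6)
    return x.reshape(b, grid[0] * grid[1] * grid[2], p**3)


class _SelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.heads = heads
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        b, t, c = x.shape
        h, dh = self.heads, self.dim // self.heads
        qkv = self.qkv(x)  # (B, T, 3C)
        q = qkv[:, :, 0 * c : 1 * c].reshape(b, t, h, dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, 1 * c : 2 * c].reshape(b, t, h, dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * c : 3 * c].reshape(b, t, h, dh).transpose(0, 2, 1, 3)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        weights = softmax(logits, axis=-1)
        out = (weights @ v).transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


class _Block(Module):
    """Pre-norm transformer block with a ReLU MLP."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float, eps: float,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim, eps)
        self.attn = _SelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim, eps)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(relu(self.fc1(self.norm2(x))))


class ImagingEncoder(Module):
    """Volumetric patch transformer producing the global imaging feature."""

    def __init__(
        self,
        volume_shape: tuple[int, int, int],
        config: ImagingEncoderConfig | None = None,
        rng: np.random.Generator | None = None,
    ):
        config = config or ImagingEncoderConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        config.validate(volume_shape)
        self.config = config
        self.volume_shape = tuple(volume_shape)
        p = config.patch_size
        self.n_patches = int(np.prod([s // p for s in volume_shape]))
        dim = config.hidden_dim
        self.patch_embed = Linear(p**3, dim, rng)
        self.cls_token = Parameter(rng.normal(0.0, 0.02, (1, 1, dim)))
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, (1, self.n_patches + 1, dim)))
        self.blocks = [
            _Block(dim, config.heads, config.mlp_ratio, config.ln_eps, rng)
            for _ in range(config.depth)
        ]
        self.final_norm = LayerNorm(dim, config.ln_eps)

    def forward(self, volumes: np.ndarray) -> Tensor:
        volumes = np.asarray(volumes, dtype=np.float64)
        if volumes.ndim != 4:
            raise ValueError("expected a batch of 3D volumes (B, H, W, D)")
        self.config.validate(volumes.shape[1:])
        b = volumes.shape[0]
        patches = extract_patches(volumes, self.config.patch_size)
        tokens = self.patch_embed(Tensor(patches))  # (B, N, C)
        cls = self.cls_token.broadcast_to((b, 1, self.config.hidden_dim))
        x = concat([cls, tokens], axis=1) + self.pos_embed
        for block in self.blocks:
            x = block(x)
        z_cls = x[:, 0, :]  # last-layer CLS state
        return self.final_norm(z_cls)


class ClinicalEncoderNet(Module):
    """Two-stage clinical semantic encoder: d_in -> 128 -> 256."""

    def __init__(self, in_features: int, rng: np.random.Generator | None = None,
                 mid_features: int = 128, out_features: int = 256,
                 eps: float = 1e-5):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = Linear(in_features, mid_features, rng)
        self.norm1 = LayerNorm(mid_features, eps)
        self.fc2 = Linear(mid_features, out_features, rng)
        self.norm2 = LayerNorm(out_features, eps)
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x, return_intermediate: bool = False):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"clinical vector length {x.shape[-1]} != expected {self.in_features}"
            )
        z1 = self.norm1(relu(self.fc1(x)))
        f_clin = self.norm2(relu(self.fc2(z1)))
        if return_intermediate:
            return z1, f_clin
        return f_clin
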