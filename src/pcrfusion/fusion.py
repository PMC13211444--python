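"""Bidirectional cross-modal attention fusion.

Both modality features are first projected into a shared 512-dim latent
space.  Two *parallel* multi-head cross-attention pathways with distinct
parameter sets then run in opposite directions:

* imaging-guided clinical attention — the imaging feature is the query,
  the clinical feature provides key and value;
* clinical-guided imaging attention — the mirrored direction.

Each feature is a single pooled vector, i.e. a one-token sequence, so each
head's post-softmax attention weight over the key axis is exactly 1; the
pooled per-sample attention summaries (head-averaged, globally averaged
post-softmax weights) are therefore constant 1 under the literal
formulation.  A documented alternative mode (``pooled="pre_softmax_sigmoid"``)
pools the sigmoid of the head-averaged scaled logit instead, giving a
sample-dependent summary.  The two attended vectors are concatenated and
linearly projected into the unified 512-dim fused feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, sigmoid, softmax
from .nn import Linear, Module

__all__ = ["FusionOutput", "CrossAttention", "BiCMAFusion", "FUSION_MODES"]

FUSION_MODES = ("concat", "igc", "cgi", "bicma")


@dataclass
class FusionOutput:
    ffused: Tensor  # (B, d_out)
    amri: Tensor  # (B, 1) pooled IGC attention summary
    aclin: Tensor  # (B, 1) pooled CGI attention summary
    fimg_attn: Tensor | None = None
    fclin_attn: Tensor | None = None
    fimg_proj: Tensor | None = None
    fclin_proj: Tensor | None = None


class CrossAttention(Module):
    """Multi-head cross-attention between two single-token feature vectors.

    Query, key and value projections are head-partitioned slices of full
    ``d_fuse x d_fuse`` maps; logits are scaled by 1/sqrt(d_head) and
    softmaxed over the (single-token) key axis.
    """

    def __init__(self, d_fuse: int, heads: int, rng: np.random.Generator,
                 pooled: str = "softmax"):
        if d_fuse % heads:
            raise ValueError(f"d_fuse {d_fuse} not divisible by heads {heads}")
        if pooled not in ("softmax", "pre_softmax_sigmoid"):
            raise ValueError(f"unknown pooled mode {pooled!r}")
        self.wq = Linear(d_fuse, d_fuse, rng)
        self.wk = Linear(d_fuse, d_fuse, rng)
        self.wv = Linear(d_fuse, d_fuse, rng)
        self.wout = Linear(d_fuse, d_fuse, rng)
        self.heads = heads
        self.d_fuse = d_fuse
        self.pooled = pooled

    def forward(self, query_vec: Tensor, key_vec: Tensor, value_vec: Tensor
                ) -> tuple[Tensor, Tensor]:
        b = query_vec.shape[0]
        h, dh = self.heads, self.d_fuse // self.heads
        q = self.wq(query_vec).reshape(b, h, dh)
        k = self.wk(key_vec).reshape(b, h, dh)
        v = self.wv(value_vec).reshape(b, h, dh)
        # one-token key sequence: per-head logit matrix is (B, H, 1)
        logits = (q * k).sum(axis=-1, keepdims=True) * (1.0 / np.sqrt(dh))
        weights = softmax(logits, axis=-1)  # exactly 1 for a single key
        attended = (weights * v).reshape(b, self.d_fuse)
        attended = self.wout(attended)
        if self.pooled == "softmax":
            # mean over heads of the globally averaged post-softmax weights
            pooled = weights.mean(axis=1)  # (B, 1)
        else:
            pooled = sigmoid(logits.mean(axis=1))  # (B, 1)
        return attended, pooled


class BiCMAFusion(Module):
    """Shared projection + bidirectional cross-attention + joint fusion.

    ``mode`` selects the ablation variant:

    * ``"bicma"``  — both attention pathways (default);
    * ``"igc"``    — imaging-guided pathway only; the clinical branch passes
      its shared projection through;
    * ``"cgi"``    — the mirrored unidirectional variant;
    * ``"concat"`` — no attention at all: the fused feature is the linear
      projection of the concatenated shared projections.
    """

    def __init__(
        self,
        d_img: int,
        d_clin: int = 256,
        d_fuse: int = 512,
        d_out: int = 512,
        heads: int = 8,
        mode: str = "bicma",
        pooled: str = "softmax",
        rng: np.random.Generator | None = None,
    ):
        if mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {mode!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.proj_img = Linear(d_img, d_fuse, rng)
        self.proj_clin = Linear(d_clin, d_fuse, rng)
        self.igc = CrossAttention(d_fuse, heads, rng, pooled)
        self.cgi = CrossAttention(d_fuse, heads, rng, pooled)
        self.fuse = Linear(2 * d_fuse, d_out, rng)
        self.mode = mode
        self.d_fuse = d_fuse

    def shared_projection(self, fimg: Tensor, fclin: Tensor) -> tuple[Tensor, Tensor]:
        return self.proj_img(fimg), self.proj_clin(fclin)

    def forward(self, fimg: Tensor, fclin: Tensor) -> FusionOutput:
        fimg_proj, fclin_proj = self.shared_projection(fimg, fclin)
        b = fimg_proj.shape[0]
        ones = Tensor(np.ones((b, 1)))

        if self.mode == "concat":
            img_branch, clin_branch = fimg_proj, fclin_proj
            amri, aclin = ones, ones
            fimg_attn = fclin_attn = None
        elif self.mode == "igc":
            fimg_attn, amri = self.igc(fimg_proj, fclin_proj, fclin_proj)
            img_branch, clin_branch = fimg_attn, fclin_proj
            aclin, fclin_attn = ones, None
        elif self.mode == "cgi":
            fclin_attn, aclin = self.cgi(fclin_proj, fimg_proj, fimg_proj)
            img_branch, clin_branch = fimg_proj, fclin_attn
            amri, fimg_attn = ones, None
        else:  # bicma
            fimg_attn, amri = self.igc(fimg_proj, fclin_proj, fclin_proj)
            fclin_attn, aclin = self.cgi(fclin_proj, fimg_proj, fimg_proj)
            img_branch, clin_branch = fimg_attn, fclin_attn

        ffused = self.fuse(concat([img_branch, clin_branch], axis=-1))
        return FusionOutput(
            ffused=ffused,
            amri=amri,
            aclin=aclin,
            fimg_attn=fimg_attn,
            fclin_attn=fclin_attn,
            fimg_proj=fimg_proj,
            fclin_proj=fclin_proj,
        )
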