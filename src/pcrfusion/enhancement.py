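"""Multimodal contrast-aware feature enhancement.

Four stages refine the fused feature into a 128-dim contrastive embedding:

1. *Modal calibration* — scalar sigmoid gates driven by the pooled
   cross-attention summaries rescale the fused vector:
   ``f_cal = (w_mri + w_clin) * f_fused`` (both gates multiply the same
   fused vector, so the sum identity holds exactly; zero gate parameters
   give w = 0.5 each and reduce calibration to the identity).
2. *Clinical semantic-guided selection* — a softmax weight over the 512
   feature slots, generated from the clinical feature, masks the calibrated
   vector.
3. *Dual-path refinement with contrast-aware dynamic activation* — two
   independently parameterized Linear+LayerNorm+ReLU paths whose activations
   are modulated by ``(1 - beta * s_intra) * alpha``: low intra-class
   similarity (hard samples) yields stronger activation.
4. *Projection* — each path maps to 128 dims with LayerNorm; the enhanced
   embedding is their average.

The intra-class similarity both feeds *on* the enhanced embedding and feeds
*into* stage 3, which is circular.  The module resolves this with a two-pass
scheme: pass 1 computes a provisional embedding with ``s_intra = 0``;
``s_intra`` is then computed from that embedding *detached from the
gradient graph*; pass 2 recomputes stages 3-4 with it.  Inference (no
labels) uses ``s_intra = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, relu, sigmoid, softmax
from .nn import LayerNorm, Linear, Module, Parameter
from .objectives import intra_class_similarity

__all__ = ["EnhancedEmbedding", "MCFE", "MCFE_MODES"]

MCFE_MODES = (
    "full",
    "off",
    "conventional_cl",
    "no_calibration",
    "no_dual_path",
    "no_dynamic_activation",
)


@dataclass
class EnhancedEmbedding:
    z_enhanced: Tensor  # (B, 128)
    s_intra: np.ndarray  # (B, 1), detached


class MCFE(Module):
    def __init__(
        self,
        d_fused: int = 512,
        d_clin: int = 256,
        d_embed: int = 128,
        alpha_init: float = 1.0,
        beta_init: float = 0.1,
        clamp_activation: bool = False,
        mode: str = "full",
        rng: np.random.Generator | None = None,
    ):
        if mode not in MCFE_MODES:
            raise ValueError(f"unknown MCFE mode {mode!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        # 1x1 gating parameters (scalar weight + scalar bias per modality)
        self.gate_w_mri = Parameter(np.zeros((1, 1)))
        self.gate_b_mri = Parameter(np.zeros(1))
        self.gate_w_clin = Parameter(np.zeros((1, 1)))
        self.gate_b_clin = Parameter(np.zeros(1))
        self.select = Linear(d_clin, d_fused, rng)
        self.select_norm = LayerNorm(d_fused)
        self.path1 = Linear(d_fused, d_fused, rng)
        self.path1_norm = LayerNorm(d_fused)
        self.path2 = Linear(d_fused, d_fused, rng)
        self.path2_norm = LayerNorm(d_fused)
        self.proj1 = Linear(d_fused, d_embed, rng)
        self.proj1_norm = LayerNorm(d_embed)
        self.proj2 = Linear(d_fused, d_embed, rng)
        self.proj2_norm = LayerNorm(d_embed)
        self.alpha = Parameter(np.array(alpha_init))
        self.beta = Parameter(np.array(beta_init))
        self.clamp_activation = clamp_activation
        self.mode = mode
        self.d_fused = d_fused

    # -- stages ----------------------------------------------------------------

    def modal_calibration(self, ffused: Tensor, amri: Tensor, aclin: Tensor) -> Tensor:
        w_mri = sigmoid(amri @ self.gate_w_mri + self.gate_b_mri)  # (B, 1)
        w_clin = sigmoid(aclin @ self.gate_w_clin + self.gate_b_clin)
        return w_mri * ffused + w_clin * ffused

    def semantic_selection(self, fcalibrated: Tensor, fclin: Tensor) -> Tensor:
        s = softmax(relu(self.select_norm(self.select(fclin))), axis=-1)
        return fcalibrated * s

    def dual_path_refine(self, fselected: Tensor, s_intra: np.ndarray
                         ) -> tuple[Tensor, Tensor]:
        f1 = relu(self.path1_norm(self.path1(fselected)))
        if self.mode == "no_dual_path":
            f2 = f1
        else:
            f2 = relu(self.path2_norm(self.path2(fselected)))
        if self.mode == "no_dynamic_activation":
            return f1, f2
        modulation = 1.0 - self.beta * Tensor(np.asarray(s_intra, dtype=float))
        if self.clamp_activation:
            modulation = relu(modulation)
        f1_act = modulation * relu(f1) * self.alpha
        f2_act = modulation * relu(f2) * self.alpha
        return f1_act, f2_act

    def enhanced_embedding(self, f1_act: Tensor, f2_act: Tensor) -> Tensor:
        f1_proj = self.proj1_norm(self.proj1(f1_act))
        f2_proj = self.proj2_norm(self.proj2(f2_act))
        return (f1_proj + f2_proj) * 0.5

    # -- full forward ----------------------------------------------------------

    def _single_pass(self, ffused: Tensor, fclin: Tensor, amri: Tensor,
                     aclin: Tensor, s_intra: np.ndarray) -> Tensor:
        if self.mode == "no_calibration":
            fcal = ffused
        else:
            fcal = self.modal_calibration(ffused, amri, aclin)
        fsel = self.semantic_selection(fcal, fclin)
        f1_act, f2_act = self.dual_path_refine(fsel, s_intra)
        return self.enhanced_embedding(f1_act, f2_act)

    def forward(
        self,
        ffused: Tensor,
        fclin: Tensor,
        amri: Tensor,
        aclin: Tensor,
        labels: np.ndarray | None = None,
        tau: float = 0.1,
    ) -> EnhancedEmbedding:
        """Two-pass forward.  ``labels=None`` selects inference mode
        (``s_intra = 0``); the similarity feedback is always detached."""
        b = ffused.shape[0]
        zeros = np.zeros((b, 1))
        if self.mode == "conventional_cl":
            # plain supervised contrastive embedding: single linear projection
            # of the fused feature, no calibration/selection/refinement
            z = self.proj1_norm(self.proj1(ffused))
            s = (
                intra_class_similarity(z.data, labels, tau)
                if labels is not None and b > 1
                else zeros
            )
            return EnhancedEmbedding(z_enhanced=z, s_intra=s)

        if labels is None:
            return EnhancedEmbedding(
                z_enhanced=self._single_pass(ffused, fclin, amri, aclin, zeros),
                s_intra=zeros,
            )
        if b < 2:
            warnings.warn(
                "batch of size 1 in training mode: intra-class similarity "
                "falls back to 0",
                stacklevel=2,
            )
            return EnhancedEmbedding(
                z_enhanced=self._single_pass(ffused, fclin, amri, aclin, zeros),
                s_intra=zeros,
            )

        provisional = self._single_pass(ffused, fclin, amri, aclin, zeros)
        s_intra = intra_class_similarity(provisional.data, labels, tau)  # detached
        z = self._single_pass(ffused, fclin, amri, aclin, s_intra)
        return EnhancedEmbedding(z_enhanced=z, s_intra=s_intra)
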