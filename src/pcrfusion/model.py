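"""End-to-end multimodal pCR classifier as a scikit-learn estimator.

``MultimodalResponseClassifier`` assembles the volumetric transformer
encoder, the two-stage clinical encoder, bidirectional cross-modal attention
fusion, the contrast-aware enhancement module, and the dual-loss objective
(class-weighted cross-entropy + supervised contrastive loss weighted by
``lam``), trained with AdamW and single-cycle cosine annealing.

``X`` is a mapping with keys ``"image"`` (B, H, W, D volumes, already
normalized) and ``"clinical"`` (B, d encoded clinical vectors); unimodal
variants (``modality="image"`` / ``"clinical"``) reuse the same encoder and
head codepaths with a linear bridge into the 512-dim fused space, so
multimodal-vs-unimodal comparisons differ only in what the model sees.

The estimator follows scikit-learn conventions: all hyperparameters are
``__init__`` arguments, fitted state carries a trailing underscore, and
``get_params``/``set_params``/cloning work as usual.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .autodiff import Tensor
from .encoders import ClinicalEncoderNet, ImagingEncoder, ImagingEncoderConfig
from .enhancement import MCFE, MCFE_MODES
from .fusion import FUSION_MODES, BiCMAFusion
from .nn import AdamW, CosineSchedule, Linear, Module
from .objectives import (
    ClassificationHead,
    class_weights_from_counts,
    supcon_loss,
    total_loss,
    weighted_cross_entropy,
)

__all__ = ["MultimodalResponseClassifier"]


class _Network(Module):
    """Container module so parameter discovery covers every component."""

    def __init__(self):
        self.imaging = None
        self.clinical = None
        self.fusion = None
        self.bridge = None
        self.mcfe = None
        self.head = None


class MultimodalResponseClassifier(BaseEstimator, ClassifierMixin):
    """Multimodal (DCE-MRI phantom + clinical) pCR classifier.

    Parameters
    ----------
    modality : {"both", "image", "clinical"}
        Which inputs the model consumes.  Unimodal variants bypass fusion
        and the contrastive branch.
    fusion : {"concat", "igc", "cgi", "bicma"}
        Fusion ablation switch (multimodal only).
    mcfe : {"full", "off", "conventional_cl", "no_calibration",
        "no_dual_path", "no_dynamic_activation"}
        Enhancement/contrastive ablation switch.  ``"off"`` trains with the
        classification loss alone.
    tau, lam : float
        Contrastive temperature and loss weight (defaults 0.1 and 0.9).
    lr_encoder, lr_other : float
        Layer-wise learning rates: ``lr_encoder`` applies to the imaging
        encoder, ``lr_other`` to every other module.
    """

    def __init__(
        self,
        modality: str = "both",
        fusion: str = "bicma",
        mcfe: str = "full",
        patch_size: int = 8,
        hidden_dim: int = 64,
        depth: int = 2,
        encoder_heads: int = 4,
        d_fuse: int = 512,
        fusion_heads: int = 8,
        pooled: str = "softmax",
        tau: float = 0.1,
        lam: float = 0.9,
        alpha_init: float = 1.0,
        beta_init: float = 0.1,
        clamp_activation: bool = False,
        normalize_embeddings: bool = False,
        normalize_class_weights: bool = False,
        head_hidden: int = 128,
        lr_encoder: float = 1e-5,
        lr_other: float = 1e-4,
        weight_decay: float = 0.01,
        batch_size: int = 4,
        epochs: int = 50,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.modality = modality
        self.fusion = fusion
        self.mcfe = mcfe
        self.patch_size = patch_size
        self.hidden_dim = hidden_dim
        self.depth = depth
        self.encoder_heads = encoder_heads
        self.d_fuse = d_fuse
        self.fusion_heads = fusion_heads
        self.pooled = pooled
        self.tau = tau
        self.lam = lam
        self.alpha_init = alpha_init
        self.beta_init = beta_init
        self.clamp_activation = clamp_activation
        self.normalize_embeddings = normalize_embeddings
        self.normalize_class_weights = normalize_class_weights
        self.head_hidden = head_hidden
        self.lr_encoder = lr_encoder
        self.lr_other = lr_other
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state
        self.verbose = verbose

    # -- input plumbing --------------------------------------------------------

    @staticmethod
    def _unpack(X) -> tuple[np.ndarray | None, np.ndarray | None]:
        if isinstance(X, dict):
            image = X.get("image")
            clinical = X.get("clinical")
        elif isinstance(X, (tuple, list)) and len(X) == 2:
            image, clinical = X
        else:
            raise TypeError(
                "X must be a dict with keys 'image'/'clinical' or a pair"
            )
        image = None if image is None else np.asarray(image, dtype=np.float64)
        clinical = None if clinical is None else np.asarray(clinical, dtype=np.float64)
        return image, clinical

    def _check_inputs(self, image, clinical, require_all: bool = True):
        if self.modality not in ("both", "image", "clinical"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion!r}")
        if self.mcfe not in MCFE_MODES:
            raise ValueError(f"unknown mcfe mode {self.mcfe!r}")
        needs_image = self.modality in ("both", "image")
        needs_clinical = self.modality in ("both", "clinical")
        if require_all and needs_image and image is None:
            raise ValueError("modality requires imaging input")
        if require_all and needs_clinical and clinical is None:
            raise ValueError("modality requires clinical input")
        n = image.shape[0] if needs_image else clinical.shape[0]
        if needs_image and needs_clinical and clinical.shape[0] != n:
            raise ValueError("imaging and clinical batches differ in length")
        return n

    # -- architecture ----------------------------------------------------------

    def _build(self, image, clinical, rng: np.random.Generator) -> _Network:
        net = _Network()
        d_out = self.d_fuse
        if self.modality in ("both", "image"):
            config = ImagingEncoderConfig(
                patch_size=self.patch_size,
                hidden_dim=self.hidden_dim,
                depth=self.depth,
                heads=self.encoder_heads,
            )
            net.imaging = ImagingEncoder(image.shape[1:], config, rng)
        if self.modality in ("both", "clinical"):
            net.clinical = ClinicalEncoderNet(clinical.shape[1], rng)
        if self.modality == "both":
            net.fusion = BiCMAFusion(
                d_img=self.hidden_dim,
                d_clin=net.clinical.out_features,
                d_fuse=self.d_fuse,
                d_out=d_out,
                heads=self.fusion_heads,
                mode=self.fusion,
                pooled=self.pooled,
                rng=rng,
            )
            if self.mcfe != "off":
                net.mcfe = MCFE(
                    d_fused=d_out,
                    d_clin=net.clinical.out_features,
                    alpha_init=self.alpha_init,
                    beta_init=self.beta_init,
                    clamp_activation=self.clamp_activation,
                    mode=self.mcfe,
                    rng=rng,
                )
        elif self.modality == "image":
            net.bridge = Linear(self.hidden_dim, d_out, rng)
        else:
            net.bridge = Linear(net.clinical.out_features, d_out, rng)
        net.head = ClassificationHead(d_out, self.head_hidden, rng)
        return net

    def _forward(self, image, clinical, labels=None):
        """Returns (probs, z_enhanced or None).  ``labels=None`` = inference."""
        net = self.network_
        if self.modality == "image":
            ffused = net.bridge(net.imaging(image))
            return net.head(ffused), None
        if self.modality == "clinical":
            ffused = net.bridge(net.clinical(clinical))
            return net.head(ffused), None
        fimg = net.imaging(image)
        fclin = net.clinical(clinical)
        out = net.fusion(fimg, fclin)
        probs = net.head(out.ffused)
        if net.mcfe is None:
            return probs, None
        enhanced = net.mcfe(
            out.ffused, fclin, out.amri, out.aclin, labels=labels, tau=self.tau
        )
        return probs, enhanced.z_enhanced

    # -- estimator API ---------------------------------------------------------

    def fit(self, X, y):
        image, clinical = self._unpack(X)
        n = self._check_inputs(image, clinical)
        y = np.asarray(y).reshape(-1).astype(int)
        if y.shape[0] != n:
            raise ValueError("labels and inputs differ in length")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("labels must contain both classes coded 0/1")
        self.classes_ = classes

        rng = np.random.default_rng(self.random_state)
        self.network_ = self._build(image, clinical, rng)
        w0, w1 = class_weights_from_counts(y, normalize=self.normalize_class_weights)
        self.class_weights_ = (w0, w1)

        encoder_params = (
            self.network_.imaging.parameters() if self.network_.imaging else []
        )
        encoder_ids = {id(p) for p in encoder_params}
        other_params = [
            p for p in self.network_.parameters() if id(p) not in encoder_ids
        ]
        groups = [{"params": other_params, "lr": self.lr_other}]
        if encoder_params:
            groups.append({"params": encoder_params, "lr": self.lr_encoder})
        optimizer = AdamW(groups, weight_decay=self.weight_decay)
        steps_per_epoch = int(np.ceil(n / self.batch_size))
        schedule = CosineSchedule(optimizer, self.epochs * steps_per_epoch)

        use_cl = self.modality == "both" and self.mcfe != "off"
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_cls, epoch_cl, epoch_total = [], [], []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                batch_img = image[idx] if image is not None else None
                batch_clin = clinical[idx] if clinical is not None else None
                batch_y = y[idx]
                probs, z = self._forward(batch_img, batch_clin, labels=batch_y)
                loss_cls = weighted_cross_entropy(probs, batch_y, w0=w0, w1=w1)
                if use_cl and z is not None and batch_y.size >= 2:
                    loss_cl = supcon_loss(
                        z, batch_y, tau=self.tau,
                        normalize=self.normalize_embeddings,
                    )
                    if not isinstance(loss_cl, Tensor):
                        loss_cl = Tensor(loss_cl)
                else:
                    loss_cl = Tensor(0.0)
                loss = total_loss(loss_cls, loss_cl, self.lam)
                for name, term in (
                    ("classification", loss_cls),
                    ("contrastive", loss_cl),
                ):
                    if not np.isfinite(term.data):
                        raise RuntimeError(
                            f"non-finite {name} loss at epoch {epoch}"
                        )
                self.network_.zero_grad()
                loss.backward()
                optimizer.step()
                schedule.step()
                epoch_cls.append(float(loss_cls.data))
                epoch_cl.append(float(loss_cl.data))
                epoch_total.append(float(loss.data))
            history.append(
                {
                    "epoch": epoch,
                    "loss_cls": float(np.mean(epoch_cls)),
                    "loss_cl": float(np.mean(epoch_cl)),
                    "loss_total": float(np.mean(epoch_total)),
                }
            )
            if self.verbose:
                print(
                    f"epoch {epoch}: total {history[-1]['loss_total']:.4f} "
                    f"(cls {history[-1]['loss_cls']:.4f}, "
                    f"cl {history[-1]['loss_cl']:.4f})"
                )
        self.loss_history_ = history
        self.n_iter_ = self.epochs
        return self

    def predict_proba(self, X, batch_size: int = 64) -> np.ndarray:
        check_is_fitted(self, "network_")
        image, clinical = self._unpack(X)
        n = self._check_inputs(image, clinical)
        out = np.empty((n, 2))
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            probs, _ = self._forward(
                image[sl] if image is not None else None,
                clinical[sl] if clinical is not None else None,
                labels=None,
            )
            out[sl] = probs.data
        return out

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
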