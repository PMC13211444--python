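"""Minimal neural-network building blocks over :mod:`pcrfusion.autodiff`.

Provides parameter containers, linear / layer-norm layers, the AdamW
optimizer with decoupled weight decay, and a single-cycle cosine-annealing
learning-rate schedule — the training toolkit the full model needs.
"""

from __future__ import annotations

import json
import pickle
from typing import Iterator

import numpy as np

from .autodiff import Tensor, layer_norm

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "AdamW", "CosineSchedule"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            value = np.asarray(state[name], dtype=np.float64)
            if value.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = value.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map ``x @ W + b`` with Glorot-uniform initialization."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class AdamW:
    """AdamW with decoupled weight decay and per-group learning rates."""

    def __init__(
        self,
        param_groups: list[dict],
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.groups = []
        for group in param_groups:
            self.groups.append(
                {
                    "params": list(group["params"]),
                    "lr": float(group["lr"]),
                    "base_lr": float(group["lr"]),
                    "weight_decay": float(group.get("weight_decay", weight_decay)),
                }
            )
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for group in self.groups:
            lr, wd = group["lr"], group["weight_decay"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                m = self._m.setdefault(key, np.zeros_like(p.data))
                v = self._v.setdefault(key, np.zeros_like(p.data))
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad ** 2
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                if wd:
                    p.data -= lr * wd * p.data

    def set_lr_factor(self, factor: float) -> None:
        for group in self.groups:
            group["lr"] = group["base_lr"] * factor


class CosineSchedule:
    """Single-cycle cosine annealing from the base rate to ``eta_min_factor``."""

    def __init__(self, optimizer: AdamW, total_steps: int, eta_min_factor: float = 0.0):
        self.optimizer = optimizer
        self.total_steps = max(int(total_steps), 1)
        self.eta_min_factor = eta_min_factor
        self.step_count = 0

    def step(self) -> None:
        self.step_count = min(self.step_count + 1, self.total_steps)
        progress = self.step_count / self.total_steps
        factor = self.eta_min_factor + (1 - self.eta_min_factor) * 0.5 * (
            1 + np.cos(np.pi * progress)
        )
        self.optimizer.set_lr_factor(factor)


def save_checkpoint(path, module: Module, config: dict) -> None:
    """Serialize parameters plus a JSON-encodable config to one file."""
    with open(path, "wb") as fh:
        pickle.dump({"config": json.dumps(config), "state": module.state_dict()}, fh)


def load_checkpoint(path) -> tuple[dict, dict]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return json.loads(payload["config"]), payload["state"]
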