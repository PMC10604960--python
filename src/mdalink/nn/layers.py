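"""Parameterized building blocks on top of the autograd tensors."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Linear", "Embedding", "LayerNorm"]


class Module:
    """Parameter container with recursive traversal and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor):
                params[key] = attr
            elif isinstance(attr, Module):
                params.update(attr.named_parameters(f"{key}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        params[f"{key}.{i}"] = item
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr._set_mode(training)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item._set_mode(training)

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(glorot(rng, in_dim, out_dim))
        self.bias = Tensor(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator, scale: float = 0.02):
        super().__init__()
        self.table = Tensor(rng.normal(0.0, scale, size=(num_embeddings, dim)))

    def __call__(self, index: np.ndarray) -> Tensor:
        return ag.gather(self.table, index)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim))
        self.beta = Tensor(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.mul(ag.layer_norm(x, self.eps), self.gamma), self.beta)
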