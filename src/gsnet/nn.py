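"""Neural-network layers and the Adam optimizer on top of the autodiff engine.

Initialization follows the Glorot-uniform convention for linear maps and
N(0, 1) for embedding rows; every layer takes an explicit
``numpy.random.Generator`` so whole-model initialization is a pure function
of the seed.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from ._autodiff import Tensor, gather_rows

__all__ = ["Module", "Linear", "Embedding", "LayerNorm", "Dropout", "MLP", "ssp", "Adam"]


def ssp(x: Tensor) -> Tensor:
    """Shifted softplus activation, ln(1 + e^x) - ln 2."""
    return x.ssp()


class Module:
    """Base class: parameter registry, train/eval mode, state (de)serialization."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = False

    def register(self, name: str, array: np.ndarray) -> Tensor:
        p = Tensor(array, requires_grad=True)
        self._params[name] = p
        return p

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + name: p for name, p in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = self.register("weight", rng.uniform(-bound, bound, (in_dim, out_dim)).astype(dtype))
        self.bias = self.register("bias", np.zeros(out_dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_items: int, dim: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = self.register("weight", rng.standard_normal((n_items, dim)).astype(dtype))

    def __call__(self, index: np.ndarray) -> Tensor:
        return gather_rows(self.weight, np.asarray(index, dtype=np.intp))


class LayerNorm(Module):
    """Layer normalization over the last axis with learned affine transform."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.scale = self.register("scale", np.ones(dim, dtype=dtype))
        self.offset = self.register("offset", np.zeros(dim, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.scale + self.offset


class Dropout(Module):
    """Inverted dropout; active only in training mode. Draws from the rng
    passed at call time so training streams stay seed-reproducible."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout fraction must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = (rng.random(x.shape) >= self.p).astype(x.dtype)
        return x * Tensor(keep / (1.0 - self.p))


class MLP(Module):
    """Stack of linear layers with shifted-softplus between them.

    ``dropout`` > 0 inserts a dropout layer before every linear layer
    (so counts follow: n linears, n-1 activations, n dropouts).
    """

    def __init__(self, dims: list[int], rng: np.random.Generator, dropout: float = 0.0, dtype=np.float32):
        super().__init__()
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.linears = [
            self.add_child(f"lin{i}", Linear(a, b, rng, dtype=dtype))
            for i, (a, b) in enumerate(zip(dims[:-1], dims[1:]))
        ]
        self.dropouts = [self.add_child(f"drop{i}", Dropout(dropout)) for i in range(len(self.linears))] if dropout > 0 else []

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        for i, lin in enumerate(self.linears):
            if self.dropouts:
                x = self.dropouts[i](x, rng)
            x = lin(x)
            if i < len(self.linears) - 1:
                x = ssp(x)
        return x

    @property
    def n_linear(self) -> int:
        return len(self.linears)

    @property
    def n_activation(self) -> int:
        return len(self.linears) - 1

    @property
    def n_dropout(self) -> int:
        return len(self.dropouts)


class Adam:
    """Adam with bias correction; moments kept per parameter array."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
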