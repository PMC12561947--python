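"""Module/Parameter plumbing shared by all layers."""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self):
        return self.value.shape

    @property
    def size(self):
        return self.value.size


class Module:
    """Base class: attribute walking gives parameter/submodule discovery.

    Attribute insertion order is deterministic, so ``parameters()`` returns
    a stable ordering — state dicts are plain lists keyed by that order.
    """

    training: bool = True

    def _walk_modules(self, seen):
        if id(self) in seen:
            return
        seen.add(id(self))
        yield self
        for _, value in vars(self).items():
            stack = [value]
            while stack:
                obj = stack.pop(0)
                if isinstance(obj, Module):
                    yield from obj._walk_modules(seen)
                elif isinstance(obj, (list, tuple)):
                    stack = list(obj) + stack

    def modules(self):
        return list(self._walk_modules(set()))

    def parameters(self) -> list[Parameter]:
        params, seen = [], set()
        for mod in self.modules():
            for _, value in vars(mod).items():
                if isinstance(value, Parameter) and id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
        return params

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for p, arr in zip(params, state):
            if p.value.shape != arr.shape:
                raise ValueError(f"shape mismatch: {p.value.shape} vs {arr.shape}")
            p.value[...] = arr

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    """Chain of layers; backward replays them in reverse."""

    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
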