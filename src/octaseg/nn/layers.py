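"""Neural-network layers on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, conv2d


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    yield v

    def named_state(self):
        """Flat name -> array mapping of parameters and buffers."""
        out = {}

        def walk(mod, prefix):
            for k, v in vars(mod).items():
                if k.startswith("last_"):   # diagnostics, not state
                    continue
                if isinstance(v, Tensor):
                    out[f"{prefix}{k}"] = v
                elif isinstance(v, np.ndarray):
                    out[f"{prefix}{k}"] = v
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return out

    def state_dict(self):
        return {k: (v.data if isinstance(v, Tensor) else v).copy()
                for k, v in self.named_state().items()}

    def load_state_dict(self, state):
        slots = self.named_state()
        missing = set(slots) ^ set(state)
        if missing:
            raise ValueError(f"state mismatch on keys: {sorted(missing)}")
        for k, v in slots.items():
            arr = np.asarray(state[k])
            if isinstance(v, Tensor):
                v.data[...] = arr
            else:
                v[...] = arr

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(DTYPE),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 pad: int | None = None, bias: bool = True):
        super().__init__()
        self.pad = k // 2 if pad is None else pad
        self.weight = he_init(rng, (cout, cin, k, k), cin * k * k)
        self.bias = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True) \
            if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.weight = he_init(rng, (cin, cout), cin)
        self.bias = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics for eval."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(c, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        from .tensor import batch_norm

        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return batch_norm(x, self.gamma, self.beta, mu, var, self.eps,
                              batch_stats=True)
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.eps, batch_stats=False)


class ConvBNReLU(Module):
    def __init__(self, cin, cout, k, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng, bias=False)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()
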