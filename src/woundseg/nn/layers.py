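"""Layer abstractions over the autodiff engine.

``Module`` provides parameter discovery, train/eval switching and an ordered
``state_dict`` so checkpoints round-trip bit-exactly.  Layers mirror the
conventional NCHW building blocks: ``Conv2d``, ``BatchNorm2d``, ``Linear``
and the ConvX unit (conv + batch norm + ReLU) that the segmentation network
is assembled from.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, avg_pool2d, batch_norm2d, conv2d


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def modules(self):
        yield self
        for _, child in self.children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode -----------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- serialisation --------------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.children():
            yield from child._named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(p.data.dtype, copy=True)
        for k, b in bufs.items():
            b[...] = state[k]
        return self

    def reset_parameters(self, rng: np.random.Generator):
        """Re-initialise every layer in definition order (deterministic)."""
        for m in self.modules():
            if m is not self and hasattr(m, "_init"):
                m._init(rng)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 padding: int | None = None, bias: bool = True, dtype=np.float32):
        super().__init__()
        if out_ch <= 0:
            raise ValueError("out_channels must be positive")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        self.weight = Tensor(np.zeros((out_ch, in_ch, kernel, kernel), dtype=dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None

    def _init(self, rng: np.random.Generator):
        fan_in = self.in_ch * self.kernel * self.kernel
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.weight.data = rng.normal(0.0, std, self.weight.data.shape).astype(
            self.weight.data.dtype
        )
        if self.bias is not None:
            self.bias.data = np.zeros_like(self.bias.data)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def _init(self, rng):
        self.gamma.data = np.ones_like(self.gamma.data)
        self.beta.data = np.zeros_like(self.beta.data)
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, dtype=np.float32):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Tensor(np.zeros((in_features, out_features), dtype=dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def _init(self, rng):
        std = np.sqrt(2.0 / self.in_features)
        self.weight.data = rng.normal(0.0, std, self.weight.data.shape).astype(
            self.weight.data.dtype
        )
        self.bias.data = np.zeros_like(self.bias.data)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ConvX(Module):
    """Convolution + batch normalisation + ReLU: the basic unit of the network."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("ConvX stride must be 1 or 2")
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class AvgPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.kernel, self.stride, self.padding)
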