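"""Network building blocks (modules) on top of the autograd core."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Tensor, add, leaky_relu, mean, power, reshape, scalar_like


class Module:
    """Base class; tracks parameters and train/eval mode recursively."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value), requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = np.array(a, dtype=p.data.dtype)

    def __call__(self, x):
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape, fan_in, scale=1.0, dtype=np.float32):
    std = scale * np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class ConvNd(Module):
    def __init__(self, rng, in_ch, out_ch, kernel, nd, stride=1, padding="same",
                 bias=True, init_scale=1.0):
        super().__init__()
        self.nd = nd
        self.stride = stride
        k = (kernel,) * nd if np.isscalar(kernel) else tuple(kernel)
        if padding == "same":
            padding = tuple(kk // 2 for kk in k)
        self.padding = padding
        fan_in = in_ch * int(np.prod(k))
        self.register("weight", _he_init(rng, (out_ch, in_ch) + k, fan_in, init_scale))
        if bias:
            self.register("bias", np.zeros(out_ch, dtype=np.float32))
        else:
            self.bias = None

    def forward(self, x):
        return F.conv_nd(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTransposeNd(Module):
    def __init__(self, rng, in_ch, out_ch, kernel, nd, stride=2, padding=1,
                 output_padding=1, bias=True, init_scale=1.0):
        super().__init__()
        k = (kernel,) * nd if np.isscalar(kernel) else tuple(kernel)
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        fan_in = in_ch * int(np.prod(k))
        self.register("weight", _he_init(rng, (in_ch, out_ch) + k, fan_in, init_scale))
        if bias:
            self.register("bias", np.zeros(out_ch, dtype=np.float32))
        else:
            self.bias = None

    def forward(self, x):
        return F.conv_transpose_nd(x, self.weight, self.bias, stride=self.stride,
                                   padding=self.padding, output_padding=self.output_padding)


class BatchNorm(Module):
    """Batch normalization over (N, *spatial) per channel."""

    def __init__(self, channels, nd, eps=1e-5, momentum=0.1):
        super().__init__()
        self.nd = nd
        self.eps = eps
        self.momentum = momentum
        self.register("gamma", np.ones(channels, dtype=np.float32))
        self.register("beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x):
        axes = (0,) + tuple(range(2, 2 + self.nd))
        cshape = (1, x.shape[1]) + (1,) * self.nd
        if self.training:
            mu = mean(x, axis=axes, keepdims=True)
            var = mean(power(x - mu, 2.0), axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(cshape).astype(x.dtype))
            var = Tensor(self.running_var.reshape(cshape).astype(x.dtype))
        xn = (x - mu) * power(var + scalar_like(self.eps, x), -0.5)
        return xn * reshape(self.gamma, cshape) + reshape(self.beta, cshape)


class Linear(Module):
    def __init__(self, rng, in_f, out_f, init_scale=1.0):
        super().__init__()
        self.register("weight", _he_init(rng, (in_f, out_f), in_f, init_scale))
        self.register("bias", np.zeros(out_f, dtype=np.float32))

    def forward(self, x):
        return add(x @ self.weight, reshape(self.bias, (1, -1)))


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return leaky_relu(x, self.slope)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[f"m{i}"] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class GlobalAvgPool(Module):
    def forward(self, x):
        return mean(x, axis=tuple(range(2, x.ndim)))
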