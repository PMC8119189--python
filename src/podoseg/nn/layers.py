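"""Neural-network layers built on the autodiff core (NHWC layout)."""

from __future__ import annotations

import numpy as np

from .core import (Tensor, channel_affine, conv2d, maxpool2x2, normalize,
                   pad2d, zero_dilate)

__all__ = [
    "Module", "Sequential", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
    "InstanceNorm2d", "Dropout", "MaxPool2d", "ReLU", "LeakyReLU",
    "Sigmoid", "Tanh",
]


class Module:
    """Base class: parameter collection, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def parameters(self):
        params = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                params.append(val)
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def _named_arrays(self, prefix=""):
        """All learnable parameters and buffers as (name, array)."""
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val.data
            elif isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child._named_arrays(prefix + cname + ".")

    def state_dict(self) -> dict:
        return {name: arr.copy() for name, arr in self._named_arrays()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self._named_arrays())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for name, arr in self._named_arrays():
            np.copyto(arr, state[name])


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _he_init(rng, k, cin, cout):
    std = np.sqrt(2.0 / (cin * k * k))
    return (rng.standard_normal((k, k, cin, cout)) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding="same", bias=True,
                 init_std=None):
        super().__init__()
        if init_std is None:
            wdata = _he_init(rng, k, cin, cout)
        else:
            wdata = (rng.standard_normal((k, k, cin, cout)) * init_std).astype(
                np.float32)
        self.w = Tensor(wdata, requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) \
            if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution as zero-dilation followed by a stride-1
    convolution. Output size = in*stride for (k, stride) = (2, 2) and
    (3, 2), and = in for stride 1 with the default padding k//2."""

    def __init__(self, cin, cout, k, rng, stride=2, padding=None,
                 output_padding=None, bias=True, init_std=None):
        super().__init__()
        if padding is None:
            padding = 0 if (k == 2 and stride == 2) else k // 2
        if output_padding is None:
            output_padding = 0 if (k == 2 and stride == 2) else (stride - 1)
        if init_std is None:
            wdata = _he_init(rng, k, cin, cout)
        else:
            wdata = (rng.standard_normal((k, k, cin, cout)) * init_std).astype(
                np.float32)
        self.w = Tensor(wdata, requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) \
            if bias else None
        self.k, self.stride = k, stride
        self.pad, self.opad = padding, output_padding

    def forward(self, x):
        xd = zero_dilate(x, self.stride, extra=self.opad)
        p = self.k - 1 - self.pad
        xd = pad2d(xd, (p, p, p, p))
        return conv2d(xd, self.w, self.b, stride=1, padding="valid")


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        if self.training:
            mu = x.data.mean(axis=(0, 1, 2), keepdims=True)
            var = x.data.var(axis=(0, 1, 2), keepdims=True)
            xhat = normalize(x, axes=(0, 1, 2), eps=self.eps,
                             moments=(mu, var))
            m = self.momentum
            self.running_mean += m * (mu.ravel() - self.running_mean)
            self.running_var += m * (var.ravel() - self.running_var)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - Tensor(self.running_mean)) * Tensor(inv)
        return channel_affine(xhat, self.gamma, self.beta)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over (H, W); no affine terms,
    identical behaviour at train and inference time."""

    def __init__(self, c=None, eps=1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        return normalize(x, axes=(1, 2), eps=self.eps)


class Dropout(Module):
    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x):
        if not self.training or self.p <= 0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))


class MaxPool2d(Module):
    def forward(self, x):
        return maxpool2x2(x)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()
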