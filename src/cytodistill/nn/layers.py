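"""Module/layer system over the autodiff tensors.

Mirrors the familiar Module API (parameters, train/eval, state_dict)
at the small scale this package needs.  Weight initialization draws from
a process-wide generator; call :func:`seed_init` before building a model
for reproducible weights.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reseed the weight-initialization stream (models built afterwards
    get deterministic initial weights)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- mode / grads ---------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def freeze(self):
        """Mark every parameter non-trainable and drop any accumulated
        gradients (used for teacher networks)."""
        for p in self.parameters():
            p.requires_grad = False
            p.grad = None
        return self

    @property
    def frozen(self) -> bool:
        params = self.parameters()
        return bool(params) and not any(p.requires_grad for p in params)

    # -- (de)serialization ----------------------------------------------
    def state_dict(self):
        sd = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            sd[name] = buf.copy()
        return sd

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray) and name.startswith("running_"):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def load_state_dict(self, sd: dict, strict: bool = True):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing, mismatched = [], []
        for name, arr in sd.items():
            target = own.get(name)
            if target is not None:
                if target.data.shape != arr.shape:
                    mismatched.append(f"{name}: {target.data.shape} vs {arr.shape}")
                else:
                    target.data = np.array(arr, dtype=np.float32)
                continue
            if name in bufs:
                if bufs[name].shape != arr.shape:
                    mismatched.append(f"{name}: {bufs[name].shape} vs {arr.shape}")
                else:
                    bufs[name][...] = arr
                continue
            missing.append(name)
        if strict and (missing or mismatched):
            raise ValueError(
                "state dict mismatch; unknown tensors: %s; shape mismatches: %s"
                % (missing, mismatched))
        return self

    def param_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 zero_init: bool = False):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel_size, kernel_size))
        else:
            std = np.sqrt(2.0 / fan_in)
            w = _INIT_RNG.normal(0.0, std, (out_ch, in_ch, kernel_size, kernel_size))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            std = np.sqrt(2.0 / in_features)
            w = _INIT_RNG.normal(0.0, std, (in_features, out_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            # running stats track the batch statistics outside the graph
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        gamma = self.weight.reshape(1, c, 1, 1)
        beta = self.bias.reshape(1, c, 1, 1)
        return xhat * gamma + beta


class ChannelLayerNorm(Module):
    """Layer normalization over the channel axis of an NCHW tensor
    (used inside the global-context transform on a (N, C, 1, 1) vector)."""

    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))

    def forward(self, x):
        c = x.shape[1]
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))
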