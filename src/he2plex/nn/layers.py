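"""Neural-network building blocks on top of the autograd engine."""
from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def xavier_uniform(shape, fan_in: int, fan_out: int, rng: np.random.Generator):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat state dict (numpy arrays) --------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}

        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor):
                    out[prefix + k] = v.data
                elif isinstance(v, np.ndarray):
                    out[prefix + k] = v
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{prefix}{k}.{i}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                key = prefix + k
                if isinstance(v, Tensor) and key in state:
                    v.data = np.asarray(state[key])  # keep the stored dtype
                elif isinstance(v, np.ndarray) and key in state:
                    mod.__dict__[k] = np.asarray(state[key])
                elif isinstance(v, Module):
                    walk(v, f"{key}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")


class Conv2d(Module):
    """3x3-style convolution with optional spectral normalization.

    Spectral normalization divides the weight by its largest singular value,
    estimated by power iteration on the (F, C*k*k) unfolding; the estimate
    vectors u/v are buffers, treated as constants by the graph (standard
    practice).
    """

    def __init__(self, in_ch, out_ch, k=3, stride=1, padding=0,
                 pad_mode="zero", bias=True, spectral_norm=False,
                 n_power_iterations=1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in, fan_out = in_ch * k * k, out_ch * k * k
        self.weight = Tensor(xavier_uniform((out_ch, in_ch, k, k), fan_in, fan_out, rng),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride, self.padding, self.pad_mode = stride, padding, pad_mode
        self.spectral_norm = spectral_norm
        self.n_power_iterations = n_power_iterations
        if spectral_norm:
            self.sn_u = rng.standard_normal(out_ch)
            self.sn_u /= np.linalg.norm(self.sn_u)

    def effective_weight(self) -> Tensor:
        if not self.spectral_norm:
            return self.weight
        f = self.weight.shape[0]
        wmat = self.weight.data.reshape(f, -1)
        u = self.sn_u
        for _ in range(self.n_power_iterations):
            v = wmat.T @ u
            v /= (np.linalg.norm(v) + 1e-12)
            u = wmat @ v
            u /= (np.linalg.norm(u) + 1e-12)
        self.sn_u = u
        ut = Tensor(u.reshape(1, f))
        vt = Tensor(v.reshape(-1, 1))
        wflat = ag.reshape(self.weight, (f, -1))
        sigma = ag.matmul(ag.matmul(ut, wflat), vt)  # (1,1); graph through weight
        sigma = ag.add(sigma, 1e-12)                 # zero weight stays zero
        return ag.mul(self.weight, ag.pow_const(ag.reshape(sigma, (1, 1, 1, 1)), -1.0))

    def forward(self, x):
        return ag.conv2d(x, self.effective_weight(), self.bias,
                         stride=self.stride, padding=self.padding,
                         pad_mode=self.pad_mode)


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(xavier_uniform((in_f, out_f), in_f, out_f, rng),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True) if bias else None

    def forward(self, x):
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = ag.add(out, self.bias)
        return out


class BatchNorm2d(Module):
    def __init__(self, n_ch, eps=1e-5, momentum=0.1):
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.eps, self.momentum = eps, momentum

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = ag.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = ag.tmean(ag.pow_const(ag.add(x, ag.neg(mu)), 2.0),
                           axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = ag.mul(ag.add(x, ag.neg(mu)),
                      ag.pow_const(ag.add(var, self.eps), -0.5))
        return ag.add(ag.mul(xhat, ag.reshape(self.gamma, (1, c, 1, 1))),
                      ag.reshape(self.beta, (1, c, 1, 1)))


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)
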