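"""Network building blocks: modules, convolutions, instance norm, Adam.

Padding policy is a first-class concept here: images in polar layout wrap
around along the angle (row) axis, so generator and discriminator convs pad
circularly along rows and reflectively along columns.  In Cartesian mode
both axes use reflection.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, conv2d, conv_transpose2d

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "LeakyReLU",
    "Tanh",
    "Sequential",
    "Adam",
]


class Module:
    """Tiny module base: child modules and parameters are discovered by
    attribute scan, in deterministic (insertion) order."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    """Conv with explicit (possibly mixed-mode) edge padding.

    ``pad_modes`` is ``(row_mode, col_mode)``; padding width is chosen so
    that k3/s1 preserves size and k4/s2 halves it.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad_modes: tuple[str, str], rng: np.random.Generator, bias: bool = True):
        self.kernel = kernel
        self.stride = stride
        self.pad = (kernel - 1) // 2 if stride == 1 else (kernel - stride + 1) // 2
        self.pad_modes = pad_modes
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if self.pad:
            x = x.pad2d(self.pad, self.pad, *self.pad_modes)
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=0)


class ConvTranspose2d(Module):
    """Stride-2 transposed conv (k=4, p=1): exactly doubles spatial size."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(c_in, c_out, 4, 4)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=2, pad=1)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes with a
    learned affine map; the standard stabilizer for style-transfer GANs.

    Implemented as one fused op with an analytic backward pass (this layer
    sits after almost every convolution, so graph overhead matters).
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.gamma, self.beta, self.eps
        data = x.data
        mu = data.mean(axis=(2, 3), keepdims=True)
        centered = data - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = centered * inv_std
        out_data = xhat * gamma.data + beta.data

        def bwd(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)).reshape(beta.data.shape))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)).reshape(gamma.data.shape))
            if x.requires_grad:
                gxhat = g * gamma.data
                m1 = gxhat.mean(axis=(2, 3), keepdims=True)
                m2 = (gxhat * xhat).mean(axis=(2, 3), keepdims=True)
                x._accum(inv_std * (gxhat - m1 - xhat * m2))

        return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with the GAN-conventional moments (0.5, 0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
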