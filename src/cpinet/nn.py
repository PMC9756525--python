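"""Layers, parameter initialisation and the Adam optimizer.

Thin conveniences over :mod:`cpinet.autodiff`: a dense layer, a same-length
1-D convolution (expressed as unfold + matmul so the im2col of a fixed input
can be cached), and Adam with the usual bias-corrected moment estimates.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, unfold1d


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    bound = np.sqrt(3.0) / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    """Dense layer y = x W + b with W of shape (in_dim, out_dim)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(kaiming_uniform(rng, (in_dim, out_dim), in_dim),
                             requires_grad=True)
        self.bias = Tensor(np.zeros((1, out_dim)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Conv1dSame:
    """Same-length 1-D convolution along the residue axis.

    Input (L, C_in) -> output (L, C_out), odd kernel, symmetric zero
    padding, stride 1.  Implemented as unfold -> matmul; `from_unfolded`
    accepts a precomputed unfolded input (useful when the input never
    changes across optimisation steps, e.g. raw embeddings).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = Tensor(
            kaiming_uniform(rng, (fan_in, out_channels), fan_in),
            requires_grad=True)
        self.bias = Tensor(np.zeros((1, out_channels)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return self.from_unfolded(unfold1d(x, self.kernel_size))

    def from_unfolded(self, unfolded: Tensor) -> Tensor:
        return unfolded @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
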