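"""Layers and the Adam optimizer built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor, affine


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal((fan_in, fan_out)) * scale).astype(DTYPE)


class Linear:
    """Affine map ``y = act(x @ W + b)`` (fused activation optional).

    ``scale`` shrinks the Kaiming init; output layers of deep residual
    stacks use scale < 1 so the network starts close to the identity.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 scale: float = 1.0):
        self.W = Parameter(kaiming(rng, in_dim, out_dim) * scale)
        self.b = Parameter(np.zeros(out_dim, dtype=DTYPE))

    def __call__(self, x: Tensor, activation: str = None) -> Tensor:
        return affine(x, self.W, self.b, activation)

    def parameters(self):
        return [self.W, self.b]


class BatchNorm1d:
    """Batch normalization over rows, with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv_std
        gamma, beta = self.gamma, self.beta
        out = Tensor(xhat * gamma.data + beta.data, True, (x, gamma, beta))
        n = x.data.shape[0]
        use_batch_stats = self.training

        def _backward():
            go = out.grad
            if gamma.requires_grad:
                gamma._accumulate((go * xhat).sum(axis=0))
            if beta.requires_grad:
                beta._accumulate(go.sum(axis=0))
            if x.requires_grad:
                dxhat = go * gamma.data
                if use_batch_stats:
                    # full batch-norm jacobian (mean and var depend on x)
                    dx = (dxhat - dxhat.mean(axis=0)
                          - xhat * (dxhat * xhat).mean(axis=0)) * inv_std
                else:
                    dx = dxhat * inv_std
                x._accumulate(dx)

        out._backward = _backward
        return out

    def parameters(self):
        return [self.gamma, self.beta]


class MLP:
    """Stack of Linear layers with ReLU between them (linear output)."""

    def __init__(self, dims, rng: np.random.Generator, final_scale: float = 1.0):
        self.layers = [
            Linear(a, b, rng,
                   scale=(final_scale if i == len(dims) - 2 else 1.0))
            for i, (a, b) in enumerate(zip(dims[:-1], dims[1:]))]

    def __call__(self, x: Tensor) -> Tensor:
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            x = layer(x, activation=None if i == last else "relu")
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay on gradients."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
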