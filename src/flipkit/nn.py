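"""Minimal neural-network engine for sequence regression.

A small, self-contained stack of numpy layers (1-D convolution,
batch normalization, LeakyReLU, dense, softplus) with hand-written
backward passes, an Adam optimizer with L2 weight decay, and a residual
convolutional regression model that outputs the two shape parameters of
a beta distribution per input sequence.  Written for 17 x 4 one-hot DNA
inputs at desk scale; everything is deterministic given the seed.

The backward pass propagates gradients to the input as well, which is
what integrated-gradients attribution needs, and the first convolutional
layer's linear activations are exposed for filter analysis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1d", "BatchNorm", "LeakyReLU", "Softplus",
           "ResidualBlock", "BetaResNet", "Adam"]

_EPS = 1e-5


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = value
        self.grad = np.zeros_like(value)


class Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Conv1d:
    """Same-padding 1-D convolution on (batch, length, channels) arrays.

    Weight layout: W[(c * k) + j, f] couples input channel c at kernel
    offset j to output filter f.
    """

    def __init__(self, kernel, c_in, c_out, rng):
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, scale, (kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._pl = (kernel - 1) // 2
        self._pr = kernel - 1 - self._pl
        self._cols = None
        self._shape = None

    def params(self):
        return [self.W, self.b]

    @property
    def filter_weights(self):
        """(kernel, c_in, c_out) view of the weights."""
        return self.W.value.reshape(self.c_in, self.kernel,
                                    self.c_out).transpose(1, 0, 2)

    def forward(self, x, train=True):
        B, L, C = x.shape
        xp = np.pad(x, ((0, 0), (self._pl, self._pr), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=1
        )                                   # (B, L, C, k); cols[b,l,c,j]
        cols = np.ascontiguousarray(cols).reshape(B, L, C * self.kernel)
        self._cols = cols
        self._shape = (B, L, C)
        y = cols @ self.W.value + self.b.value
        return y

    def backward(self, dy):
        B, L, C = self._shape
        k = self.kernel
        flat = self._cols.reshape(B * L, C * k)
        self.W.grad += flat.T @ dy.reshape(B * L, self.c_out)
        self.b.grad += dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.value.T).reshape(B, L, C, k)
        dxp = np.zeros((B, L + k - 1, C))
        for j in range(k):
            dxp[:, j:j + L, :] += dcols[:, :, :, j]
        return dxp[:, self._pl:self._pl + L, :]


class BatchNorm:
    """Batch normalization over all non-channel axes."""

    def __init__(self, n_channels, momentum=0.9):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.momentum = momentum
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + _EPS)
        xn = (x - mu) * ivar
        self._cache = (xn, ivar, axes, train,
                       int(np.prod([x.shape[a] for a in axes])))
        return self.gamma.value * xn + self.beta.value

    def backward(self, dy):
        xn, ivar, axes, train, m = self._cache
        self.gamma.grad += (dy * xn).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxn = dy * self.gamma.value
        if not train:
            return dxn * ivar
        # standard batch-norm backward with batch statistics
        return (ivar / m) * (
            m * dxn - dxn.sum(axis=axes) - xn * (dxn * xn).sum(axis=axes)
        )


class LeakyReLU:
    def __init__(self, alpha=0.1):
        self.alpha = alpha
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Softplus:
    def __init__(self):
        self._x = None

    def params(self):
        return []

    def forward(self, x, train=True):
        self._x = x
        return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)

    def backward(self, dy):
        return dy / (1.0 + np.exp(-self._x))


class _Chain:
    def __init__(self, layers):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock:
    """Two-convolution residual block.

    out = act(bn2(conv_b(act(bn1(conv_a(x))))) + skip(x)); conv_a carries
    the wide kernel, conv_b is 1 x 1; skip is identity when channel counts
    match, else a 1 x 1 projection.
    """

    def __init__(self, c_in, filters, kernels, rng, act_alpha=0.1):
        k_a, k_b = kernels
        self.conv_a = Conv1d(k_a, c_in, filters, rng)
        self.bn1 = BatchNorm(filters)
        self.act1 = LeakyReLU(act_alpha)
        self.conv_b = Conv1d(k_b, filters, filters, rng)
        self.bn2 = BatchNorm(filters)
        self.act_out = LeakyReLU(act_alpha)
        self.skip = None if c_in == filters else Conv1d(1, c_in, filters, rng)

    def params(self):
        out = (self.conv_a.params() + self.bn1.params()
               + self.conv_b.params() + self.bn2.params())
        if self.skip is not None:
            out += self.skip.params()
        return out

    def forward(self, x, train=True):
        h = self.conv_a.forward(x, train)
        h = self.act1.forward(self.bn1.forward(h, train), train)
        h = self.bn2.forward(self.conv_b.forward(h, train), train)
        s = x if self.skip is None else self.skip.forward(x, train)
        return self.act_out.forward(h + s, train)

    def backward(self, dy):
        dy = self.act_out.backward(dy)
        dh, ds = dy, dy
        dh = self.conv_b.backward(self.bn2.backward(dh))
        dh = self.bn1.backward(self.act1.backward(dh))
        dx = self.conv_a.backward(dh)
        if self.skip is None:
            dx = dx + ds
        else:
            dx = dx + self.skip.backward(ds)
        return dx


class BetaResNet:
    """Residual convolutional network with a two-parameter beta head.

    One-hot (length x 4) inputs pass through ``n_blocks`` residual blocks
    and are flattened into two parallel fully connected stacks, each
    ending in a softplus so that the two outputs (alpha, beta) are
    strictly positive (offset 1e-3).
    """

    SHAPE_OFFSET = 1e-3

    def __init__(self, seq_len=17, n_channels=4, n_blocks=3, filters=64,
                 kernels=(9, 1), fc_units=64, seed=0):
        rng = np.random.default_rng(seed)
        self.seq_len = seq_len
        self.blocks = []
        c = n_channels
        for _ in range(n_blocks):
            self.blocks.append(ResidualBlock(c, filters, kernels, rng))
            c = filters
        n_flat = seq_len * filters
        self.head_alpha = _Chain([
            Dense(n_flat, fc_units, rng), BatchNorm(fc_units), LeakyReLU(),
            Dense(fc_units, 1, rng), Softplus(),
        ])
        self.head_beta = _Chain([
            Dense(n_flat, fc_units, rng), BatchNorm(fc_units), LeakyReLU(),
            Dense(fc_units, 1, rng), Softplus(),
        ])
        self._flat_shape = None

    def params(self):
        out = [p for b in self.blocks for p in b.params()]
        out += self.head_alpha.params() + self.head_beta.params()
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x, train=True):
        h = x
        for block in self.blocks:
            h = block.forward(h, train)
        B = h.shape[0]
        self._flat_shape = h.shape
        flat = h.reshape(B, -1)
        alpha = self.head_alpha.forward(flat, train)[:, 0]
        beta = self.head_beta.forward(flat, train)[:, 0]
        return alpha + self.SHAPE_OFFSET, beta + self.SHAPE_OFFSET

    def backward(self, dalpha, dbeta):
        da = self.head_alpha.backward(dalpha[:, None])
        db = self.head_beta.backward(dbeta[:, None])
        dh = (da + db).reshape(self._flat_shape)
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        return dh

    def first_conv_activations(self, x):
        """Linear activations of the first convolutional layer (the wide
        conv of block 1, before its skip connection), (B, L, filters)."""
        return self.blocks[0].conv_a.forward(x, train=False)

    def first_conv_weights(self):
        """(kernel, 4, filters) weights of the first convolutional layer."""
        return self.blocks[0].conv_a.filter_weights

    def input_gradient(self, x, dalpha, dbeta):
        """d(scalar)/d(input) for given output cotangents, in eval mode."""
        self.forward(x, train=False)
        self.zero_grad()
        return self.backward(dalpha, dbeta)


class Adam:
    def __init__(self, params, lr=0.01, weight_decay=0.0,
                 betas=(0.9, 0.999), eps=1e-8, clip_norm=10.0):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        if self.clip_norm:
            total = np.sqrt(sum(float((p.grad**2).sum())
                                for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    p.grad *= scale
        for i, p in enumerate(self.params):
            g = p.grad + self.wd * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
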