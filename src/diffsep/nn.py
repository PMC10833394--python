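"""A compact CPU tensor-layer library with explicit backpropagation.

Implements exactly the pieces the image-translation networks need: strided
convolution and transposed convolution (im2col based), instance
normalization, leaky ReLU / ReLU / tanh / sigmoid, inverted dropout and the
Adam optimizer.  Layers cache their forward activations and expose
``backward`` returning the input gradient while accumulating parameter
gradients; parameters are plain float64 arrays so checkpoints round-trip
bit-exactly through ``.npz`` files.

Array layout is (batch, channels, height, width) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Sequential",
    "Adam",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, C*kh*kw, OH*OW) patch matrix (a view-based copy)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(windows).reshape(n, c * kh * kw, oh * ow), (oh, ow)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add the inverse of _im2col."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for a in range(kh):
        for b in range(kw):
            xp[:, :, a : a + stride * oh : stride, b : b + stride * ow : stride] += cols[
                :, :, a, b
            ]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    """Strided 2D convolution (cross-correlation), square kernel."""

    def __init__(self, c_in, c_out, kernel=4, stride=2, pad=1, rng=None, bias=True):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        cols, (oh, ow) = _im2col(x, k, k, s, p)
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        y = np.einsum("fk,nkp->nfp", wmat, cols).reshape(x.shape[0], -1, oh, ow)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache = (x.shape, cols)
        return y

    def backward(self, grad):
        x_shape, cols = self._cache
        n, f = grad.shape[:2]
        gmat = grad.reshape(n, f, -1)
        self.weight.grad += np.einsum("nfp,nkp->fk", gmat, cols).reshape(
            self.weight.value.shape
        )
        if self.bias is not None:
            self.bias.grad += gmat.sum(axis=(0, 2))
        wmat = self.weight.value.reshape(f, -1)
        dcols = np.einsum("fk,nfp->nkp", wmat, gmat)
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Strided transposed convolution: the adjoint of Conv2d's forward map."""

    def __init__(self, c_in, c_out, kernel=4, stride=2, pad=1, rng=None, bias=True):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        # stored in the layout of the adjoint convolution: (c_in, c_out, k, k)
        self.weight = Parameter(rng.normal(0.0, scale, (c_in, c_out, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _out_shape(self, x_shape):
        n, c, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.pad
        return (
            n,
            self.weight.value.shape[1],
            (h - 1) * s - 2 * p + k,
            (w - 1) * s - 2 * p + k,
        )

    def forward(self, x):
        n, c, h, w = x.shape
        out_shape = self._out_shape(x.shape)
        wmat = self.weight.value.reshape(c, -1)  # (c_in, c_out*k*k)
        cols = np.einsum("ck,ncp->nkp", wmat, x.reshape(n, c, -1))
        y = _col2im(cols, out_shape, self.kernel, self.kernel, self.stride, self.pad)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache = x
        return y

    def backward(self, grad):
        x = self._cache
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        gcols, _ = _im2col(grad, k, k, s, p)  # (n, c_out*k*k, h*w)
        self.weight.grad += np.einsum(
            "ncp,nkp->ck", x.reshape(n, c, -1), gcols
        ).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        wmat = self.weight.value.reshape(c, -1)
        dx = np.einsum("ck,nkp->ncp", wmat, gcols).reshape(x.shape)
        return dx


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization with affine parameters."""

    def __init__(self, channels, eps=1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, inv = self._cache
        m = xhat.shape[2] * xhat.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(2, 3), keepdims=True)
        gx = (g * xhat).sum(axis=(2, 3), keepdims=True)
        return inv * (g - gsum / m - xhat * gx / m)


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; the mask source doubles as the network's noise input."""

    def __init__(self, rate=0.5, rng=None):
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self.active = True
        self._mask = None

    def forward(self, x):
        if not self.active or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam with the usual bias correction; state is checkpointable."""

    def __init__(self, params: list[Parameter], lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state_arrays(self, state) -> None:
        self.t = int(state["t"])
        for i in range(len(self.m)):
            self.m[i][...] = state[f"m{i}"]
            self.v[i][...] = state[f"v{i}"]
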