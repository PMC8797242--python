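"""Layer zoo: parameterized modules with explicit forward/backward passes.

The network graph of the morphology models is static, so instead of a general
autodiff tape each layer caches what its backward pass needs.  Conventions:

* arrays are (N, C, *spatial), float32 by default;
* ``Layer.params()`` yields :class:`Param` objects (trainable);
* spectral weight normalization wraps Conv/Linear weights: the trainable array
  is the raw weight, the forward pass divides by the leading singular value
  estimated with one power iteration (u/v are non-trainable buffers).
"""

from __future__ import annotations

import numpy as np

from . import functional as F

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; subclasses define forward(x, train) and backward(dy)."""

    def params(self) -> list[Param]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.params())
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class _SpectralState:
    """Power-iteration state for one weight matrix view (rows = out dim)."""

    def __init__(self, rng: np.random.Generator, rows: int, cols: int):
        u = rng.standard_normal(rows)
        self.u = (u / np.linalg.norm(u)).astype(DTYPE)
        self.v = np.zeros(cols, dtype=DTYPE)
        self.sigma = 1.0

    def normalize(self, w: np.ndarray, update: bool) -> np.ndarray:
        wmat = w.reshape(w.shape[0], -1)
        if update:
            v = wmat.T @ self.u
            v /= np.linalg.norm(v) + 1e-12
            u = wmat @ v
            u /= np.linalg.norm(u) + 1e-12
            self.u, self.v = u.astype(DTYPE), v.astype(DTYPE)
        self.sigma = float(self.u @ wmat @ self.v) or 1.0
        return w / self.sigma

    def grad(self, dwbar: np.ndarray, wbar: np.ndarray) -> np.ndarray:
        """dL/dW from dL/dW_bar with u, v held constant."""
        inner = float(np.sum(dwbar * wbar))
        uv = np.outer(self.u, self.v).reshape(dwbar.shape)
        return (dwbar - inner * uv) / self.sigma


class ConvNd(Layer):
    def __init__(self, rng, cin, cout, k, stride=1, pad=None, bias=True, spectral=True):
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.k = k
        self.w = Param(None)
        self.b = Param(np.zeros(cout, dtype=DTYPE)) if bias else None
        self._cin, self._cout = cin, cout
        self._rng = rng
        self._spectral = spectral
        self._built_dim = None

    def build(self, d: int):
        shape = (self._cout, self._cin) + (self.k,) * d
        fan_in = self._cin * self.k**d
        self.w.value = _kaiming(self._rng, shape, fan_in)
        self.w.grad = np.zeros_like(self.w.value)
        self.sn = (
            _SpectralState(self._rng, self._cout, self._cin * self.k**d)
            if self._spectral
            else None
        )
        self._built_dim = d
        return self

    def forward(self, x, train=False):
        d = x.ndim - 2
        if self._built_dim is None:
            self.build(d)
        w = self.w.value
        if self.sn is not None:
            w = self.sn.normalize(w, update=train)
        self._wbar = w
        self._x_spatial = x.shape[2:]
        b = self.b.value if self.b is not None else None
        y, self._cols = F.conv_forward(x, w, b, self.stride, self.pad)
        return y

    def backward(self, dy):
        dwbar, db = F.conv_backward_weight(self._cols, dy, self.w.value.shape)
        if self.sn is not None:
            self.w.grad += self.sn.grad(dwbar, self._wbar)
        else:
            self.w.grad += dwbar
        if self.b is not None:
            self.b.grad += db
        dx = F.conv_backward_input(dy, self._wbar, self._x_spatial, self.stride, self.pad)
        self._cols = None
        return dx


class ConvTransposeNd(Layer):
    """Stride-2 transposed convolution (adjoint of ConvNd's spatial map)."""

    def __init__(self, rng, cin, cout, k=4, stride=2, pad=1, bias=True, spectral=True):
        self.stride, self.pad, self.k = stride, pad, k
        self.w = Param(None)  # shape (cin, cout, *K): conv weight of the adjoint
        self.b = Param(np.zeros(cout, dtype=DTYPE)) if bias else None
        self._cin, self._cout = cin, cout
        self._rng = rng
        self._spectral = spectral
        self._built_dim = None

    def build(self, d):
        shape = (self._cin, self._cout) + (self.k,) * d
        self.w.value = _kaiming(self._rng, shape, self._cin * self.k**d)
        self.w.grad = np.zeros_like(self.w.value)
        self.sn = (
            _SpectralState(self._rng, self._cin, self._cout * self.k**d)
            if self._spectral
            else None
        )
        self._built_dim = d
        return self

    def forward(self, x, train=False):
        d = x.ndim - 2
        if self._built_dim is None:
            self.build(d)
        w = self.w.value
        if self.sn is not None:
            w = self.sn.normalize(w, update=train)
        self._wbar = w
        self._x = x
        out_spatial = tuple(s * self.stride for s in x.shape[2:])
        self._out_spatial = out_spatial
        y = F.conv_backward_input(x, w, out_spatial, self.stride, self.pad)
        if self.b is not None:
            y = y + self.b.value.reshape((1, -1) + (1,) * d)
        return y

    def backward(self, dy):
        d = dy.ndim - 2
        cols, _ = F._im2col(dy, self.k, self.stride, self.pad)
        # weight grad: <dy, A_W^T x> = <W . cols(dy), x>
        n = self._x.shape[0]
        xf = self._x.reshape(n, self._cin, -1)
        dwbar = np.einsum("ncp,npk->ck", xf, cols, optimize=True).reshape(
            self.w.value.shape
        )
        if self.sn is not None:
            self.w.grad += self.sn.grad(dwbar, self._wbar)
        else:
            self.w.grad += dwbar
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0,) + tuple(range(2, 2 + d)))
        dx, _ = F.conv_forward(dy, self._wbar, None, self.stride, self.pad)
        self._x = None
        return dx


class Linear(Layer):
    def __init__(self, rng, cin, cout, bias=True, spectral=True):
        self.w = Param(_kaiming(rng, (cout, cin), cin))
        self.b = Param(np.zeros(cout, dtype=DTYPE)) if bias else None
        self.sn = _SpectralState(rng, cout, cin) if spectral else None

    def forward(self, x, train=False):
        w = self.w.value
        if self.sn is not None:
            w = self.sn.normalize(w, update=train)
        self._wbar = w
        self._x = x
        y = x @ w.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        dwbar = dy.T @ self._x
        if self.sn is not None:
            self.w.grad += self.sn.grad(dwbar, self._wbar)
        else:
            self.w.grad += dwbar
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        dx = dy @ self._wbar
        self._x = None
        return dx


class BatchNorm(Layer):
    """Batch normalization over (N, *spatial) per channel; affine."""

    def __init__(self, ch, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(ch, dtype=DTYPE))
        self.beta = Param(np.zeros(ch, dtype=DTYPE))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        self._train = train
        self._axes, self._sh = axes, sh
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(sh)) * self._istd.reshape(sh)
        return self.gamma.value.reshape(sh) * self._xhat + self.beta.value.reshape(sh)

    def backward(self, dy):
        axes, sh = self._axes, self._sh
        self.gamma.grad += (dy * self._xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(sh)
        dxhat = dy * g
        if not self._train:
            return dxhat * self._istd.reshape(sh)
        n = dy.size // dy.shape[1]
        t1 = dxhat - dxhat.mean(axis=axes).reshape(sh)
        t2 = self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(sh)
        dx = (t1 - t2) * self._istd.reshape(sh)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2x(Layer):
    def forward(self, x, train=False):
        return F.avg_pool(x)

    def backward(self, dy):
        return F.avg_pool_backward(dy)


class LinearUpsample2x(Layer):
    def forward(self, x, train=False):
        self._in_spatial = x.shape[2:]
        return F.resize_linear(x, tuple(2 * s for s in self._in_spatial))

    def backward(self, dy):
        return F.resize_linear_adjoint(dy, self._in_spatial)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adam with the training configuration's (0.9, 0.999) moments."""

    def __init__(self, params: list[Param], lr=2e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def iter_layers(root: Layer):
    """Depth-first walk over a layer tree (including the root)."""
    yield root
    for v in root.__dict__.values():
        if isinstance(v, Layer):
            yield from iter_layers(v)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Layer):
                    yield from iter_layers(item)


def collect_state(root: Layer) -> dict[str, np.ndarray]:
    """Snapshot of all trainable values plus normalization buffers."""
    state: dict[str, np.ndarray] = {}
    for i, p in enumerate(root.params()):
        state[f"param_{i}"] = p.value.copy()
    b = 0
    for layer in iter_layers(root):
        for name, arr in layer.buffers().items():
            state[f"buffer_{b}_{name}"] = arr.copy()
            b += 1
        sn = getattr(layer, "sn", None)
        if isinstance(sn, _SpectralState):
            state[f"buffer_{b}_sn_u"] = sn.u.copy()
            state[f"buffer_{b}_sn_v"] = sn.v.copy()
            b += 1
    return state


def restore_state(root: Layer, state: dict[str, np.ndarray]) -> None:
    for i, p in enumerate(root.params()):
        p.value[...] = state[f"param_{i}"]
    b = 0
    for layer in iter_layers(root):
        for name in layer.buffers():
            layer.buffers()[name][...] = state[f"buffer_{b}_{name}"]
            b += 1
        sn = getattr(layer, "sn", None)
        if isinstance(sn, _SpectralState):
            sn.u = state[f"buffer_{b}_sn_u"].copy()
            sn.v = state[f"buffer_{b}_sn_v"].copy()
            b += 1
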