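"""Compact CPU neural-network engine used by the patch classifier.

Implements exactly the layers a small residual image classifier needs —
2-D convolution (via im2col + BLAS matmul), batch normalization, ReLU,
max/global-average pooling, a linear head, residual basic blocks — with
explicit, hand-derived backward passes, plus SGD with momentum and a
softmax cross-entropy loss.  Everything is float32 NCHW and fully
deterministic given the seeds fed to the initializers and the trainer.

The explicit backward passes double as the gradient source for Grad-CAM:
backpropagating a one-hot class score through the head yields the
gradient at any intermediate feature map.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A learnable array with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "velocity", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        self.name = name


class Module:
    """Base class: forward caches whatever backward needs."""

    frozen = False  # excluded from optimizer updates when True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.params()}


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold NCHW into (N*Ho*Wo, C*k*k) patch rows."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(col, dtype=F32), ho, wo


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int = 0, bias: bool = False, rng: np.random.Generator | None = None,
                 is_projection: bool = False, input_grad: bool = True) -> None:
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.is_projection = is_projection  # shortcut 1x1 convs are not counted as weighted layers
        # a stem conv never needs dL/dx; skipping it avoids a very large
        # full-resolution im2col in the transposed convolution
        self.input_grad = input_grad
        std = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.w = Param(rng.normal(0.0, std, size=(c_out, c_in, k, k)), "w")
        self.b = Param(np.zeros(c_out), "b") if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        col, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.w.value.reshape(self.c_out, -1).T  # (C*k*k, O)
        out = col @ wmat
        if self.b is not None:
            out += self.b.value
        n = x.shape[0]
        self._cache = (col, x.shape)
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        col, x_shape = self._cache
        n, o, ho, wo = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1), dtype=F32).reshape(-1, o)
        self.w.grad += (col.T @ dyf).T.reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        if not self.input_grad:
            return None
        # dx = full correlation of the (dilated) upstream gradient with the
        # spatially flipped kernel — itself an im2col matmul.
        k, s, p = self.k, self.stride, self.pad
        h_in = x_shape[2]
        w_in = x_shape[3]
        if s > 1:
            dil = np.zeros((n, o, (ho - 1) * s + 1, (wo - 1) * s + 1), dtype=F32)
            dil[:, :, ::s, ::s] = dy
        else:
            dil = dy.astype(F32, copy=False)
        rh = (h_in + 2 * p - k) % s
        rw = (w_in + 2 * p - k) % s
        if rh or rw:
            dil = np.pad(dil, ((0, 0), (0, 0), (0, rh), (0, rw)))
        wrot = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_in, O, k, k)
        col2, h2, w2 = _im2col(dil, k, 1, k - 1 - p)
        dx = (col2 @ wrot.reshape(self.c_in, -1).T.reshape(o * k * k, self.c_in))
        # note: wrot reshaped so rows are (O,k,k) flattened in the same order as col2
        return dx.reshape(n, h2, w2, self.c_in).transpose(0, 3, 1, 2)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c), "gamma")
        self.beta = Param(np.zeros(c), "beta")
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"gamma": self.gamma.value, "beta": self.beta.value,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train=False):
        g = self.gamma.value.reshape(1, -1, 1, 1)
        b = self.beta.value.reshape(1, -1, 1, 1)
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
        self._cache = (xhat.astype(F32), inv_std.astype(F32), train)
        return (g * xhat + b).astype(F32)

    def backward(self, dy):
        xhat, inv_std, was_train = self._cache
        g = self.gamma.value.reshape(1, -1, 1, 1)
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        if not was_train:
            return (dxhat * inv_std.reshape(1, -1, 1, 1)).astype(F32)
        n_eff = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std.reshape(1, -1, 1, 1) / n_eff) * (n_eff * dxhat - s1 - xhat * s2)
        return dx.astype(F32)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(F32)


class MaxPool2d(Module):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1) -> None:
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, train=False):
        # max over the k*k shifted strided views; cheaper than materializing
        # the full window tensor
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        hp, wp = xp.shape[2], xp.shape[3]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        best = None
        arg = None
        for ki in range(k):
            for kj in range(k):
                v = xp[:, :, ki:ki + (ho - 1) * s + 1:s, kj:kj + (wo - 1) * s + 1:s]
                if best is None:
                    best = v.copy()
                    arg = np.zeros(best.shape, dtype=np.int8)
                else:
                    m = v > best
                    np.copyto(best, v, where=m)
                    arg[m] = ki * k + kj
        self._arg = arg
        self._geom = (x.shape, xp.shape)
        return best.astype(F32)

    def backward(self, dy):
        k, s, p = self.k, self.stride, self.pad
        x_shape, xp_shape = self._geom
        n, c, ho, wo = dy.shape
        hp, wp = xp_shape[2], xp_shape[3]
        ai, aj = np.divmod(self._arg, k)
        ii = (np.arange(ho) * s)[None, None, :, None] + ai
        jj = (np.arange(wo) * s)[None, None, None, :] + aj
        plane = (np.arange(n * c) * (hp * wp)).reshape(n, c, 1, 1)
        flat_idx = (plane + ii * wp + jj).ravel()
        dxp = np.zeros(n * c * hp * wp, dtype=F32)
        np.add.at(dxp, flat_idx, dy.ravel())
        dxp = dxp.reshape(n, c, hp, wp)
        return dxp[:, :, p:p + x_shape[2], p:p + x_shape[3]]


class GlobalAvgPool(Module):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(F32)

    def backward(self, dy):
        n, c, h, w = self._shape
        return (np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)).astype(F32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / d_in)
        self.w = Param(rng.uniform(-bound, bound, size=(d_out, d_in)), "w")
        self.b = Param(rng.uniform(-bound, bound, size=d_out), "b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return (x @ self.w.value.T + self.b.value).astype(F32)

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.w.value).astype(F32)


class BasicBlock(Module):
    """Two 3x3 conv+BN with a ReLU between, residual add, final ReLU.

    When the block changes resolution or width, the skip path is a
    stride-matched 1x1 projection conv + BN.
    """

    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride, 0, rng=rng, is_projection=True)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None
            self.proj_bn = None

    def submodules(self):
        mods = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.proj is not None:
            mods += [self.proj, self.proj_bn]
        return mods

    def params(self):
        return [p for m in self.submodules() for p in m.params()]

    def state(self):
        out = {}
        for i, m in enumerate(self.submodules()):
            for k, v in m.state().items():
                out[f"m{i}.{k}"] = v
        return out

    def forward(self, x, train=False):
        out = self.conv1.forward(x, train)
        out = self.bn1.forward(out, train)
        out = self.relu1.forward(out, train)
        out = self.conv2.forward(out, train)
        out = self.bn2.forward(out, train)
        if self.proj is not None:
            idn = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            idn = x
        y = out + idn
        self._mask = y > 0
        return np.where(self._mask, y, 0).astype(F32)

    def backward(self, dy):
        dsum = np.where(self._mask, dy, 0).astype(F32)
        d = self.bn2.backward(dsum)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        dx = self.conv1.backward(d)
        if self.proj is not None:
            dx = dx + self.proj.backward(self.proj_bn.backward(dsum))
        else:
            dx = dx + dsum
        return dx


class Sequential(Module):
    def __init__(self, layers: list[Module]) -> None:
        self.layers = layers

    def params(self):
        return [p for m in self.layers if not m.frozen for p in m.params()]

    def all_params(self):
        return [p for m in self.layers for p in m.params()]

    def forward(self, x, train=False):
        for m in self.layers:
            x = m.forward(x, train)
        return x

    def backward(self, dy):
        for m in reversed(self.layers):
            dy = m.backward(dy)
        return dy

    def forward_upto(self, x, index: int, train: bool = False):
        """Run layers [0, index], return that activation."""
        for m in self.layers[: index + 1]:
            x = m.forward(x, train)
        return x

    def forward_from(self, x, index: int, train: bool = False):
        for m in self.layers[index + 1:]:
            x = m.forward(x, train)
        return x

    def backward_downto(self, dy, index: int):
        """Backprop through layers (end, index], return grad at layer index's output."""
        for m in reversed(self.layers[index + 1:]):
            dy = m.backward(dy)
        return dy

    def state(self):
        out = {}
        for i, m in enumerate(self.layers):
            for k, v in m.state().items():
                out[f"layer{i}.{k}"] = v
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state()
        if set(own) != set(state):
            raise ShapeMismatchError("checkpoint keys do not match the model")
        for i, m in enumerate(self.layers):
            for k in m.state():
                src = state[f"layer{i}.{k}"]
                dst = m.state()[k]
                if src.shape != dst.shape:
                    raise ShapeMismatchError(
                        f"layer{i}.{k}: checkpoint {src.shape} vs model {dst.shape}")
        for i, m in enumerate(self.layers):
            if isinstance(m, BatchNorm2d):
                m.gamma.value[...] = state[f"layer{i}.gamma"]
                m.beta.value[...] = state[f"layer{i}.beta"]
                m.running_mean = state[f"layer{i}.running_mean"].astype(F32).copy()
                m.running_var = state[f"layer{i}.running_var"].astype(F32).copy()
            elif isinstance(m, BasicBlock):
                for j, sm in enumerate(m.submodules()):
                    for k in sm.state():
                        v = state[f"layer{i}.m{j}.{k}"]
                        if isinstance(sm, BatchNorm2d) and k == "running_mean":
                            sm.running_mean = v.astype(F32).copy()
                        elif isinstance(sm, BatchNorm2d) and k == "running_var":
                            sm.running_var = v.astype(F32).copy()
                        else:
                            for p in sm.params():
                                if p.name == k:
                                    p.value[...] = v
            else:
                for p in m.params():
                    p.value[...] = state[f"layer{i}.{p.name}"]


class ShapeMismatchError(ValueError):
    """Checkpoint incompatible with the model's shapes."""


class SGD:
    """Plain SGD with momentum: v <- mu*v + g; p <- p - lr*v."""

    def __init__(self, model: Sequential, lr: float, momentum: float = 0.9) -> None:
        self.model, self.lr, self.momentum = model, lr, momentum

    def zero_grad(self) -> None:
        for p in self.model.all_params():
            p.grad[...] = 0

    def step(self) -> None:
        for p in self.model.params():  # skips frozen modules
            p.velocity[...] = self.momentum * p.velocity + p.grad
            p.value[...] -= self.lr * p.velocity


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.mean(np.log(np.clip(p[np.arange(n), labels], 1e-12, None)))
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(F32)
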