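"""Minimal NumPy neural-network layers with exact backpropagation.

Each layer implements ``forward(x, training, rng)`` and
``backward(grad)``; trainable arrays live in ``layer.params`` and their
gradients (repopulated on every backward pass) in ``layer.grads``.
Parameters are updated in place by the optimizer, so references held by
optimizer state stay valid.

Conventions match the reference deep-learning stacks the architecture
was designed in: "same" padding pads ``(k-1)//2`` on the left and the
remainder on the right; max-pooling uses floor semantics; dropout is
"inverted" (activations scaled by ``1/(1-rate)`` at train time, identity
at inference); the LSTM is the standard forget/input/output-gate cell
run in sequence-output mode, with gates packed in (i, f, g, o) order and
a unit forget-gate bias at initialization.

L2 weight decay: a layer constructed with ``l2 > 0`` contributes
``l2 * sum(W**2)`` to the penalized loss (kernel weights only, never
biases) and adds ``2 * l2 * W`` to its kernel gradient during backward.
"""

from __future__ import annotations

import numpy as np


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _activate(z, activation):
    if activation is None:
        return z
    if activation == "relu":
        return relu(z)
    if activation == "sigmoid":
        return sigmoid(z)
    if activation == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {activation!r}")


def _activation_grad(grad, z, a, activation):
    """dL/dz given dL/da, with a = activation(z)."""
    if activation is None:
        return grad
    if activation == "relu":
        return grad * (z > 0)
    if activation == "sigmoid":
        return grad * a * (1.0 - a)
    if activation == "tanh":
        return grad * (1.0 - a * a)
    raise ValueError(f"unknown activation {activation!r}")


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer; subclasses fill in forward/backward."""

    name: str = ""
    path: str = ""          # architecture path this layer belongs to
    kernel: int | None = None
    units: int | None = None
    stride: int | None = None

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.last_output_shape: tuple | None = None

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover
        raise NotImplementedError

    def l2_penalty(self) -> float:
        return 0.0

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv1D(Layer):
    """1-D convolution over (N, L, C) inputs.

    Each of the ``filters`` output neurons slides a receptive field of
    ``kernel`` positions across the sequence and applies a pointwise
    non-linearity to the windowed weighted sum -- the textbook
    cross-correlation form of a convolutional layer.
    """

    def __init__(self, in_channels, filters, kernel, stride=1,
                 padding="same", activation="relu", l2=0.0, *,
                 rng: np.random.Generator, name="conv1d"):
        super().__init__()
        if filters < 1 or kernel < 1 or stride < 1:
            raise ValueError("filters, kernel and stride must be positive")
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.activation = activation
        self.l2 = float(l2)
        self.name = name
        self.units = filters
        fan_in = kernel * in_channels
        self.params["W"] = glorot_uniform(
            rng, (kernel, in_channels, filters), fan_in, filters)
        self.params["b"] = np.zeros(filters)

    def _pads(self):
        if self.padding == "same":
            total = self.kernel - 1
            left = total // 2
            return left, total - left
        if self.padding == "valid":
            return 0, 0
        raise ValueError(f"unknown padding {self.padding!r}")

    def forward(self, x, training=False, rng=None):
        W, b = self.params["W"], self.params["b"]
        left, right = self._pads()
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        Lp = xp.shape[1]
        L_out = (Lp - self.kernel) // self.stride + 1
        if L_out < 1:
            raise ValueError(
                f"{self.name}: input too short ({x.shape[1]}) for "
                f"kernel {self.kernel}")
        z = np.broadcast_to(b, (x.shape[0], L_out, self.filters)).copy()
        end = (L_out - 1) * self.stride + 1
        for j in range(self.kernel):
            z += xp[:, j:j + end:self.stride, :] @ W[j]
        a = _activate(z, self.activation)
        self._cache = (xp, z, a, x.shape[1], left)
        self.last_output_shape = a.shape
        return a

    def backward(self, grad, skip_activation=False):
        xp, z, a, L_in, left = self._cache
        W = self.params["W"]
        dz = grad if skip_activation else _activation_grad(
            grad, z, a, self.activation)
        L_out = dz.shape[1]
        end = (L_out - 1) * self.stride + 1
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            xs = xp[:, j:j + end:self.stride, :]
            dW[j] = np.einsum("nlc,nlf->cf", xs, dz)
            dxp[:, j:j + end:self.stride, :] += dz @ W[j].T
        if self.l2:
            dW += 2.0 * self.l2 * W
        self.grads["W"] = dW
        self.grads["b"] = dz.sum(axis=(0, 1))
        return dxp[:, left:left + L_in, :]

    def l2_penalty(self):
        return self.l2 * float(np.sum(self.params["W"] ** 2))


class MaxPool1D(Layer):
    """Max pooling with floor semantics (trailing remainder dropped)."""

    def __init__(self, pool=2, stride=2, name="maxpool"):
        super().__init__()
        if pool != stride:
            raise ValueError("only pool == stride is supported")
        self.pool = pool
        self.stride = stride
        self.name = name

    def forward(self, x, training=False, rng=None):
        N, L, C = x.shape
        L_out = L // self.pool
        if L_out < 1:
            raise ValueError(f"{self.name}: input length {L} shorter than "
                             f"pool size {self.pool}")
        xw = x[:, :L_out * self.pool, :].reshape(N, L_out, self.pool, C)
        idx = xw.argmax(axis=2)
        out = np.take_along_axis(xw, idx[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (idx, x.shape)
        self.last_output_shape = out.shape
        return out

    def backward(self, grad):
        idx, in_shape = self._cache
        N, L, C = in_shape
        L_out = grad.shape[1]
        dxw = np.zeros((N, L_out, self.pool, C), dtype=grad.dtype)
        np.put_along_axis(dxw, idx[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(in_shape, dtype=grad.dtype)
        dx[:, :L_out * self.pool, :] = dxw.reshape(N, L_out * self.pool, C)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate=0.5, name="dropout"):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.name = name

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            self.last_output_shape = x.shape
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        out = x * self._mask
        self.last_output_shape = out.shape
        return out

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def __init__(self, name="flatten"):
        super().__init__()
        self.name = name

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        out = x.reshape(x.shape[0], -1)
        self.last_output_shape = out.shape
        return out

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, units, activation=None, l2=0.0, *,
                 rng: np.random.Generator, name="dense"):
        super().__init__()
        if units < 1:
            raise ValueError("units must be positive")
        self.in_features = in_features
        self.units = units
        self.activation = activation
        self.l2 = float(l2)
        self.name = name
        self.params["W"] = glorot_uniform(
            rng, (in_features, units), in_features, units)
        self.params["b"] = np.zeros(units)

    def forward(self, x, training=False, rng=None):
        z = x @ self.params["W"] + self.params["b"]
        a = _activate(z, self.activation)
        self._cache = (x, z, a)
        self.last_output_shape = a.shape
        return a

    def backward(self, grad, skip_activation=False):
        x, z, a = self._cache
        dz = grad if skip_activation else _activation_grad(
            grad, z, a, self.activation)
        dW = x.T @ dz
        if self.l2:
            dW += 2.0 * self.l2 * self.params["W"]
        self.grads["W"] = dW
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T

    def l2_penalty(self):
        return self.l2 * float(np.sum(self.params["W"] ** 2))


class LSTM(Layer):
    """Sequence-output LSTM cell.

    For input x_t and previous hidden state h_{t-1}, the forget, input
    and output gates are sigmoid transforms of ``W x_t + U h_{t-1} + b``;
    the cell state is ``s_t = f_t * s_{t-1} + i_t * tanh(...)`` and the
    emitted hidden state ``h_t = o_t * tanh(s_t)``.  One hidden vector is
    emitted per sequence position, giving a (N, T, units) output.

    Parameter count is ``4 * (units*d + units^2 + units)`` for input
    dimension ``d``.
    """

    def __init__(self, input_dim, units, *, rng: np.random.Generator,
                 name="lstm"):
        super().__init__()
        if units < 1:
            raise ValueError("units must be positive")
        self.input_dim = input_dim
        self.units = units
        self.name = name
        u = units
        self.params["Wx"] = glorot_uniform(
            rng, (input_dim, 4 * u), input_dim, u)
        self.params["Wh"] = glorot_uniform(rng, (u, 4 * u), u, u)
        b = np.zeros(4 * u)
        b[u:2 * u] = 1.0  # unit forget-gate bias
        self.params["b"] = b

    def forward(self, x, training=False, rng=None):
        N, T, _ = x.shape
        u = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((N, u))
        c = np.zeros((N, u))
        H = np.empty((N, T, u))
        cache = []
        xw = x @ Wx  # precompute input contribution for all steps
        for t in range(T):
            zt = xw[:, t, :] + h @ Wh + b
            i = sigmoid(zt[:, :u])
            f = sigmoid(zt[:, u:2 * u])
            g = np.tanh(zt[:, 2 * u:3 * u])
            o = sigmoid(zt[:, 3 * u:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            H[:, t, :] = h
        self._cache = (x, cache)
        self.last_output_shape = H.shape
        return H

    def backward(self, grad):
        x, cache = self._cache
        N, T, _ = x.shape
        u = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((N, u))
        dc_next = np.zeros((N, u))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = grad[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads["Wx"] = dWx
        self.grads["Wh"] = dWh
        self.grads["b"] = db
        return dx


class Sequential(Layer):
    """A chain of layers applied in order."""

    def __init__(self, layers, name="sequential"):
        super().__init__()
        self.layers = list(layers)
        self.name = name

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        self.last_output_shape = x.shape
        return x

    def backward(self, grad, skip_last_activation=False):
        for pos, layer in enumerate(reversed(self.layers)):
            if pos == 0 and skip_last_activation:
                grad = layer.backward(grad, skip_activation=True)
            else:
                grad = layer.backward(grad)
        return grad

    def walk(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, ParallelPaths)):
                yield from layer.walk()
            else:
                yield layer


class ParallelPaths(Layer):
    """Feed one input through parallel branches and concatenate.

    Each branch must end in a layer producing a 2-D (N, width) output
    (typically a Flatten); the branch outputs are concatenated along the
    feature axis.  Gradients flowing back are split by branch width and
    the per-branch input gradients are summed.
    """

    def __init__(self, branches, name="parallel"):
        super().__init__()
        self.branches = [b if isinstance(b, Sequential) else Sequential(b)
                         for b in branches]
        self.name = name

    def forward(self, x, training=False, rng=None):
        outs = [b.forward(x, training=training, rng=rng)
                for b in self.branches]
        if any(o.ndim != 2 for o in outs):
            raise ValueError("every branch must produce a flat (N, k) output")
        self._widths = [o.shape[1] for o in outs]
        out = np.concatenate(outs, axis=1)
        self.last_output_shape = out.shape
        return out

    @property
    def branch_widths(self) -> list[int]:
        return list(self._widths)

    def backward(self, grad):
        splits = np.cumsum(self._widths)[:-1]
        parts = np.split(grad, splits, axis=1)
        dx = None
        for branch, part in zip(self.branches, parts):
            g = branch.backward(part)
            dx = g if dx is None else dx + g
        return dx

    def walk(self):
        for branch in self.branches:
            yield from branch.walk()


def iter_parameters(root: Sequential):
    """Yield (key, layer, param_name) triples for every trainable array."""
    for li, layer in enumerate(root.walk()):
        for pname in layer.params:
            yield f"{li}.{layer.name}.{pname}", layer, pname


def numeric_gradient(loss_fn, array, eps=1e-6):
    """Central-difference gradient of ``loss_fn()`` w.r.t. ``array`` (in place)."""
    grad = np.zeros_like(array)
    it = np.nditer(array, flags=["multi_index"])
    while not it.finished:
        ix = it.multi_index
        orig = array[ix]
        array[ix] = orig + eps
        lp = loss_fn()
        array[ix] = orig - eps
        lm = loss_fn()
        array[ix] = orig
        grad[ix] = (lp - lm) / (2 * eps)
        it.iternext()
    return grad
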