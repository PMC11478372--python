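"""Minimal sequential neural-network engine in numpy.

Implements exactly the layer zoo the beat classifier needs — 1-D
convolution, batch normalization, max pooling, a squeeze-and-excitation
channel-attention block, LSTM, dense, dropout — each with an analytic
backward pass, plus the Adam optimizer and fused softmax cross-entropy.
Everything is float64 and seeded, so two runs from the same seed are
bit-identical; gradients are validated against finite differences in the
test suite.

Array conventions: convolutional tensors are ``(batch, time, channels)``;
after the recurrent layer activations are ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def swish(x: np.ndarray) -> np.ndarray:
    return x * sigmoid(x)


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Layer:
    """Base class: parameters, gradients, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trained state (BN stats)
        self.built = False

    def build(self, input_shape: tuple[int, ...], rng: np.random.Generator) -> None:
        self.built = True

    def output_shape(self, input_shape: tuple[int, ...]) -> tuple[int, ...]:
        return input_shape

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_loss(self) -> float:
        return 0.0


def conv_output_length(input_len: int, kernel: int, stride: int, padding: str) -> int:
    """Sequence-axis output length of a strided 1-D convolution or pooling.

    ``'same'`` padding gives ``ceil(input_len / stride)``; ``'valid'`` gives
    ``floor((input_len - kernel) / stride) + 1``.
    """
    if input_len < 1 or kernel < 1 or stride < 1:
        raise ValueError("input_len, kernel and stride must all be >= 1")
    if padding == "same":
        return -(-input_len // stride)
    if padding == "valid":
        if kernel > input_len:
            raise ValueError(
                f"kernel {kernel} exceeds input length {input_len} under 'valid' padding"
            )
        return (input_len - kernel) // stride + 1
    raise ValueError(f"unknown padding mode {padding!r}")


class Conv1D(Layer):
    """1-D convolution, 'same' or 'valid' padding, linear output."""

    def __init__(self, filters: int, kernel: int, stride: int = 1,
                 padding: str = "same") -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding mode {padding!r}")
        self.filters, self.kernel, self.stride, self.padding = filters, kernel, stride, padding

    def build(self, input_shape, rng):
        c_in = input_shape[-1]
        fan_in, fan_out = self.kernel * c_in, self.kernel * self.filters
        self.params["W"] = _glorot_uniform(
            rng, (self.kernel, c_in, self.filters), fan_in, fan_out)
        self.params["b"] = np.zeros(self.filters)
        self.built = True

    def output_shape(self, input_shape):
        t_out = conv_output_length(input_shape[0], self.kernel, self.stride, self.padding)
        return (t_out, self.filters)

    def _pad(self, t_in: int) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        t_out = conv_output_length(t_in, self.kernel, self.stride, "same")
        total = max((t_out - 1) * self.stride + self.kernel - t_in, 0)
        return total // 2, total - total // 2

    def forward(self, x, training=False):
        b, t_in, _ = x.shape
        pl, pr = self._pad(t_in)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        t_out = conv_output_length(t_in, self.kernel, self.stride, self.padding)
        w = self.params["W"]
        y = np.broadcast_to(self.params["b"], (b, t_out, self.filters)).copy()
        for j in range(self.kernel):
            y += xp[:, j : j + t_out * self.stride : self.stride, :] @ w[j]
        self._cache = (xp, t_in, t_out, pl)
        return y

    def backward(self, dy):
        xp, t_in, t_out, pl = self._cache
        w = self.params["W"]
        dW = np.zeros_like(w)
        dxp = np.zeros_like(xp)
        for j in range(self.kernel):
            sl = slice(j, j + t_out * self.stride, self.stride)
            dW[j] = np.einsum("btc,btf->cf", xp[:, sl, :], dy)
            dxp[:, sl, :] += dy @ w[j].T
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1))
        return dxp[:, pl : pl + t_in, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over the batch (and time) axes.

    The running-statistics momentum defaults to 0.9 so that inference
    statistics converge within a few hundred optimizer steps — the regime
    this pipeline trains in (tens of batches per epoch).
    """

    def __init__(self, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.buffers["running_mean"] = np.zeros(c)
        self.buffers["running_var"] = np.ones(c)
        self.built = True

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = m * self.buffers["running_mean"] + (1 - m) * mean
            self.buffers["running_var"] = m * self.buffers["running_var"] + (1 - m) * var
        else:
            mean, var = self.buffers["running_mean"], self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv, axes, training = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        if not training:
            return dxhat * inv
        m = np.prod([xhat.shape[a] for a in axes])
        return (inv / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Temporal max pooling with 'valid' padding."""

    def __init__(self, pool: int, stride: int) -> None:
        super().__init__()
        self.pool, self.stride = pool, stride

    def output_shape(self, input_shape):
        t_out = conv_output_length(input_shape[0], self.pool, self.stride, "valid")
        return (t_out, input_shape[1])

    def forward(self, x, training=False):
        t_out = conv_output_length(x.shape[1], self.pool, self.stride, "valid")
        windows = np.stack(
            [x[:, j : j + t_out * self.stride : self.stride, :] for j in range(self.pool)]
        )
        self._argmax = windows.argmax(axis=0)
        self._in_shape = x.shape
        self._t_out = t_out
        return windows.max(axis=0)

    def backward(self, dy):
        dx = np.zeros(self._in_shape)
        for j in range(self.pool):
            sl = slice(j, j + self._t_out * self.stride, self.stride)
            dx[:, sl, :] += dy * (self._argmax == j)
        return dx


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average over time per channel. Excitation: dense
    bottleneck to ``channels // reduction`` with Swish, dense restore with
    sigmoid, yielding per-channel weights in (0, 1). Scale: channel-wise
    multiplication; output shape equals input shape.
    """

    def __init__(self, reduction: int = 8) -> None:
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        self.reduction = reduction

    def build(self, input_shape, rng):
        c = input_shape[-1]
        h = max(c // self.reduction, 1)
        self.params["W1"] = _glorot_uniform(rng, (c, h), c, h)
        self.params["b1"] = np.zeros(h)
        self.params["W2"] = _glorot_uniform(rng, (h, c), h, c)
        self.params["b2"] = np.zeros(c)
        self.built = True

    def forward(self, x, training=False):
        t = x.shape[1]
        z = x.mean(axis=1)                                  # squeeze: (B, C)
        a1 = z @ self.params["W1"] + self.params["b1"]
        s1 = swish(a1)
        a2 = s1 @ self.params["W2"] + self.params["b2"]
        w = sigmoid(a2)                                     # (B, C) in (0, 1)
        self._cache = (x, z, a1, s1, w, t)
        return x * w[:, None, :]

    def backward(self, dy):
        x, z, a1, s1, w, t = self._cache
        dw = (dy * x).sum(axis=1)
        da2 = dw * w * (1.0 - w)
        self.grads["W2"] = s1.T @ da2
        self.grads["b2"] = da2.sum(axis=0)
        ds1 = da2 @ self.params["W2"].T
        sig1 = sigmoid(a1)
        da1 = ds1 * (sig1 + a1 * sig1 * (1.0 - sig1))
        self.grads["W1"] = z.T @ da1
        self.grads["b1"] = da1.sum(axis=0)
        dz = da1 @ self.params["W1"].T
        return dy * w[:, None, :] + dz[:, None, :] / t


class LSTM(Layer):
    """LSTM layer returning the final hidden state.

    Gates follow the standard cell: input, forget and output gates through
    the logistic function, candidate memory through tanh, elementwise
    memory update and gated tanh output. Fused weights are stored with
    gate order (i, f, c, o); the forget-gate bias is initialized to one.
    """

    def __init__(self, units: int) -> None:
        super().__init__()
        self.units = units

    def build(self, input_shape, rng):
        c, h = input_shape[-1], self.units
        self.params["W"] = _glorot_uniform(rng, (c, 4 * h), c, 4 * h)
        self.params["U"] = np.concatenate([_orthogonal(rng, h) for _ in range(4)], axis=1)
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.params["b"] = b
        self.built = True

    def output_shape(self, input_shape):
        return (self.units,)

    def forward(self, x, training=False):
        b, t, _ = x.shape
        hdim = self.units
        w, u, bias = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((b, hdim))
        c = np.zeros((b, hdim))
        steps = []
        for k in range(t):
            gates = x[:, k, :] @ w + h @ u + bias
            i = sigmoid(gates[:, :hdim])
            f = sigmoid(gates[:, hdim : 2 * hdim])
            g = np.tanh(gates[:, 2 * hdim : 3 * hdim])
            o = sigmoid(gates[:, 3 * hdim :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            steps.append((x[:, k, :], h, c, i, f, g, o, tanh_c))
            h, c = o * tanh_c, c_new
        self._steps = steps
        return h

    def backward(self, dy):
        w, u = self.params["W"], self.params["U"]
        dW = np.zeros_like(w)
        dU = np.zeros_like(u)
        db = np.zeros_like(self.params["b"])
        dh = dy
        dc = np.zeros_like(dy)
        t = len(self._steps)
        dx = np.zeros((dy.shape[0], t, w.shape[0]))
        for k in reversed(range(t)):
            xk, h_prev, c_prev, i, f, g, o, tanh_c = self._steps[k]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dW += xk.T @ dgates
            dU += h_prev.T @ dgates
            db += dgates.sum(axis=0)
            dx[:, k, :] = dgates @ w.T
            dh = dgates @ u.T
            dc = dc * f
        self.grads["W"], self.grads["U"], self.grads["b"] = dW, dU, db
        return dx


class Flatten(Layer):
    def output_shape(self, input_shape):
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def build(self, input_shape, rng):
        self._rng = np.random.default_rng(rng.integers(2**31))
        self.built = True

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    """Fully connected layer with optional ReLU and L2 weight penalty."""

    def __init__(self, units: int, activation: str | None = None, l2: float = 0.0) -> None:
        super().__init__()
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported dense activation {activation!r}")
        self.units, self.activation, self.l2 = units, activation, l2

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.params["W"] = _glorot_uniform(rng, (c, self.units), c, self.units)
        self.params["b"] = np.zeros(self.units)
        self.built = True

    def output_shape(self, input_shape):
        return (self.units,)

    def forward(self, x, training=False):
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._cache = (x, z > 0)
            return z * (z > 0)
        self._cache = (x, None)
        return z

    def backward(self, dy):
        x, mask = self._cache
        if mask is not None:
            dy = dy * mask
        self.grads["W"] = x.T @ dy + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T

    def l2_loss(self) -> float:
        return self.l2 * float(np.sum(self.params["W"] ** 2))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.sum(onehot * np.log(np.clip(p, 1e-300, None)))) / n
    return loss, (p - onehot) / n


class Sequential:
    """An ordered layer stack with seeded building and a predict API."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        self.input_shape: tuple[int, ...] | None = None

    def build(self, input_shape: tuple[int, ...], seed: int = 0) -> "Sequential":
        rng = np.random.default_rng(seed)
        shape = tuple(input_shape)
        for layer in self.layers:
            layer.build(shape, rng)
            shape = layer.output_shape(shape)
        self.input_shape = tuple(input_shape)
        return self

    def output_shapes(self, input_shape: tuple[int, ...] | None = None) -> list[tuple[int, ...]]:
        shape = tuple(input_shape or self.input_shape)
        shapes = []
        for layer in self.layers:
            shape = layer.output_shape(shape)
            shapes.append(shape)
        return shapes

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        outs = [
            softmax(self.forward(x[i : i + batch_size], training=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def l2_loss(self) -> float:
        return sum(layer.l2_loss() for layer in self.layers)

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def _slots(self):
        """Trainable parameters followed by persistent buffers (BN stats)."""
        for layer in self.layers:
            for name in layer.params:
                yield layer.params, name
            for name in layer.buffers:
                yield layer.buffers, name

    def get_weights(self) -> list[np.ndarray]:
        return [store[n].copy() for store, n in self._slots()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (store, name), w in zip(self._slots(), weights, strict=True):
            store[name] = w.copy()


class Adam:
    """Adaptive moment estimation optimizer."""

    def __init__(self, model: Sequential, learning_rate: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.model = model
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in model.parameters()]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, (layer, name) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            layer.params[name] -= (
                self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            )
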