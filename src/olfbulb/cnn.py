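"""A small convolutional classifier for PD-vs-NPOD scan discrimination.

Architecture (7 layers, counting conv/pool/flatten/dense):

    input H x W x C
    -> conv 32 @ 3x3, stride 1, valid padding, ReLU
    -> 2x2 max pool, stride 2                       (+ dropout 0.5)
    -> conv 32 @ 3x3, stride 1, valid padding, ReLU
    -> 2x2 max pool, stride 2                       (+ dropout 0.5)
    -> flatten
    -> dense 128, ReLU                              (+ dropout 0.5)
    -> dense 2, softmax

On the reference 150 x 150 x 3 input this network has exactly 5,318,946
trainable parameters.  Training is plain mini-batch SGD (default learning
rate 3e-4, momentum 0, batch 32) minimising categorical cross-entropy.

Everything -- forward pass, exact max-pool gradient routing, backward
pass, the optimiser -- is implemented in numpy; convolutions go through
``sliding_window_view`` (im2col) so small inputs train quickly on one CPU.
The explicit backward machinery is also what powers Grad-CAM, which needs
the gradient of a class logit with respect to the last convolution layer's
activations (see :mod:`olfbulb.saliency`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class ArchitectureSpec:
    input_size: tuple[int, int] = (150, 150)
    channels: int = 3
    conv_filters: int = 32
    kernel: int = 3
    dense_units: int = 128
    n_classes: int = 2
    dropout: float = 0.5

    def validate(self) -> None:
        if self.dense_units < 1 or self.n_classes < 2 or self.conv_filters < 1:
            raise ValueError("degenerate architecture (zero-width layer)")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        feature_map_shape(self.input_size)  # raises if input too small


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 100
    learning_rate: float = 3e-4
    momentum: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.learning_rate < 0 or self.momentum < 0:
            raise ValueError("learning_rate and momentum must be >= 0")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def feature_map_shape(input_size: tuple[int, int],
                      layers: tuple[str, ...] = ("conv", "pool", "conv", "pool")
                      ) -> list[tuple[int, int]]:
    """Spatial shape after each conv/pool layer (valid 3x3 convs lose 2
    per side-length; 2x2 stride-2 pools floor-halve).  Raises if any
    intermediate dimension collapses."""
    h, w = input_size
    shapes = []
    for layer in layers:
        if layer == "conv":
            h, w = h - 2, w - 2
        elif layer == "pool":
            h, w = h // 2, w // 2
        else:
            raise ValueError(f"unknown layer {layer!r}")
        if h < 1 or w < 1:
            raise ValueError(f"feature map exhausted at layer {layer!r}: {h}x{w}")
        shapes.append((h, w))
    return shapes


def count_trainable_params(spec: ArchitectureSpec) -> int:
    """Closed-form trainable parameter count.

    conv1: (k*k*C + 1) * F;  conv2: (k*k*F + 1) * F;
    dense: (flat + 1) * units;  output: (units + 1) * classes,
    with flat = F * (final feature-map area).
    """
    spec.validate()
    k, c, f = spec.kernel, spec.channels, spec.conv_filters
    shapes = feature_map_shape(spec.input_size)
    fh, fw = shapes[-1]
    flat = f * fh * fw
    return ((k * k * c + 1) * f
            + (k * k * f + 1) * f
            + (flat + 1) * spec.dense_units
            + (spec.dense_units + 1) * spec.n_classes)


# ---------------------------------------------------------------------------
# layers (NHWC tensors throughout)

class _Conv2D:
    def __init__(self, c_in, c_out, k, rng):
        fan_in = k * k * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out))
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x):
        self._cols = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        # cols: (n, Ho, Wo, C, k, k); kernel (k, k, C, out)
        out = np.einsum("nhwcij,ijco->nhwo", self._cols, self.w, optimize=True)
        return out + self.b

    def backward(self, dout):
        self.dw = np.einsum("nhwcij,nhwo->ijco", self._cols, dout, optimize=True)
        self.db = dout.sum(axis=(0, 1, 2))
        n, ho, wo, _ = dout.shape
        c_in = self.w.shape[2]
        dx = np.zeros((n, ho + self.k - 1, wo + self.k - 1, c_in))
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + ho, j:j + wo, :] += np.tensordot(
                    dout, self.w[i, j], axes=([3], [1]))
        return dx

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    """2x2 stride-2 max pooling with exact argmax gradient routing."""

    def forward(self, x):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xt = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        xt = xt.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._arg = xt.argmax(axis=-1)
        return np.take_along_axis(xt, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h2, w2, c = dout.shape
        flat = np.zeros((n, h2, w2, c, 4))
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        dx_t = flat.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape)
        dx[:, :h2 * 2, :w2 * 2, :] = dx_t.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class _Dropout:
    def __init__(self, p):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """The 7-layer scan classifier, with explicit forward/backward."""

    def __init__(self, spec: ArchitectureSpec | None = None, seed: int = 0):
        self.spec = spec or ArchitectureSpec()
        self.spec.validate()
        rng = np.random.default_rng(seed)
        s = self.spec
        fh, fw = feature_map_shape(s.input_size)[-1]
        flat = s.conv_filters * fh * fw
        self.conv1 = _Conv2D(s.channels, s.conv_filters, s.kernel, rng)
        self.relu1 = _ReLU()
        self.pool1 = _MaxPool2()
        self.drop1 = _Dropout(s.dropout)
        self.conv2 = _Conv2D(s.conv_filters, s.conv_filters, s.kernel, rng)
        self.relu2 = _ReLU()
        self.pool2 = _MaxPool2()
        self.drop2 = _Dropout(s.dropout)
        self.flatten = _Flatten()
        self.dense1 = _Dense(flat, s.dense_units, rng)
        self.relu3 = _ReLU()
        self.drop3 = _Dropout(s.dropout)
        self.dense2 = _Dense(s.dense_units, s.n_classes, rng)
        self._param_layers = [self.conv1, self.conv2, self.dense1, self.dense2]
        self._velocity = None

    # -- forward -----------------------------------------------------------
    def _check_input(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        expect = (*self.spec.input_size, self.spec.channels)
        if x.shape[1:] != expect:
            raise ValueError(f"input shape {x.shape[1:]} != expected {expect}")
        return x

    def forward(self, x, train=False, rng=None):
        x = self._check_input(x)
        a = self.relu1.forward(self.conv1.forward(x))
        a = self.drop1.forward(self.pool1.forward(a), train, rng)
        a = self.relu2.forward(self.conv2.forward(a))
        self._last_conv_act = a  # post-ReLU conv2 activations
        a = self.drop2.forward(self.pool2.forward(a), train, rng)
        a = self.flatten.forward(a)
        a = self.drop3.forward(self.relu3.forward(self.dense1.forward(a)), train, rng)
        return self.dense2.forward(a)

    def head_forward(self, last_conv_act):
        """Logits from given post-ReLU last-conv activations (inference
        path); used by the Grad-CAM finite-difference oracle."""
        a = self.pool2.forward(np.asarray(last_conv_act, dtype=float))
        a = self.flatten.forward(a)
        a = self.relu3.forward(self.dense1.forward(a))
        return self.dense2.forward(a)

    # -- backward ----------------------------------------------------------
    def backward(self, dlogits, to_last_conv=False):
        d = self.dense2.backward(dlogits)
        d = self.dense1.backward(self.relu3.backward(self.drop3.backward(d)))
        d = self.pool2.backward(self.drop2.backward(self.flatten.backward(d)))
        if to_last_conv:
            return d
        d = self.conv2.backward(self.relu2.backward(d))
        d = self.pool1.backward(self.drop1.backward(d))
        self.conv1.backward(self.relu1.backward(d))
        return None

    def grad_wrt_last_conv(self, x, class_idx):
        """d(logit of class)/d(last-conv post-ReLU activations), and those
        activations, for a single scan (inference mode)."""
        logits = self.forward(x, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_idx] = 1.0
        grad = self.backward(dlogits, to_last_conv=True)
        return grad, self._last_conv_act, logits

    # -- parameters --------------------------------------------------------
    def parameter_arrays(self):
        out = []
        for layer in self._param_layers:
            for _, arr, _ in layer.params():
                out.append(arr)
        return out

    def n_params(self) -> int:
        """Layer-by-layer enumeration of trainable parameters."""
        return int(sum(a.size for a in self.parameter_arrays()))

    def sgd_step(self, lr, momentum=0.0):
        grads = []
        for layer in self._param_layers:
            for _, arr, gname in layer.params():
                grads.append((arr, getattr(layer, gname)))
        if momentum > 0.0:
            if self._velocity is None:
                self._velocity = [np.zeros_like(a) for a, _ in grads]
            for v, (a, g) in zip(self._velocity, grads):
                v *= momentum
                v -= lr * g
                a += v
        else:
            for a, g in grads:
                a -= lr * g

    # -- inference ---------------------------------------------------------
    def predict_proba(self, x):
        x = self._check_input(x)
        out = []
        for i in range(0, len(x), 64):
            out.append(_softmax(self.forward(x[i:i + 64], train=False)))
        return np.concatenate(out, axis=0)

    def predict(self, x):
        p = self.predict_proba(x)
        return p, p.argmax(axis=1)


def _evaluate(model, x, y, batch=64):
    loss, correct = 0.0, 0
    for i in range(0, len(x), batch):
        p = _softmax(model.forward(x[i:i + batch], train=False))
        yi = y[i:i + batch]
        loss += -np.sum(np.log(np.clip(p[np.arange(len(yi)), yi], 1e-12, None)))
        correct += int((p.argmax(axis=1) == yi).sum())
    return loss / len(x), correct / len(x)


def train(
    model: SmallCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainHistory:
    """Mini-batch SGD on categorical cross-entropy.

    The seed fixes batch order and dropout masks; per-epoch training
    metrics are accumulated over the training batches as seen (dropout
    active), validation metrics are inference-mode.
    """
    config.validate()
    x_train = model._check_input(x_train)
    y_train = np.asarray(y_train, dtype=int)
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    n = len(x_train)

    for _ in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True, rng=rng)
            probs = _softmax(logits)
            ep_loss += -np.sum(np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)))
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            model.backward(dlogits / len(yb))
            model.sgd_step(config.learning_rate, config.momentum)
        history.loss.append(ep_loss / n)
        history.accuracy.append(ep_correct / n)
        if x_val is not None and len(x_val):
            vl, va = _evaluate(model, x_val, np.asarray(y_val, dtype=int))
            history.val_loss.append(vl)
            history.val_accuracy.append(va)
    return history
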