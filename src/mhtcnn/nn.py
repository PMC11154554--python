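"""Minimal 1D convolutional network in numpy.

This is the numerical engine behind :mod:`mhtcnn.classifier`: dilated 1D
convolutions with zero ("same") padding, ReLU activations, a per-position
sigmoid head trained with binary cross-entropy, and Adam updates.  Everything
is dense numpy, deterministic given the seed, and fast enough for the
sequence lengths this package works with (10^3 - 10^5 positions).

Shapes follow the (batch, channels, length) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LayerSpec", "ConvNet", "AdamState", "bce_with_logits", "sigmoid"]


@dataclass(frozen=True)
class LayerSpec:
    """One convolutional layer: ``filters`` output channels, kernel
    ``kernel_size`` spread by ``dilation``, followed by ``activation``
    ("relu" or "linear")."""

    filters: int
    kernel_size: int
    dilation: int = 1
    activation: str = "relu"
    trainable: bool = True
    init: str = "he"

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if self.activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.init not in ("he", "uniform"):
            raise ValueError(f"unknown init {self.init!r}")


def _im2col_indices(length: int, k: int, dilation: int):
    """Gather indices and validity mask for a same-padded dilated window."""
    span = (k - 1) * dilation
    pad_left = span // 2
    pos = np.arange(length)[None, :] + (np.arange(k) * dilation)[:, None] - pad_left
    valid = (pos >= 0) & (pos < length)
    return np.clip(pos, 0, length - 1), valid


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and its gradient w.r.t. the logits ``z``."""
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad


class ConvNet:
    """A stack of same-padded dilated 1D convolutions.

    Parameters are He-initialised from ``seed``.  The final layer is expected
    to emit a single channel of logits; the sigmoid lives in the loss and in
    :meth:`predict_proba` so training stays numerically stable.
    """

    def __init__(self, layers: list[LayerSpec], in_channels: int = 1, seed: int = 0):
        self.specs = list(layers)
        self.in_channels = in_channels
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        cin = in_channels
        for sp in self.specs:
            if sp.init == "uniform":
                # fixed moving-average layer (e.g. the logit-smoothing head)
                w = np.full((sp.filters, cin * sp.kernel_size),
                            1.0 / (cin * sp.kernel_size))
            else:
                std = np.sqrt(2.0 / (cin * sp.kernel_size))
                w = rng.normal(0.0, std, (sp.filters, cin * sp.kernel_size))
            self.weights.append(w)
            self.biases.append(np.zeros(sp.filters))
            cin = sp.filters

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Run the stack on ``x`` of shape (B, C_in, L).

        Returns the final pre-activation output (logits for a linear head)
        and, when ``keep_cache``, the per-layer cache needed for backprop.
        """
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected input of shape (B, {self.in_channels}, L)")
        caches = []
        a = x
        for sp, w, b in zip(self.specs, self.weights, self.biases):
            B, cin, L = a.shape
            pos, valid = _im2col_indices(L, sp.kernel_size, sp.dilation)
            cols = (a[:, :, pos] * valid[None, None]).reshape(B, cin * sp.kernel_size, L)
            z = np.einsum("oc,bcl->bol", w, cols) + b[None, :, None]
            if sp.init == "uniform" and not sp.trainable:
                # moving average renormalised by the in-bounds tap count, so
                # edge positions are means of fewer values, not zero-diluted
                z = z * (sp.kernel_size / valid.sum(0))[None, None, :]
            if keep_cache:
                caches.append((a.shape, cols, pos, valid, z))
            a = np.maximum(z, 0.0) if sp.activation == "relu" else z
        return a, caches

    def backward(self, caches, d_out: np.ndarray):
        """Gradients of all weights/biases given d(loss)/d(final output)."""
        grads_w: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        da = d_out
        for sp, w, (a_shape, cols, pos, valid, z) in zip(
            reversed(self.specs), reversed(self.weights), reversed(caches)
        ):
            dz = da * (z > 0) if sp.activation == "relu" else da
            if sp.init == "uniform" and not sp.trainable:
                dz = dz * (sp.kernel_size / valid.sum(0))[None, None, :]
            if sp.trainable:
                grads_w.append(np.einsum("bol,bcl->oc", dz, cols))
                grads_b.append(dz.sum(axis=(0, 2)))
            else:
                grads_w.append(np.zeros_like(w))
                grads_b.append(np.zeros(sp.filters))
            B, cin, L = a_shape
            dcols = np.einsum("oc,bol->bcl", w, dz).reshape(B, cin, sp.kernel_size, L)
            dcols *= valid[None, None]
            da = np.zeros(a_shape)
            for j in range(sp.kernel_size):
                np.add.at(da, (slice(None), slice(None), pos[j]), dcols[:, :, j])
        return list(reversed(grads_w)), list(reversed(grads_b))

    # -- inference ----------------------------------------------------------
    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.forward(x)
        return out

    def predict_proba(self, seq: np.ndarray) -> np.ndarray:
        """Per-position probabilities for a single 1D sequence."""
        seq = np.asarray(seq, float)
        logits = self.predict_logits(seq[None, None, :])[0, 0]
        return sigmoid(logits)

    # -- parameter plumbing -------------------------------------------------
    def zero_weights(self) -> None:
        """Test hook: all-zero parameters make every prediction sigmoid(0)=0.5."""
        for w, b in zip(self.weights, self.biases):
            w[...] = 0.0
            b[...] = 0.0

    def get_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w
            out[f"b{i}"] = b
        return out

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for i in range(len(self.weights)):
            self.weights[i] = np.asarray(params[f"w{i}"], float).reshape(self.weights[i].shape)
            self.biases[i] = np.asarray(params[f"b{i}"], float).reshape(self.biases[i].shape)


class AdamState:
    """Adaptive-moment optimiser state for a :class:`ConvNet`."""

    def __init__(self, net: ConvNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(w) for w in net.weights] + [np.zeros_like(b) for b in net.biases]
        self.v = [np.zeros_like(w) for w in net.weights] + [np.zeros_like(b) for b in net.biases]

    def step(self, net: ConvNet, grads_w, grads_b) -> None:
        self.t += 1
        params = net.weights + net.biases
        grads = grads_w + grads_b
        c1 = 1.0 - self.beta1 ** self.t
        c2 = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
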