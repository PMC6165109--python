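"""Minimal feed-forward neural-network core.

Fully-connected multilayer perceptrons with leaky-rectifier hidden
units, Xavier (Glorot-uniform) weight initialization, zero biases,
inverted dropout, manual backpropagation and an Adam optimizer with
optional decoupled-into-gradient L2 weight decay on the weight matrices
only.  All losses are computed from pre-activation logits for numerical
stability.
"""

from __future__ import annotations

import hashlib

import numpy as np

EPS = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _activate(s: np.ndarray, kind: str, slope: float) -> np.ndarray:
    if kind == "lrelu":
        return np.where(s > 0, s, slope * s)
    if kind == "relu":
        return np.maximum(s, 0.0)
    if kind == "linear":
        return s
    if kind == "sigmoid":
        return sigmoid(s)
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(s: np.ndarray, kind: str, slope: float) -> np.ndarray:
    if kind == "lrelu":
        return np.where(s > 0, 1.0, slope)
    if kind == "relu":
        return (s > 0).astype(np.float64)
    if kind == "linear":
        return np.ones_like(s)
    raise ValueError(f"no gradient for activation {kind!r}")


class MLP:
    """A stack of dense layers.

    ``forward`` returns the *pre-activation* of the final layer together
    with a cache for ``backward``; ``output`` applies the output
    activation.  Dropout (inverted) can be applied to the input and/or
    after every hidden activation when ``train=True``.
    """

    def __init__(
        self,
        widths,
        rng: np.random.Generator,
        hidden_activation: str = "lrelu",
        out_activation: str = "linear",
        negative_slope: float = 0.2,
    ):
        if any(w <= 0 for w in widths):
            raise ValueError("layer widths must be positive")
        self.widths = list(widths)
        self.hidden_activation = hidden_activation
        self.out_activation = out_activation
        self.negative_slope = negative_slope
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for n_in, n_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (n_in + n_out))
            self.W.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    @property
    def in_width(self) -> int:
        return self.widths[0]

    @property
    def out_width(self) -> int:
        return self.widths[-1]

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        input_dropout: float = 0.0,
        hidden_dropout: float = 0.0,
    ):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.in_width:
            raise ValueError(
                f"expected input width {self.in_width}, got shape {X.shape}"
            )
        use_drop = train and (input_dropout > 0 or hidden_dropout > 0)
        if use_drop and rng is None:
            raise ValueError("dropout requires an rng in training mode")
        cache = {"inputs": [], "pre": [], "masks": []}
        a = X
        if train and input_dropout > 0:
            keep = 1.0 - input_dropout
            mask = (rng.random(a.shape) < keep) / keep
            a = a * mask
            cache["input_mask"] = mask
        else:
            cache["input_mask"] = None
        for i in range(self.n_layers):
            cache["inputs"].append(a)
            s = a @ self.W[i] + self.b[i]
            cache["pre"].append(s)
            if i < self.n_layers - 1:
                a = _activate(s, self.hidden_activation, self.negative_slope)
                if train and hidden_dropout > 0:
                    keep = 1.0 - hidden_dropout
                    mask = (rng.random(a.shape) < keep) / keep
                    a = a * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
        return cache["pre"][-1], cache

    def output(self, s_last: np.ndarray) -> np.ndarray:
        return _activate(s_last, self.out_activation, self.negative_slope)

    def predict(self, X: np.ndarray) -> np.ndarray:
        s, _ = self.forward(X, train=False)
        return self.output(s)

    def backward(self, d_s_last: np.ndarray, cache):
        """Backpropagate a gradient w.r.t. the final pre-activation.

        Returns ``(grads, d_input)`` where grads is a list of (dW, db).
        """
        grads = [None] * self.n_layers
        delta = np.asarray(d_s_last, dtype=np.float64)
        for i in range(self.n_layers - 1, -1, -1):
            a_in = cache["inputs"][i]
            grads[i] = (a_in.T @ delta, delta.sum(axis=0))
            d_a = delta @ self.W[i].T
            if i > 0:
                mask = cache["masks"][i - 1]
                if mask is not None:
                    d_a = d_a * mask
                d_a = d_a * _activate_grad(
                    cache["pre"][i - 1], self.hidden_activation, self.negative_slope
                )
            delta = d_a
        if cache["input_mask"] is not None:
            delta = delta * cache["input_mask"]
        return grads, delta

    # -- parameter plumbing -------------------------------------------------

    def get_params(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_params(self, params):
        Ws, bs = params
        self.W = [w.copy() for w in Ws]
        self.b = [b.copy() for b in bs]

    def params_hash(self) -> str:
        h = hashlib.sha256()
        for w, b in zip(self.W, self.b):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()

    def to_arrays(self, prefix: str) -> dict:
        out = {f"{prefix}_meta": np.array(
            [self.hidden_activation, self.out_activation, str(self.negative_slope)]
        )}
        out[f"{prefix}_widths"] = np.array(self.widths)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            out[f"{prefix}_W{i}"] = w
            out[f"{prefix}_b{i}"] = b
        return out

    @classmethod
    def from_arrays(cls, arrays: dict, prefix: str) -> "MLP":
        widths = arrays[f"{prefix}_widths"].tolist()
        meta = arrays[f"{prefix}_meta"]
        obj = cls.__new__(cls)
        obj.widths = [int(w) for w in widths]
        obj.hidden_activation = str(meta[0])
        obj.out_activation = str(meta[1])
        obj.negative_slope = float(meta[2])
        obj.W = [np.asarray(arrays[f"{prefix}_W{i}"]) for i in range(len(widths) - 1)]
        obj.b = [np.asarray(arrays[f"{prefix}_b{i}"]) for i in range(len(widths) - 1)]
        return obj


class Adam:
    """Adam with conventional moments (0.9, 0.999) and optional L2 decay
    added to the weight gradients (never to biases)."""

    def __init__(
        self,
        mlp: MLP,
        lr: float,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.mlp = mlp
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(w) for w in mlp.W]
        self.vW = [np.zeros_like(w) for w in mlp.W]
        self.mb = [np.zeros_like(b) for b in mlp.b]
        self.vb = [np.zeros_like(b) for b in mlp.b]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for i, (dW, db) in enumerate(grads):
            if self.weight_decay > 0:
                dW = dW + self.weight_decay * self.mlp.W[i]
            self.mW[i] = b1 * self.mW[i] + (1 - b1) * dW
            self.vW[i] = b2 * self.vW[i] + (1 - b2) * dW * dW
            self.mb[i] = b1 * self.mb[i] + (1 - b1) * db
            self.vb[i] = b2 * self.vb[i] + (1 - b2) * db * db
            self.mlp.W[i] -= self.lr * (self.mW[i] / c1) / (
                np.sqrt(self.vW[i] / c2) + self.eps
            )
            self.mlp.b[i] -= self.lr * (self.mb[i] / c1) / (
                np.sqrt(self.vb[i] / c2) + self.eps
            )


# ---------------------------------------------------------------------------
# Losses (logit-space, with mean-gradient helpers)


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray | None = None
):
    """Element-wise binary cross-entropy from logits.

    Returns ``(loss, d_logits)`` where loss is the (weighted) mean over
    all elements and d_logits its gradient.  With weights, the loss is
    sum(w * bce) / size — zero-weight entries contribute exactly zero.
    """
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    per = softplus(logits) - targets * logits
    grad = sigmoid(logits) - targets
    if weights is not None:
        per = per * weights
        grad = grad * weights
    denom = per.size
    return float(per.sum() / denom), grad / denom
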