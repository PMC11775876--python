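"""Small 1-D convolutional classifier for raw accelerometer epochs.

Architecture: two blocks of [1-D convolution (16 then 32 filters, kernel 9,
stride 1, ReLU) + max-pool 4], global average pooling, dense softmax.
Trained with stochastic gradient descent (learning rate 0.01, per-update
decay 1e-4, Nesterov momentum 0.9) for at most 100 epochs, batch size 32.
Pure NumPy (float32), deterministic given the seed: two runs with the same
seed produce identical predictions.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_DT = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, L, C) -> (n, L-k+1, C*k) patches for a stride-1 valid convolution."""
    win = sliding_window_view(x, k, axis=1)  # (n, L-k+1, C, k)
    n, lo, c, _ = win.shape
    return np.ascontiguousarray(win).reshape(n, lo, c * k)


def _col2im(dcols: np.ndarray, k: int, length: int, channels: int) -> np.ndarray:
    n, lo, _ = dcols.shape
    d = dcols.reshape(n, lo, channels, k)
    dx = np.zeros((n, length, channels), dtype=_DT)
    for off in range(k):
        dx[:, off:off + lo, :] += d[:, :, :, off]
    return dx


class ConvNetClassifier:
    """Dynamic-activity classifier over (n, samples, 3) epoch arrays."""

    def __init__(
        self,
        classes: list[str],
        lr: float = 0.01,
        decay: float = 1e-4,
        momentum: float = 0.9,
        max_epochs: int = 100,
        batch_size: int = 32,
        kernel: int = 9,
        filters: tuple[int, int] = (16, 32),
        pool: int = 4,
        seed: int = 0,
    ):
        self.classes = list(classes)
        self.lr0 = lr
        self.decay = decay
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.kernel = kernel
        self.filters = filters
        self.pool = pool
        self.seed = seed
        self.loss_history: list[float] = []
        self.params: dict[str, np.ndarray] = {}
        self.missing_classes: list[str] = []

    def _init_params(self, in_channels: int, rng: np.random.Generator) -> None:
        k, (f1, f2) = self.kernel, self.filters
        n_out = len(self.classes)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DT)

        self.params = {
            "W1": he((in_channels * k, f1), in_channels * k),
            "b1": np.zeros(f1, dtype=_DT),
            "W2": he((f1 * k, f2), f1 * k),
            "b2": np.zeros(f2, dtype=_DT),
            "Wd": he((f2, n_out), f2),
            "bd": np.zeros(n_out, dtype=_DT),
        }
        self._vel = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def _forward(self, x: np.ndarray, cache: bool = False):
        p = self.params
        k, pool = self.kernel, self.pool
        cols1 = _im2col(x, k)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0)
        l1 = (a1.shape[1] // pool) * pool
        r1 = a1[:, :l1].reshape(a1.shape[0], l1 // pool, pool, -1)
        am1 = r1.argmax(axis=2)
        p1 = r1.max(axis=2)

        cols2 = _im2col(p1, k)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0)
        l2 = (a2.shape[1] // pool) * pool
        r2 = a2[:, :l2].reshape(a2.shape[0], l2 // pool, pool, -1)
        am2 = r2.argmax(axis=2)
        p2 = r2.max(axis=2)

        gap = p2.mean(axis=1)
        logits = gap @ p["Wd"] + p["bd"]
        if not cache:
            return logits
        return logits, (x, cols1, z1, a1, am1, p1, cols2, z2, a2, am2, p2, gap)

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        k, pool = self.kernel, self.pool
        x, cols1, z1, a1, am1, p1, cols2, z2, a2, am2, p2, gap = cache
        n = x.shape[0]

        grads = {"Wd": gap.T @ dlogits, "bd": dlogits.sum(axis=0)}
        dgap = dlogits @ p["Wd"].T
        dp2 = np.repeat(dgap[:, None, :], p2.shape[1], axis=1) / p2.shape[1]

        # unpool 2
        da2 = np.zeros_like(a2)
        l2 = p2.shape[1] * pool
        dr2 = np.zeros((n, p2.shape[1], pool, a2.shape[2]), dtype=_DT)
        np.put_along_axis(dr2, am2[:, :, None, :], dp2[:, :, None, :], axis=2)
        da2[:, :l2] = dr2.reshape(n, l2, -1)
        dz2 = da2 * (z2 > 0)
        grads["W2"] = cols2.reshape(-1, cols2.shape[2]).T @ dz2.reshape(-1, dz2.shape[2])
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ p["W2"].T
        dp1 = _col2im(dcols2, k, p1.shape[1], p1.shape[2])

        # unpool 1
        da1 = np.zeros_like(a1)
        l1 = p1.shape[1] * pool
        dr1 = np.zeros((n, p1.shape[1], pool, a1.shape[2]), dtype=_DT)
        np.put_along_axis(dr1, am1[:, :, None, :], dp1[:, :, None, :], axis=2)
        da1[:, :l1] = dr1.reshape(n, l1, -1)
        dz1 = da1 * (z1 > 0)
        grads["W1"] = cols1.reshape(-1, cols1.shape[2]).T @ dz1.reshape(-1, dz1.shape[2])
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ConvNetClassifier":
        X = np.asarray(X, dtype=_DT)
        y = np.asarray(y)
        present = set(y.tolist())
        self.missing_classes = [c for c in self.classes if c not in present]
        if self.missing_classes:
            import warnings

            warnings.warn(
                f"classes absent from training data and unlearnable: "
                f"{self.missing_classes}",
                stacklevel=2,
            )
        idx = {c: i for i, c in enumerate(self.classes)}
        t = np.array([idx[c] for c in y])
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[2], rng)

        n = len(X)
        step = 0
        self.loss_history = []
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                xb, tb = X[sel], t[sel]
                logits, cache = self._forward(xb, cache=True)
                logits = logits - logits.max(axis=1, keepdims=True)
                expz = np.exp(logits)
                prob = expz / expz.sum(axis=1, keepdims=True)
                loss = -np.mean(np.log(prob[np.arange(len(tb)), tb] + 1e-12))
                epoch_loss += loss * len(tb)
                dlogits = prob.copy()
                dlogits[np.arange(len(tb)), tb] -= 1.0
                dlogits = (dlogits / len(tb)).astype(_DT)
                grads = self._backward(dlogits, cache)
                lr = _DT(self.lr0 / (1.0 + self.decay * step))
                for name, g in grads.items():
                    v = self._vel[name]
                    v_new = self.momentum * v - lr * g
                    # Nesterov lookahead update
                    self.params[name] += self.momentum * v_new - lr * g
                    self._vel[name] = v_new
                step += 1
            self.loss_history.append(epoch_loss / n)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=_DT)
        out = []
        for start in range(0, len(X), 256):
            logits = self._forward(X[start:start + 256])
            out.append(np.argmax(logits, axis=1))
        labels = np.concatenate(out) if out else np.array([], dtype=int)
        return np.array([self.classes[i] for i in labels], dtype=object)
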