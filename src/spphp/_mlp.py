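"""Minimal fully connected regressor trained with Adam.

Single-precision NumPy implementation of the de-overlapping network:
dense layers with rectified-linear hidden activations, mean-squared-
error loss, Adam updates on shuffled mini-batches, optional L2 weight
penalty. Written for speed and bit-reproducibility at this very small
architecture; behaviour is cross-checked against scikit-learn's
``MLPRegressor`` in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AdamMLP"]


class AdamMLP:
    """Fully connected ReLU network trained by mini-batch Adam on MSE.

    Parameters mirror the de-overlapper's configuration: layer sizes,
    learning rate, epoch count, batch size, L2 penalty ``alpha``
    (scaled by batch size, as in scikit-learn), and a seed controlling
    initialization and batch order.
    """

    def __init__(
        self,
        layer_sizes: tuple[int, ...],
        learning_rate: float = 1e-3,
        epochs: int = 200,
        batch_size: int = 32,
        alpha: float = 1e-4,
        weight_decay: float = 0.0,
        lr_decay: str = "linear",
        seed: int = 0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.learning_rate = float(learning_rate)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.alpha = float(alpha)
        self.weight_decay = float(weight_decay)
        if lr_decay not in ("linear", "constant"):
            raise ValueError("lr_decay must be 'linear' or 'constant'")
        self.lr_decay = lr_decay
        self.seed = int(seed)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.loss_curve_: list[float] = []
        self._init_params()

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for n_in, n_out in zip(self.layer_sizes, self.layer_sizes[1:]):
            # Glorot-uniform, as is standard for small dense nets
            bound = np.sqrt(6.0 / (n_in + n_out))
            self.weights.append(
                rng.uniform(-bound, bound, (n_in, n_out)).astype(np.float32)
            )
            self.biases.append(np.zeros(n_out, dtype=np.float32))

    # ------------------------------------------------------------------

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ w + b
            if i < len(self.weights) - 1:
                z = np.maximum(z, 0.0)
            acts.append(z)
        return acts

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        return self._forward(x)[-1].astype(np.float64)

    def fit(self, x: np.ndarray, y: np.ndarray, augment=None) -> "AdamMLP":
        """Train on (x, y); ``augment(xb, rng)``, when given, perturbs
        each mini-batch freshly at every presentation (noise/drift
        augmentation), so no static noise pattern is ever repeated."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.ascontiguousarray(y, dtype=np.float32)
        n = x.shape[0]
        rng = np.random.default_rng(self.seed + 1)
        m = [np.zeros_like(w) for w in self.weights]
        v = [np.zeros_like(w) for w in self.weights]
        mb = [np.zeros_like(b) for b in self.biases]
        vb = [np.zeros_like(b) for b in self.biases]
        t = 0
        lr0, b1, b2, eps = self.learning_rate, self.beta1, self.beta2, self.eps
        n_batches = int(np.ceil(n / self.batch_size))
        total_updates = max(self.epochs * n_batches, 1)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x[idx], y[idx]
                if augment is not None:
                    xb = augment(xb, rng)
                acts = self._forward(xb)
                err = acts[-1] - yb
                epoch_loss += float(np.sum(err**2))
                # backprop: dL/dz for MSE = 2 err / (batch * n_outputs)
                delta = (2.0 / (err.shape[0] * err.shape[1])) * err
                t += 1
                # annealed step size freezes the end-of-training random
                # walk that constant-lr Adam keeps along flat directions
                if self.lr_decay == "linear":
                    lr = lr0 * max(1.0 - t / total_updates, 0.0)
                else:
                    lr = lr0
                for i in range(len(self.weights) - 1, -1, -1):
                    grad_w = acts[i].T @ delta + (
                        self.alpha / err.shape[0]
                    ) * self.weights[i]
                    grad_b = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ self.weights[i].T) * (acts[i] > 0)
                    m[i] = b1 * m[i] + (1 - b1) * grad_w
                    v[i] = b2 * v[i] + (1 - b2) * grad_w**2
                    mb[i] = b1 * mb[i] + (1 - b1) * grad_b
                    vb[i] = b2 * vb[i] + (1 - b2) * grad_b**2
                    bc1 = 1 - b1**t
                    bc2 = 1 - b2**t
                    step = lr * (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)
                    if self.weight_decay > 0.0:
                        # decoupled decay: pins weights along directions the
                        # data leaves unidentified, which plain L2 cannot do
                        # through Adam's gradient normalization
                        step = step + lr * self.weight_decay * self.weights[i]
                    self.weights[i] -= step.astype(np.float32)
                    self.biases[i] -= (
                        lr * (mb[i] / bc1) / (np.sqrt(vb[i] / bc2) + eps)
                    ).astype(np.float32)
            self.loss_curve_.append(epoch_loss / (n * y.shape[1]))
        return self
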