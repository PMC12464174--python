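"""Sequential network with Adam and class-weighted cross-entropy.

The network trains on mini-batches with the head activation (sigmoid or
softmax) fused into the loss gradient for numerical stability: the gradient
at the logits is ``(p - y) * w`` with per-sample weights ``w`` normalized to
mean one over the batch.  Binary heads use one sigmoid unit and binary
cross-entropy; multi-class heads use softmax and categorical cross-entropy.
"""

from __future__ import annotations

import numpy as np

from .layers import Activation, Layer

__all__ = ["Sequential", "Adam"]


class Adam:
    """Adam optimizer (beta1 0.9, beta2 0.999, eps 1e-7)."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for li, layer in enumerate(layers):
            if not layer.params:
                continue
            m = self._m.setdefault(li, {k: np.zeros_like(v) for k, v in layer.params.items()})
            v = self._v.setdefault(li, {k: np.zeros_like(p) for k, p in layer.params.items()})
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g**2
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


class Sequential:
    """Ordered layer stack over a fixed input shape.

    ``input_shape`` excludes the batch axis, e.g. ``(4100, 1)`` for the
    wavelet feature vector treated as a length-4100 single-channel sequence.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...], seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for idx, layer in enumerate(layers):
            try:
                shape = layer.build(shape, rng)
            except ValueError as exc:
                raise ValueError(f"layer {idx} ({type(layer).__name__}): {exc}") from exc
        self.output_shape = shape
        head = layers[-1]
        if not isinstance(head, Activation) or head.kind not in ("sigmoid", "softmax"):
            raise ValueError("final layer must be a sigmoid or softmax Activation")
        self.head_kind = head.kind

    # ------------------------------------------------------------- inference

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if tuple(x.shape[1:]) != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input "
                f"{self.input_shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    predict_proba = forward

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        p = self.forward(x, training=False)
        if self.head_kind == "sigmoid":
            return (p[:, 0] >= threshold).astype(np.int64)
        return p.argmax(axis=1)

    # -------------------------------------------------------------- training

    def _logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        if tuple(x.shape[1:]) != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input "
                f"{self.input_shape}"
            )
        for layer in self.layers[:-1]:
            x = layer.forward(x, training=training)
        return x

    def _loss_and_grad(
        self, logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Weighted cross-entropy at the logits, head activation fused in."""
        w = sample_weight / sample_weight.mean()
        n = logits.shape[0]
        if self.head_kind == "sigmoid":
            z = np.clip(logits[:, 0], -60, 60)
            p = 1.0 / (1.0 + np.exp(-z))
            ce = -(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))
            grad = ((p - y) * w / n)[:, None]
        else:
            z = logits - logits.max(axis=1, keepdims=True)
            logsumexp = np.log(np.exp(z).sum(axis=1))
            ce = logsumexp - z[np.arange(n), y]
            p = np.exp(z - logsumexp[:, None])
            grad = p.copy()
            grad[np.arange(n), y] -= 1.0
            grad *= (w / n)[:, None]
        loss = float((w * ce).mean()) + sum(l.regularization_loss() for l in self.layers)
        return loss, grad

    def train_batch(
        self,
        x: np.ndarray,
        y: np.ndarray,
        optimizer: Adam,
        sample_weight: np.ndarray | None = None,
    ) -> tuple[float, int]:
        """One optimizer step; returns the batch loss and its correct count
        (from the training-mode logits, so no extra forward pass)."""
        if sample_weight is None:
            sample_weight = np.ones(len(y))
        logits = self._logits(x, training=True)
        loss, grad = self._loss_and_grad(logits, y, sample_weight)
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)
        optimizer.step(self.layers)
        if self.head_kind == "sigmoid":
            pred = (logits[:, 0] >= 0.0).astype(np.int64)
        else:
            pred = logits.argmax(axis=1)
        return loss, int((pred == y).sum())

    def evaluate(
        self, x: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
    ) -> tuple[float, float]:
        """Weighted loss and plain accuracy without updating anything."""
        if sample_weight is None:
            sample_weight = np.ones(len(y))
        logits = self._logits(x, training=False)
        loss, _ = self._loss_and_grad(logits, y, sample_weight)
        if self.head_kind == "sigmoid":
            pred = (logits[:, 0] >= 0.0).astype(np.int64)
        else:
            pred = logits.argmax(axis=1)
        return loss, float((pred == y).mean())

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float = 1e-4,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
        class_weight: dict[int, float] | None = None,
        shuffle_rng: np.random.Generator | None = None,
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Fixed-epoch training with per-epoch reshuffling.

        Returns a history dict with per-epoch train loss/accuracy and, when
        validation data is given, validation loss/accuracy.
        """
        rng = shuffle_rng or np.random.default_rng(0)
        opt = Adam(lr=lr)
        sw = np.ones(len(y))
        if class_weight:
            sw = np.array([class_weight[int(c)] for c in y])
        history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        if validation_data is not None:
            history["val_loss"] = []
            history["val_accuracy"] = []
        order = np.arange(len(y))
        for epoch in range(epochs):
            rng.shuffle(order)
            # epoch loss/accuracy are running averages over training batches
            total_loss, total_correct = 0.0, 0
            for start in range(0, len(order), batch_size):
                idx = order[start : start + batch_size]
                bloss, bcorrect = self.train_batch(x[idx], y[idx], opt, sw[idx])
                total_loss += bloss * len(idx)
                total_correct += bcorrect
            loss = total_loss / len(order)
            acc = total_correct / len(order)
            history["loss"].append(loss)
            history["accuracy"].append(acc)
            if validation_data is not None:
                vx, vy = validation_data
                vloss, vacc = self.evaluate(vx, vy)
                history["val_loss"].append(vloss)
                history["val_accuracy"].append(vacc)
            if verbose:
                msg = f"epoch {epoch + 1}/{epochs} loss={loss:.4f} acc={acc:.4f}"
                if validation_data is not None:
                    msg += f" val_loss={vloss:.4f} val_acc={vacc:.4f}"
                print(msg)
        return history
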