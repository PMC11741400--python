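"""Adam optimizer, loss functions and the generic mini-batch fit loop with
early stopping on validation loss."""

from __future__ import annotations

import numpy as np

from kinetraits.nn.autodiff import Tensor


def mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error against a constant target."""
    return (pred - Tensor(target)).abs().mean()


def bce_with_logits_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on logits."""
    z = logits.data
    target = np.asarray(target, dtype=float).reshape(z.shape)
    softplus = np.logaddexp(0.0, z)
    out = Tensor((softplus - target * z).mean(), (logits,))
    n = z.size

    def backward() -> None:
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        logits._accumulate(out.grad * (sig - target) / n)

    out._backward = backward
    return out


class Adam:
    """Adam over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
            m_hat = self.m[key] / (1 - self.beta1**self.t)
            v_hat = self.v[key] / (1 - self.beta2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def fit(
    params: dict[str, Tensor],
    forward_loss,  # (indices, train: bool) -> Tensor scalar loss
    n_train: int,
    val_loss,  # () -> float, or None
    *,
    lr: float,
    batch_size: int,
    epochs: int,
    patience: int,
    rng: np.random.Generator,
) -> float:
    """Generic training loop; returns the best monitored loss.

    ``forward_loss`` computes the mini-batch loss for given sample indices;
    ``val_loss`` is monitored for early stopping (falls back to the mean
    training loss when no validation set exists). Best parameters are
    restored before returning.
    """
    optimizer = Adam(params, lr=lr)
    best = np.inf
    best_state = {k: p.data.copy() for k, p in params.items()}
    stale = 0
    for _ in range(epochs):
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, batch_size):
            batch = order[start : start + batch_size]
            optimizer.zero_grad()
            loss = forward_loss(batch, True)
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        monitored = val_loss() if val_loss is not None else float(np.mean(epoch_losses))
        if monitored < best - 1e-9:
            best = monitored
            best_state = {k: p.data.copy() for k, p in params.items()}
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break
    for key, p in params.items():
        p.data = best_state[key]
    return best
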