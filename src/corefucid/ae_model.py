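"""Self-supervised autoencoder anomaly detector for core-fucose identification.

A 10-9-8-7-8-9-10 fully connected autoencoder with tanh activations on every
layer (inputs are normalized relative intensities in [0, 1], inside tanh
range) is trained with Adam to reconstruct tagged nCF feature vectors. A
spectrum is called CF when its reconstruction error ‖X − g(f(X))‖ exceeds the
threshold α = μ + k·σ, where μ and σ are the mean and standard deviation of
the reconstruction errors over the training vectors and k is a user
parameter (0.4 by default, the setting found best in the original
experiment).

The network is implemented directly in numpy: it is tiny (seven layers, at
most ten units), fully seeded, and needs nothing beyond dense matmuls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .labeling import CF, NCF

logger = logging.getLogger("corefucid")

LAYER_SIZES = (10, 9, 8, 7, 8, 9, 10)
DEFAULT_K = 0.4


@dataclass
class AEConfig:
    """Training hyperparameters (the architecture itself is fixed)."""

    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 500
    patience: int = 20  # early stop after this many epochs without improvement
    min_delta: float = 1e-6
    min_train: int = 100
    seed: int = 42


@dataclass
class AEModel:
    """Trained autoencoder with its decision threshold.

    ``alpha = mu + k * sigma`` exactly, with μ, σ taken over the training
    set's final reconstruction errors.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    k: float
    mu: float
    sigma: float
    alpha: float
    config: AEConfig = field(default_factory=AEConfig)
    layer_sizes: tuple[int, ...] = LAYER_SIZES
    final_loss: float = float("nan")

    def with_k(self, k: float) -> "AEModel":
        """Same network, rethresholded at a different k (no retraining)."""
        return AEModel(weights=self.weights, biases=self.biases, k=k,
                       mu=self.mu, sigma=self.sigma, alpha=self.mu + k * self.sigma,
                       config=self.config, layer_sizes=self.layer_sizes,
                       final_loss=self.final_loss)


def _init_params(rng: np.random.Generator) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for n_in, n_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
        # Xavier/Glorot scaling, appropriate for tanh
        limit = np.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
        biases.append(np.zeros(n_out))
    return weights, biases


def _forward(weights, biases, X: np.ndarray) -> list[np.ndarray]:
    """Return activations per layer; tanh on every layer including the output."""
    acts = [X]
    a = X
    for W, b in zip(weights, biases):
        a = np.tanh(a @ W + b)
        acts.append(a)
    return acts


def reconstruct(model: AEModel, X: np.ndarray) -> np.ndarray:
    """g(f(X)) for a vector or matrix of normalized feature vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return _forward(model.weights, model.biases, X)[-1]


def reconstruction_error(model: AEModel, X: np.ndarray) -> float | np.ndarray:
    """Euclidean norm of the reconstruction residual, per vector."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    err = np.linalg.norm(X2 - reconstruct(model, X2), axis=1)
    return float(err[0]) if single else err


def train_ae(
    X_train: np.ndarray,
    k: float = DEFAULT_K,
    config: AEConfig | None = None,
) -> AEModel:
    """Train the autoencoder on tagged nCF vectors and set the CF threshold.

    Minimizes mean squared reconstruction error with Adam; stops early when
    the epoch loss stops improving. Raises on loss divergence (NaN).
    """
    cfg = config or AEConfig()
    X = np.atleast_2d(np.asarray(X_train, dtype=np.float64))
    n = len(X)
    if n < cfg.min_train:
        raise ValueError(f"need at least {cfg.min_train} training vectors, got {n}")
    if X.shape[1] != LAYER_SIZES[0]:
        raise ValueError(f"expected {LAYER_SIZES[0]}-dim vectors, got {X.shape[1]}")

    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_params(rng)
    # Adam state
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mB = [np.zeros_like(b) for b in biases]
    vB = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    best_loss = np.inf
    stall = 0
    epoch_loss = np.nan
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = X[order[start:start + cfg.batch_size]]
            acts = _forward(weights, biases, batch)
            out = acts[-1]
            resid = out - batch
            losses.append(float(np.mean(resid**2)))
            # backprop: dL/dout for MSE over all elements of the batch
            delta = (2.0 / resid.size) * resid * (1.0 - out**2)
            gW = [np.empty(0)] * len(weights)
            gB = [np.empty(0)] * len(biases)
            for layer in range(len(weights) - 1, -1, -1):
                gW[layer] = acts[layer].T @ delta
                gB[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (1.0 - acts[layer]**2)
            t += 1
            for layer in range(len(weights)):
                for g, m, v, p in ((gW[layer], mW[layer], vW[layer], weights[layer]),
                                   (gB[layer], mB[layer], vB[layer], biases[layer])):
                    m[...] = beta1 * m + (1 - beta1) * g
                    v[...] = beta2 * v + (1 - beta2) * g**2
                    m_hat = m / (1 - beta1**t)
                    v_hat = v / (1 - beta2**t)
                    p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        epoch_loss = float(np.mean(losses))
        if not np.isfinite(epoch_loss):
            raise RuntimeError(f"autoencoder training diverged (loss={epoch_loss}) with {cfg}")
        if epoch_loss < best_loss - cfg.min_delta:
            best_loss = epoch_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                logger.info("early stop at epoch %d (loss %.3g)", epoch + 1, epoch_loss)
                break

    model = AEModel(weights=weights, biases=biases, k=k, mu=0.0, sigma=0.0,
                    alpha=0.0, config=cfg, final_loss=epoch_loss)
    errors = reconstruction_error(model, X)
    model.mu = float(np.mean(errors))
    model.sigma = float(np.std(errors))
    model.alpha = model.mu + k * model.sigma
    return model


def ae_predict(model: AEModel, X: np.ndarray) -> str | np.ndarray:
    """CF iff the reconstruction error strictly exceeds α; nCF otherwise."""
    err = reconstruction_error(model, X)
    if np.isscalar(err) or getattr(err, "ndim", 1) == 0:
        return CF if err > model.alpha else NCF
    return np.where(err > model.alpha, CF, NCF)
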