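"""Autoencoder classification with swarm-tuned weights.

An autoencoder compresses an input ``x in R^m`` to a latent code
``h = f(W x + b) in R^n`` (n < m) and reconstructs ``x' = f'(W' h + b')``;
quality is the squared reconstruction error ``||x - x'||^2``.  Here one
autoencoder is trained per class and a sample is assigned to the class
whose autoencoder reconstructs it best (ties go to label 0) — the minimal
arrangement that turns a reconstruction model into a classifier without an
extra output head.

Rather than gradient descent, the flattened weights and biases of both
class autoencoders form one decision vector tuned by the multileader
optimizer under a classification-error fitness,

    fitness = 100 * misclassified / total  (+ 1e-3 * mean reconstruction MSE),

the small reconstruction term breaking plateaus of the discrete error
rate.  An optional warm start seeds the swarm with a few epochs of plain
gradient pretraining per class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .optimizers import MLOParams, ObjectiveSpec, OptimizeResult, mlo_optimize
from .phantoms import LabeledDataset


class AEError(ValueError):
    """Raised for invalid autoencoder configuration or inputs."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTIVATIONS = {
    "sigmoid": _sigmoid,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass(frozen=True)
class AEConfig:
    """Shape and activations of one autoencoder.

    ``latent_dim`` defaults to ``ceil(input_dim / 4)`` — a genuine
    compression, as the model requires ``latent_dim < input_dim``.
    """

    input_dim: int
    latent_dim: Optional[int] = None
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.latent_dim is None:
            object.__setattr__(self, "latent_dim", max(1, math.ceil(self.input_dim / 4)))
        if self.activation not in _ACTIVATIONS:
            raise AEError(
                f"activation must be one of {sorted(_ACTIVATIONS)}, got {self.activation!r}"
            )
        if self.latent_dim < 1:
            raise AEError(f"latent_dim must be >= 1, got {self.latent_dim}")
        if self.latent_dim >= self.input_dim:
            raise AEError(
                f"latent_dim ({self.latent_dim}) must be below input_dim "
                f"({self.input_dim}) — the autoencoder must compress"
            )

    @property
    def n_params(self) -> int:
        m, n = self.input_dim, self.latent_dim
        return 2 * (m * n) + m + n


@dataclass
class AEParams:
    """Encoder/decoder weights and biases of one autoencoder."""

    enc_weights: np.ndarray  # (n, m)
    enc_bias: np.ndarray  # (n,)
    dec_weights: np.ndarray  # (m, n)
    dec_bias: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        for name in ("enc_weights", "enc_bias", "dec_weights", "dec_bias"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise AEError(f"{name} contains non-finite entries")
            setattr(self, name, arr)
        n, m = self.enc_weights.shape
        if self.enc_bias.shape != (n,) or self.dec_weights.shape != (m, n) or \
                self.dec_bias.shape != (m,):
            raise AEError("autoencoder parameter shapes are inconsistent")

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [
                self.enc_weights.ravel(),
                self.enc_bias,
                self.dec_weights.ravel(),
                self.dec_bias,
            ]
        )

    @classmethod
    def from_flat(cls, vector: np.ndarray, config: AEConfig) -> "AEParams":
        vector = np.asarray(vector, dtype=float)
        m, n = config.input_dim, config.latent_dim
        if vector.shape != (config.n_params,):
            raise AEError(
                f"expected flat vector of length {config.n_params}, got {vector.shape}"
            )
        i = 0
        enc_w = vector[i : i + n * m].reshape(n, m); i += n * m
        enc_b = vector[i : i + n]; i += n
        dec_w = vector[i : i + m * n].reshape(m, n); i += m * n
        dec_b = vector[i : i + m]
        return cls(enc_w, enc_b, dec_w, dec_b)


def ae_forward(
    x: np.ndarray, params: AEParams, config: AEConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Encode then decode: ``h = f(Wx + b)``, ``x' = f'(W'h + b')``.

    Accepts a single vector (m,) or a batch (N, m); returns (h, x') with
    matching leading shape.
    """
    act = _ACTIVATIONS[config.activation]
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    batch = np.atleast_2d(x)
    if batch.shape[1] != config.input_dim:
        raise AEError(
            f"input dimension {batch.shape[1]} does not match config "
            f"({config.input_dim})"
        )
    h = act(batch @ params.enc_weights.T + params.enc_bias)
    x_prime = act(h @ params.dec_weights.T + params.dec_bias)
    if single:
        return h[0], x_prime[0]
    return h, x_prime


def reconstruction_error(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Squared reconstruction error ``||x - x'||^2`` of one instance."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise AEError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    return float(np.sum((x - x_prime) ** 2))


def fitness_error_rate(predictions, labels) -> float:
    """Classification error rate as a percentage: ``100 * wrong / total``."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise AEError("predictions and labels must be equal-length and non-empty")
    return 100.0 * float(np.mean(predictions != labels))


@dataclass
class ClassifierModel:
    """One autoencoder per class plus the training-set feature scaling."""

    config: AEConfig
    params_by_class: dict[int, AEParams]
    feature_min: np.ndarray
    feature_max: np.ndarray
    training_fitness: Optional[float] = None

    def __post_init__(self) -> None:
        if set(self.params_by_class) != {0, 1}:
            raise AEError("model must hold autoencoders for both classes 0 and 1")
        self.feature_min = np.asarray(self.feature_min, dtype=float)
        self.feature_max = np.asarray(self.feature_max, dtype=float)

    def scale(self, x: np.ndarray) -> np.ndarray:
        """Min-max scale features with the stored training-set ranges."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.config.input_dim:
            raise AEError(
                f"feature dimension {x.shape[1]} does not match model "
                f"({self.config.input_dim})"
            )
        span = np.where(self.feature_max > self.feature_min,
                        self.feature_max - self.feature_min, 1.0)
        return (x - self.feature_min) / span

    def reconstruction_errors(self, x_scaled: np.ndarray) -> np.ndarray:
        """Per-class squared reconstruction errors, shape (N, 2)."""
        errs = np.empty((x_scaled.shape[0], 2))
        for label in (0, 1):
            _, x_prime = ae_forward(x_scaled, self.params_by_class[label], self.config)
            errs[:, label] = np.sum((x_scaled - x_prime) ** 2, axis=1)
        return errs

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Labels for raw (unscaled) feature rows; ties resolve to 0."""
        errs = self.reconstruction_errors(self.scale(x))
        return (errs[:, 1] < errs[:, 0]).astype(np.int64)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                "input_dim": self.config.input_dim,
                "latent_dim": self.config.latent_dim,
                "activation": self.config.activation,
            },
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "params": {
                str(label): p.flatten().tolist()
                for label, p in self.params_by_class.items()
            },
            "training_fitness": self.training_fitness,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        config = AEConfig(**payload["config"])
        params = {
            int(label): AEParams.from_flat(np.array(vec), config)
            for label, vec in payload["params"].items()
        }
        return cls(
            config=config,
            params_by_class=params,
            feature_min=np.array(payload["feature_min"]),
            feature_max=np.array(payload["feature_max"]),
            training_fitness=payload.get("training_fitness"),
        )


def classify(x: np.ndarray, model: ClassifierModel) -> int:
    """Label one raw feature vector by smallest reconstruction error."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise AEError("classify expects a single 1-D feature vector")
    return int(model.predict(x[None, :])[0])


def _model_from_vector(
    vector: np.ndarray,
    config: AEConfig,
    feature_min: np.ndarray,
    feature_max: np.ndarray,
) -> ClassifierModel:
    half = config.n_params
    return ClassifierModel(
        config=config,
        params_by_class={
            0: AEParams.from_flat(vector[:half], config),
            1: AEParams.from_flat(vector[half:], config),
        },
        feature_min=feature_min,
        feature_max=feature_max,
    )


def _gradient_pretrain(
    x: np.ndarray, config: AEConfig, seed: int, epochs: int = 200, lr: float = 0.5
) -> AEParams:
    """A few epochs of full-batch gradient descent on reconstruction MSE.

    Sigmoid-only helper used to warm-start the swarm; deliberately simple
    (no momentum, no minibatching).
    """
    rng = np.random.default_rng(seed)
    m, n = config.input_dim, config.latent_dim
    enc_w = rng.normal(0, 0.3, (n, m))
    enc_b = np.zeros(n)
    dec_w = rng.normal(0, 0.3, (m, n))
    dec_b = np.zeros(m)
    n_obs = x.shape[0]
    for _ in range(epochs):
        h = _sigmoid(x @ enc_w.T + enc_b)
        xp = _sigmoid(h @ dec_w.T + dec_b)
        d_out = 2.0 * (xp - x) * xp * (1 - xp) / n_obs
        d_h = (d_out @ dec_w) * h * (1 - h)
        dec_w -= lr * d_out.T @ h
        dec_b -= lr * d_out.sum(axis=0)
        enc_w -= lr * d_h.T @ x
        enc_b -= lr * d_h.sum(axis=0)
    return AEParams(enc_w, enc_b, dec_w, dec_b)


def train_mlo(
    train_set: LabeledDataset,
    config: Optional[AEConfig] = None,
    mlo: Optional[MLOParams] = None,
    warm_start: bool = False,
    search_bound: float = 3.0,
) -> tuple[ClassifierModel, OptimizeResult]:
    """Tune both class autoencoders with the multileader optimizer.

    The decision vector concatenates the flattened parameters of the
    class-0 and class-1 autoencoders, searched in
    ``[-search_bound, search_bound]`` per coordinate (sigmoids saturate
    beyond about 3).  Fitness on the training set is the error-rate
    percentage plus ``1e-3`` times the mean squared reconstruction error of
    each sample under its own class's autoencoder.  Deterministic given the
    MLO seed.

    Returns the fitted model (with ``training_fitness`` set) and the full
    optimization result.
    """
    x_raw, y = train_set.feature_matrix()
    if len(np.unique(y)) < 2:
        raise AEError("training data must contain both classes")
    if config is None:
        config = AEConfig(input_dim=x_raw.shape[1])
    if config.input_dim != x_raw.shape[1]:
        raise AEError(
            f"config input_dim ({config.input_dim}) does not match features "
            f"({x_raw.shape[1]})"
        )
    if mlo is None:
        mlo = MLOParams()

    feat_min = x_raw.min(axis=0)
    feat_max = x_raw.max(axis=0)
    span = np.where(feat_max > feat_min, feat_max - feat_min, 1.0)
    x = (x_raw - feat_min) / span
    mask1 = y == 1

    act = _ACTIVATIONS[config.activation]
    half = config.n_params

    def evaluate(vector: np.ndarray) -> float:
        errs = np.empty((x.shape[0], 2))
        for label, sl in ((0, slice(0, half)), (1, slice(half, 2 * half))):
            p = AEParams.from_flat(vector[sl], config)
            h = act(x @ p.enc_weights.T + p.enc_bias)
            xp = act(h @ p.dec_weights.T + p.dec_bias)
            errs[:, label] = np.sum((x - xp) ** 2, axis=1)
        pred = errs[:, 1] < errs[:, 0]
        error_rate = 100.0 * float(np.mean(pred != mask1))
        own_mse = float(np.mean(np.where(mask1, errs[:, 1], errs[:, 0])))
        return error_rate + 1e-3 * own_mse

    bounds = np.tile([-search_bound, search_bound], (2 * half, 1))
    objective = ObjectiveSpec(evaluate, bounds, 2 * half)

    initial = None
    if warm_start:
        seeds = []
        for label in (0, 1):
            pre = _gradient_pretrain(x[y == label], config, seed=mlo.seed + label)
            seeds.append(np.clip(pre.flatten(), -search_bound, search_bound))
        initial = np.concatenate(seeds)[None, :]

    result = mlo_optimize(objective, mlo, initial_positions=initial)
    model = _model_from_vector(result.best_position, config, feat_min, feat_max)
    model.training_fitness = result.best_fitness
    return model, result
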