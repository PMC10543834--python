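"""Training loop: mini-batch Adam on the mean-squared-error loss.

Defaults follow the published configuration (Adam, learning rate 5e-4,
1000 epochs, dropout 0.2); batch size defaults to 512 with automatic
reduction to the training-set size for small data.  No early stopping and
no learning-rate schedule by default; both are exposed as options.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Tensor
from .errors import ConfigError, InputError, TrainingDivergedError
from .metrics import EvalResult, evaluate
from .model import AffinityModel, FeaturizedDataset

__all__ = ["TrainConfig", "TrainHistory", "mse_loss", "train", "evaluate_model"]


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    epochs: int = 1000
    batch_size: int = 512
    seed: int = 0
    shuffle: bool = True
    eval_every: int = 0  # 0 = no per-epoch held-out evaluation
    log_every: int = 0  # 0 = silent; else print loss every k epochs
    early_stop_patience: int = 0  # 0 = off; else stop after k non-improving evals

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 300) -> "TrainConfig":
        """Reduced configuration for CPU-scale experiments: full-batch Adam
        with a larger step size compensating for the short schedule."""
        return cls(learning_rate=5e-3, epochs=epochs, batch_size=512, seed=seed)


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    eval_epochs: list[int] = field(default_factory=list)
    eval_ci: list[float] = field(default_factory=list)
    eval_mse: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)


def mse_loss(pred: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable mean squared error between predictions and labels."""
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if labels.size == 0:
        raise InputError("empty batch")
    if pred.data.shape != labels.shape:
        raise InputError("prediction/label length mismatch")
    diff = pred - Tensor(labels)
    return (diff * diff).mean()


def train(
    model: AffinityModel,
    train_records,
    valid_records,
    config: TrainConfig,
) -> tuple[AffinityModel, TrainHistory]:
    """Train in place for exactly ``config.epochs`` epochs; returns history.

    Dropout (as configured on the model) is active during training only.
    A non-finite loss aborts with the offending epoch and batch.
    """
    config.validate()
    dataset = FeaturizedDataset(train_records, model.config)
    valid_ds = (
        FeaturizedDataset(valid_records, model.config) if valid_records else None
    )
    n = len(dataset.records)
    batch_size = min(config.batch_size, n)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    t0 = time.perf_counter()
    best_eval = np.inf
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        epoch_losses = []
        for b, start in enumerate(range(0, n, batch_size)):
            batch = dataset.batch(order[start : start + batch_size])
            optimizer.zero_grad()
            pred = model.forward_batch(batch, training=True)
            loss = mse_loss(pred, batch.labels)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergedError(epoch, b)
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        history.epoch_loss.append(float(np.mean(epoch_losses)))
        history.wall_time.append(time.perf_counter() - t0)
        if config.log_every and (epoch + 1) % config.log_every == 0:
            print(f"epoch {epoch + 1}: loss {history.epoch_loss[-1]:.6f}")
        if valid_ds is not None and config.eval_every and (
            (epoch + 1) % config.eval_every == 0
        ):
            result = _evaluate_dataset(model, valid_ds)
            history.eval_epochs.append(epoch + 1)
            history.eval_ci.append(result.ci)
            history.eval_mse.append(result.mse)
            if config.early_stop_patience:
                if result.mse < best_eval - 1e-12:
                    best_eval, stale = result.mse, 0
                else:
                    stale += 1
                    if stale >= config.early_stop_patience:
                        break
    return model, history


def _evaluate_dataset(model: AffinityModel, dataset: FeaturizedDataset) -> EvalResult:
    pred = model.forward_batch(dataset.batch(), training=False).data
    return evaluate(dataset.labels, pred)


def evaluate_model(model: AffinityModel, records) -> EvalResult:
    """Evaluation-mode predictions followed by the full metric suite."""
    if not records:
        raise InputError("no records to evaluate")
    return _evaluate_dataset(model, FeaturizedDataset(records, model.config))
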