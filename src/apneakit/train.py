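"""Training protocol for the per-minute apnea classifier.

Adam on categorical cross-entropy, batch size 10, 50 epochs; the experiment
is repeated with independent seeds (10 by default) and the checkpoint kept
is the one with the highest validation accuracy across all epochs and
repeats (ties broken by the earliest epoch / lowest experiment index).
Training metrics per epoch are batch-averaged; validation metrics are
computed in a full inference pass at the end of each epoch, which is why
validation curves are noisier than training curves at small sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import ModelConfig, build_model
from .nn import Network, softmax_cross_entropy
from .preprocess import MinuteSegment

__all__ = [
    "TrainingConfig", "ExperimentHistory",
    "segments_to_arrays", "train_once", "run_experiments", "predict_segments",
]

LABEL_TO_CLASS = {"N": 0, "A": 1}
CLASS_TO_LABEL = {v: k for k, v in LABEL_TO_CLASS.items()}


@dataclass
class TrainingConfig:
    """Optimization protocol parameters (defaults follow the reference run)."""

    batch_size: int = 10
    epochs: int = 50
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    n_experiments: int = 10
    seeds: Optional[list[int]] = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if self.seeds is not None and len(self.seeds) != self.n_experiments:
            raise ValueError(
                f"{len(self.seeds)} seeds for {self.n_experiments} experiments")

    def experiment_seeds(self, base_seed: int = 0) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        ss = np.random.SeedSequence(base_seed)
        return [int(s) % (2 ** 31) for s in ss.generate_state(self.n_experiments)]


@dataclass
class ExperimentHistory:
    """Per-epoch metrics of one training run and its best checkpoint."""

    train_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -math.inf
    seed: Optional[int] = None

    def as_dict(self) -> dict:
        return {
            "epoch": list(range(1, len(self.train_accuracy) + 1)),
            "train_accuracy": self.train_accuracy,
            "train_loss": self.train_loss,
            "val_accuracy": self.val_accuracy,
            "val_loss": self.val_loss,
        }


def segments_to_arrays(segments: Sequence[MinuteSegment]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into (n, length, 1) float32 inputs and class indices."""
    if not segments:
        raise ValueError("no segments given")
    X = np.stack([np.asarray(s.values, dtype=np.float32) for s in segments])
    y = np.array([LABEL_TO_CLASS[s.label] for s in segments], dtype=np.int64)
    return X[:, :, None], y


def _full_pass(net: Network, X: np.ndarray, y: np.ndarray,
               batch_size: int = 64) -> tuple[float, float]:
    """Inference-mode loss and accuracy over a whole array."""
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = net.forward(X[i:i + batch_size], training=False)
        loss, _ = softmax_cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train_once(model: Network,
               train_segments: Sequence[MinuteSegment],
               val_segments: Sequence[MinuteSegment],
               cfg: TrainingConfig,
               seed: int) -> tuple[ExperimentHistory, dict]:
    """Train one model; returns (history, best-validation checkpoint).

    The checkpoint is the model state at the epoch with the highest
    validation accuracy (validation loss is never the criterion).
    """
    from .nn import Adam

    Xtr, ytr = segments_to_arrays(train_segments)
    Xva, yva = segments_to_arrays(val_segments)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training data contains a single class; "
                         "both N and A minutes are required")

    rng = np.random.default_rng(seed)
    opt = Adam(model, lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    hist = ExperimentHistory(seed=seed)
    best_state: dict = model.state_dict()

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        batch_losses, batch_accs = [], []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, acc = model.train_step(Xtr[idx], ytr[idx], rng)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, "
                    f"batch {start // cfg.batch_size}: {loss}")
            opt.step()
            batch_losses.append(loss)
            batch_accs.append(acc)
        hist.train_loss.append(float(np.mean(batch_losses)))
        hist.train_accuracy.append(float(np.mean(batch_accs)))
        val_loss, val_acc = _full_pass(model, Xva, yva)
        hist.val_loss.append(val_loss)
        hist.val_accuracy.append(val_acc)
        if val_acc > hist.best_val_accuracy:
            hist.best_val_accuracy = val_acc
            hist.best_epoch = epoch + 1
            best_state = model.state_dict()
    return hist, best_state


def run_experiments(model_cfg: ModelConfig,
                    train_segments: Sequence[MinuteSegment],
                    val_segments: Sequence[MinuteSegment],
                    cfg: TrainingConfig,
                    base_seed: int = 0
                    ) -> tuple[list[ExperimentHistory], dict, int]:
    """Repeat training with independent seeds; keep the best checkpoint.

    Returns (histories, best checkpoint state, index of the best
    experiment).  The best experiment is the one with the maximum
    best_val_accuracy; ties go to the lowest index.
    """
    histories: list[ExperimentHistory] = []
    best_state: dict = {}
    best_idx = -1
    best_acc = -math.inf
    for i, seed in enumerate(cfg.experiment_seeds(base_seed)):
        model = build_model(model_cfg, seed)
        hist, state = train_once(model, train_segments, val_segments, cfg,
                                 seed)
        histories.append(hist)
        if hist.best_val_accuracy > best_acc:
            best_acc = hist.best_val_accuracy
            best_state = state
            best_idx = i
    return histories, best_state, best_idx


def predict_segments(model: Network, segments: Sequence[MinuteSegment]
                     ) -> tuple[np.ndarray, list[str]]:
    """Apnea probabilities and hard labels for a list of segments.

    The hard label is the class with the greater probability; an exact tie
    (p = 0.5) predicts 'N'.
    """
    X, _ = segments_to_arrays(segments)
    proba = model.predict_proba(X)[:, 1]
    labels = ["A" if p > 0.5 else "N" for p in proba]
    return proba, labels
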