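"""Training loop, learning-rate schedules, k-fold cross-validation and the
augmentation/schedule ablation grid.

Schedules (epoch t >= 0):

    constant      alpha_t = alpha0
    exponential   alpha_t = alpha0 * exp(-k * t)
    step          alpha_t = alpha0 * eta ** (-floor(t / gamma))

Cross-validation follows the hybrid design of a fixed, chip-disjoint test
set plus a 10-fold split of the train+validation pool: the pool is shuffled
once, cut into k near-equal partitions, fold i trains on the other k-1
partitions (its own partition serves as the validation monitor), and every
fold is evaluated on the same test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment_batch
from .evaluate import MetricsReport, evaluate_predictions, summarize_folds
from .network import (AdamConfig, AdamState, NetworkConfig, SmallCNN,
                      adam_step, build_network)

__all__ = [
    "ScheduleConfig", "TrainRun", "schedule", "train",
    "cross_validate", "ablation_grid", "ABLATION_CONFIGS",
]


@dataclass(frozen=True)
class ScheduleConfig:
    """Learning-rate schedule: constant, exponential or step decay."""

    kind: str = "step"
    alpha0: float = 0.001
    k: float = 0.1        # exponential rate constant
    eta: float = 2.0      # step base
    gamma: float = 5.0    # step interval (epochs)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "exponential", "step"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.k < 0:
            raise ValueError("k must be nonnegative")
        if self.eta <= 1:
            raise ValueError("eta must exceed 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def schedule(config: ScheduleConfig, t: int | float) -> float:
    """Learning rate at epoch ``t`` (non-increasing in t; alpha0 at t=0)."""
    if t < 0:
        raise ValueError("epoch number must be >= 0")
    if config.kind == "constant":
        return config.alpha0
    if config.kind == "exponential":
        return config.alpha0 * math.exp(-config.k * t)
    return config.alpha0 * config.eta ** (-math.floor(t / config.gamma))


@dataclass
class TrainRun:
    """Per-epoch history plus the trained network."""

    network: SmallCNN
    loss_history: list[float]
    acc_history: list[float]
    val_acc_history: list[float]
    lr_history: list[float]
    fold_id: int | None = None
    seed: int | None = None

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(len(self.loss_history)),
                             "loss": self.loss_history, "accuracy": self.acc_history,
                             "val_accuracy": self.val_acc_history,
                             "learning_rate": self.lr_history})


def train(X_train: np.ndarray, y_train: np.ndarray,
          X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          network_config: NetworkConfig = NetworkConfig(),
          adam_config: AdamConfig = AdamConfig(),
          schedule_config: ScheduleConfig = ScheduleConfig(),
          augment_config: AugmentConfig | None = None,
          epochs: int = 50, seed: int = 0, fold_id: int | None = None) -> TrainRun:
    """Train the classifier; deterministic given the seed.

    Augmentation, when configured, touches training batches only.  The
    learning rate of epoch t is ``schedule(schedule_config, t)``.
    """
    if len(X_train) == 0:
        raise ValueError("training set must be non-empty")
    net = build_network(network_config, seed=seed)
    state = AdamState.zeros_like(net.params)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA06]))
    n = len(X_train)
    bs = adam_config.batch_size
    loss_hist, acc_hist, val_hist, lr_hist = [], [], [], []
    for epoch in range(epochs):
        alpha_t = schedule(schedule_config, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb = X_train[idx]
            if augment_config is not None:
                xb = augment_batch(xb, augment_config, rng)
            loss, grads = net.loss_and_gradients(xb, y_train[idx])
            adam_step(net.params, grads, state, adam_config, alpha_t)
            epoch_loss += loss * len(idx)
            # running accuracy over the (augmented) batches of this epoch
            epoch_correct += int((net.last_probs.argmax(axis=1) == y_train[idx]).sum())
        loss_hist.append(epoch_loss / n)
        acc_hist.append(epoch_correct / n)
        if X_val is not None and len(X_val):
            val_hist.append(float((net.predict(X_val) == y_val).mean()))
        else:
            val_hist.append(float("nan"))
        lr_hist.append(alpha_t)
    return TrainRun(network=net, loss_history=loss_hist, acc_history=acc_hist,
                    val_acc_history=val_hist, lr_history=lr_hist,
                    fold_id=fold_id, seed=seed)


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffle ``range(n)`` once and cut it into k near-equal partitions."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError("pool smaller than the number of folds")
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


def cross_validate(X_pool: np.ndarray, y_pool: np.ndarray,
                   X_test: np.ndarray, y_test: np.ndarray, k: int = 10,
                   network_config: NetworkConfig = NetworkConfig(),
                   adam_config: AdamConfig = AdamConfig(),
                   schedule_config: ScheduleConfig = ScheduleConfig(),
                   augment_config: AugmentConfig | None = None,
                   epochs: int = 50, seed: int = 0,
                   ) -> tuple[list[MetricsReport], pd.DataFrame]:
    """k-fold cross-validation against a fixed test set.

    Returns the per-fold metric reports (each computed on the same
    chip-disjoint test set) and a mean +- sd summary over folds.
    """
    folds = make_folds(len(X_pool), k, seed)
    reports: list[MetricsReport] = []
    for i, held in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(X_pool)), held)
        run = train(X_pool[train_idx], y_pool[train_idx],
                    X_pool[held], y_pool[held],
                    network_config, adam_config, schedule_config,
                    augment_config, epochs=epochs,
                    seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
                    fold_id=i)
        scores = run.network.predict_proba(X_test)
        reports.append(evaluate_predictions(y_test, scores, fold_id=i))
    return reports, summarize_folds(reports)


#: the eight rows of the ablation: no augmentation with constant rates, then
#: augmentation crossed with the three schedules, each at alpha0 in
#: {0.0001, 0.001}
ABLATION_CONFIGS: list[dict] = [
    {"name": "no_aug_constant_1e-4", "augment": False,
     "schedule": ScheduleConfig("constant", 0.0001)},
    {"name": "no_aug_constant_1e-3", "augment": False,
     "schedule": ScheduleConfig("constant", 0.001)},
    {"name": "aug_constant_1e-4", "augment": True,
     "schedule": ScheduleConfig("constant", 0.0001)},
    {"name": "aug_constant_1e-3", "augment": True,
     "schedule": ScheduleConfig("constant", 0.001)},
    {"name": "aug_exponential_1e-4", "augment": True,
     "schedule": ScheduleConfig("exponential", 0.0001)},
    {"name": "aug_exponential_1e-3", "augment": True,
     "schedule": ScheduleConfig("exponential", 0.001)},
    {"name": "aug_step_1e-4", "augment": True,
     "schedule": ScheduleConfig("step", 0.0001)},
    {"name": "aug_step_1e-3", "augment": True,
     "schedule": ScheduleConfig("step", 0.001)},
]


def ablation_grid(X_pool: np.ndarray, y_pool: np.ndarray,
                  X_test: np.ndarray, y_test: np.ndarray, k: int = 10,
                  network_config: NetworkConfig = NetworkConfig(),
                  adam_config: AdamConfig = AdamConfig(),
                  augment_config: AugmentConfig = AugmentConfig(),
                  epochs: int = 50, seed: int = 0) -> pd.DataFrame:
    """Run the eight-configuration augmentation/schedule ablation.

    All configurations share the same fold assignment (same seed) for
    comparability.  The result has one row per configuration and mean/sd
    columns for accuracy, precision, recall, F1, sensitivity, specificity
    (percent, macro-averaged over the four levels).
    """
    rows = []
    for cfg in ABLATION_CONFIGS:
        aug = augment_config if cfg["augment"] else None
        _, summary = cross_validate(
            X_pool, y_pool, X_test, y_test, k=k,
            network_config=network_config, adam_config=adam_config,
            schedule_config=cfg["schedule"], augment_config=aug,
            epochs=epochs, seed=seed)
        row = {"configuration": cfg["name"], "augment": cfg["augment"],
               "schedule": cfg["schedule"].kind, "alpha0": cfg["schedule"].alpha0}
        for metric in summary.index:
            row[f"{metric}_mean"] = summary.loc[metric, "mean"]
            row[f"{metric}_sd"] = summary.loc[metric, "sd"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("configuration")
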