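"""Model/Results surface over the training pipeline.

``ResistanceLevelModel`` bundles a dataset split with the architecture,
optimizer, schedule and augmentation settings; ``fit`` trains one network
and returns a :class:`ResistanceLevelResults` carrying the trained
classifier, its training history and test-set metrics, while
``fit_cross_validate`` runs the k-fold protocol and returns a
:class:`CrossValidationResults` with fold-wise metrics and a mean +- sd
summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .chipsim import ChipStackSet, GeneratorParams, generate_dataset
from .evaluate import MetricsReport, evaluate_predictions, macro_summary
from .network import AdamConfig, NetworkConfig, SmallCNN
from .preprocess import (DatasetSplit, DEFAULT_SLICES, build_inputs,
                         split_dataset, stack_pixels)
from .trainkit import ScheduleConfig, TrainRun, cross_validate, train

__all__ = ["ResistanceLevelModel", "ResistanceLevelResults", "CrossValidationResults"]


class ResistanceLevelModel:
    """CNN grading of drug-resistance level, bound to a dataset split."""

    def __init__(self, split: DatasetSplit,
                 network: NetworkConfig = NetworkConfig(),
                 adam: AdamConfig = AdamConfig(),
                 schedule: ScheduleConfig = ScheduleConfig(),
                 augment: AugmentConfig | None = AugmentConfig()):
        self.split = split
        self.network = network
        self.adam = adam
        self.schedule = schedule
        self.augment = augment
        self._X_train, self._y_train = stack_pixels(split.train)
        if split.validation:
            self._X_val, self._y_val = stack_pixels(split.validation)
        else:
            self._X_val = np.zeros((0,) + self._X_train.shape[1:], dtype=np.float32)
            self._y_val = np.zeros(0, dtype=np.int64)
        self._X_test, self._y_test = stack_pixels(split.test)

    @classmethod
    def from_chips(cls, chips: Sequence[ChipStackSet],
                   slices=DEFAULT_SLICES, val_fraction: float = 0.10,
                   seed: int = 0, **kwargs) -> "ResistanceLevelModel":
        """Build from generated chips: slice-select, resize, split."""
        inputs = build_inputs(chips, slices)
        split = split_dataset(inputs, val_fraction=val_fraction, seed=seed)
        return cls(split, **kwargs)

    @classmethod
    def from_synthetic(cls, params: GeneratorParams = GeneratorParams(),
                       chips_per_level: int = 6, level0_missing_rois: int = 2,
                       seed: int = 0, **kwargs) -> "ResistanceLevelModel":
        """Generate the synthetic study end-to-end and build the model."""
        _, chips = generate_dataset(params, chips_per_level=chips_per_level,
                                    level0_missing_rois=level0_missing_rois,
                                    seed=seed)
        return cls.from_chips(chips, seed=seed, **kwargs)

    def fit(self, epochs: int = 50, seed: int = 0) -> "ResistanceLevelResults":
        run = train(self._X_train, self._y_train, self._X_val, self._y_val,
                    self.network, self.adam, self.schedule, self.augment,
                    epochs=epochs, seed=seed)
        scores = run.network.predict_proba(self._X_test)
        report = evaluate_predictions(self._y_test, scores)
        return ResistanceLevelResults(model=self, run=run, report=report)

    def fit_cross_validate(self, k: int = 10, epochs: int = 50,
                           seed: int = 0) -> "CrossValidationResults":
        """The k-fold protocol: folds partition the train+validation pool,
        every fold is scored on the fixed chip-disjoint test set."""
        X_pool = np.concatenate([self._X_train, self._X_val]) \
            if len(self._X_val) else self._X_train
        y_pool = np.concatenate([self._y_train, self._y_val]) \
            if len(self._y_val) else self._y_train
        reports, summary = cross_validate(
            X_pool, y_pool, self._X_test, self._y_test, k=k,
            network_config=self.network, adam_config=self.adam,
            schedule_config=self.schedule, augment_config=self.augment,
            epochs=epochs, seed=seed)
        return CrossValidationResults(model=self, reports=reports, table=summary)


@dataclass
class ResistanceLevelResults:
    """One trained network with its history and test-set evaluation."""

    model: ResistanceLevelModel
    run: TrainRun
    report: MetricsReport

    @property
    def network(self) -> SmallCNN:
        return self.run.network

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(X)

    def plot_confusion(self, path=None):
        from .viz import plot_confusion
        return plot_confusion(self.report.cm, path, title="Test-set confusion")

    def plot_roc(self, path=None):
        from .viz import plot_roc
        return plot_roc(self.report, path)

    def plot_history(self, path=None):
        from .viz import plot_history
        return plot_history(self.run.history, path)

    def summary(self) -> str:
        r = self.run
        lines = [
            "Resistance-level CNN fit",
            "========================",
            f"epochs: {len(r.loss_history)}  "
            f"final train acc: {r.acc_history[-1]:.3f}  "
            f"final val acc: {r.val_acc_history[-1]:.3f}",
            f"parameters: {self.network.n_parameters:,}",
            "",
            "Test-set confusion matrix (rows actual, cols predicted):",
            self.report.cm.to_frame().astype(int).to_string(),
            "",
            "Per-level metrics (%):",
            self.report.per_level.round(1).to_string(),
            "",
            "Macro: " + ", ".join(f"{k} {v:.1f}" for k, v in self.report.macro.items()),
        ]
        if self.report.auc:
            lines.append("AUC: " + ", ".join(
                f"L{lv} {a:.2f}" for lv, a in sorted(self.report.auc.items())))
        return "\n".join(lines)


@dataclass
class CrossValidationResults:
    """Fold-wise metric reports and their mean +- sd summary."""

    model: ResistanceLevelModel
    reports: list[MetricsReport]
    table: pd.DataFrame          # index metric, columns mean/sd

    @property
    def mean_confusion(self):
        return macro_summary(self.reports)["mean_confusion"]

    @property
    def mean_auc(self) -> dict[int, float]:
        return macro_summary(self.reports)["mean_auc"]

    def plot_confusion(self, path=None):
        from .viz import plot_confusion
        return plot_confusion(self.mean_confusion, path,
                              title="Fold-averaged confusion")

    def summary(self) -> str:
        lines = [
            f"Cross-validation over {len(self.reports)} folds",
            "=" * 40,
            "Macro metrics over folds (%, mean +- sd):",
        ]
        for metric, row in self.table.iterrows():
            lines.append(f"  {metric:<12s} {row['mean']:5.1f} +- {row['sd']:.1f}")
        lines += [
            "",
            "Fold-averaged confusion matrix (rows actual, cols predicted):",
            self.mean_confusion.to_frame().round(1).to_string(),
        ]
        if self.mean_auc:
            lines.append("Mean AUC: " + ", ".join(
                f"L{lv} {a:.2f}" for lv, a in sorted(self.mean_auc.items())))
        return "\n".join(lines)
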