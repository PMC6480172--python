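"""Stratified k-fold evaluation of the classifier family.

Ten-fold cross-validation is the evaluation protocol: each fold holds
out 10% of the segments for testing; of the remaining 90% training
portion, 10% is reserved as an inner validation split that steers early
stopping.  Class-wise precision (TP/(TP+FP)) and recall (TP/(TP+FN)) are
pooled over folds by summing confusion counts — every segment is tested
exactly once, so pooled counts sum to the dataset size — and the
support-weighted averages of precision and recall are the model-selection
criterion across the depth sweep.

For the sleep-position task only segments whose ground-truth quality is
C1 are admitted: noise carries no position information, and the blurry
C2 waveform lacks the P/T detail the position classes differ by.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .arch import build_spec
from .errors import ConfigurationError, EmptyTaskError
from .model import ConvNet1D, ConvNetResults, TrainConfig
from .preprocess import SegmentDataset

__all__ = [
    "CVPlan",
    "ClassMetrics",
    "make_folds",
    "train_model",
    "evaluate",
    "metrics_from_predictions",
    "task_arrays",
    "cross_validate",
    "ExperimentReport",
    "inject_label_noise",
    "QUALITY_LABELS",
    "POSITION_LABELS",
]

QUALITY_LABELS = ("C1", "C2", "N")
POSITION_LABELS = ("S", "L", "R")


@dataclass(frozen=True)
class CVPlan:
    """Fold assignment for stratified k-fold CV with an inner val split."""

    k: int
    fold_assignment: np.ndarray  # (n,) fold id per segment
    inner_val_fraction: float
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignment != fold)


def make_folds(labels, k: int = 10, seed: int = 0, inner_val_fraction: float = 0.1,
               stratified: bool = True) -> CVPlan:
    """Assign each segment to one of ``k`` disjoint, exhaustive test folds.

    ``labels`` may be any per-segment label sequence (for joint
    stratification pass combined "quality|position" strings).  Strata
    smaller than ``k`` are handled best-effort by scikit-learn's
    stratified splitter (which warns).
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if not 2 <= k <= n:
        raise ConfigurationError(f"need 2 <= k <= n, got k={k}, n={n}")
    assignment = np.empty(n, dtype=int)
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        y = np.array([str(l) for l in labels])
        for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
            assignment[test_idx] = fold
    else:
        rng = np.random.default_rng(seed)
        assignment[...] = np.arange(n) % k
        rng.shuffle(assignment)
    return CVPlan(k=k, fold_assignment=assignment, inner_val_fraction=inner_val_fraction,
                  seed=seed, stratified=stratified)


@dataclass
class ClassMetrics:
    """Per-class confusion counts, precision/recall and weighted averages."""

    classes: tuple[str, ...]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    support: np.ndarray
    zero_prediction_classes: tuple[str, ...] = ()

    @property
    def precision(self) -> np.ndarray:
        denom = self.tp + self.fp
        return np.where(denom > 0, self.tp / np.maximum(denom, 1), 0.0)

    @property
    def recall(self) -> np.ndarray:
        denom = self.tp + self.fn
        return np.where(denom > 0, self.tp / np.maximum(denom, 1), 0.0)

    @property
    def weighted_precision(self) -> float:
        return float(np.average(self.precision, weights=self.support))

    @property
    def weighted_recall(self) -> float:
        return float(np.average(self.recall, weights=self.support))

    def per_class(self, label: str) -> dict:
        i = self.classes.index(label)
        return {
            "tp": int(self.tp[i]), "fp": int(self.fp[i]), "fn": int(self.fn[i]),
            "precision": float(self.precision[i]), "recall": float(self.recall[i]),
            "support": int(self.support[i]),
        }

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "class": list(self.classes),
            "precision": self.precision,
            "recall": self.recall,
            "support": self.support.astype(int),
        })
        df.loc[len(df)] = ["weighted avg", self.weighted_precision,
                           self.weighted_recall, int(self.support.sum())]
        return df

    @staticmethod
    def add(a: "ClassMetrics", b: "ClassMetrics") -> "ClassMetrics":
        if a.classes != b.classes:
            raise ConfigurationError("cannot pool metrics over different class sets")
        return ClassMetrics(
            classes=a.classes, tp=a.tp + b.tp, fp=a.fp + b.fp, fn=a.fn + b.fn,
            support=a.support + b.support,
            zero_prediction_classes=tuple(sorted(set(a.zero_prediction_classes)
                                                 | set(b.zero_prediction_classes))),
        )


def metrics_from_predictions(y_true, y_pred, classes) -> ClassMetrics:
    """Confusion counts and precision/recall from label sequences."""
    classes = tuple(classes)
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    tp = np.zeros(len(classes))
    fp = np.zeros(len(classes))
    fn = np.zeros(len(classes))
    support = np.zeros(len(classes))
    for i, c in enumerate(classes):
        is_true = y_true == c
        is_pred = y_pred == c
        tp[i] = np.sum(is_true & is_pred)
        fp[i] = np.sum(~is_true & is_pred)
        fn[i] = np.sum(is_true & ~is_pred)
        support[i] = np.sum(is_true)
    zero_pred = tuple(c for i, c in enumerate(classes) if tp[i] + fp[i] == 0)
    return ClassMetrics(classes=classes, tp=tp, fp=fp, fn=fn, support=support,
                        zero_prediction_classes=zero_pred)


def train_model(spec_or_model, X_train, y_train, X_val=None, y_val=None,
                config: TrainConfig | None = None,
                label_map=None) -> ConvNetResults:
    """Fit one classifier; thin functional wrapper over ``ConvNet1D.fit``."""
    if isinstance(spec_or_model, ConvNet1D):
        model = spec_or_model
    else:
        if label_map is None:
            label_map = tuple(sorted(set(y_train)))
        model = ConvNet1D(spec_or_model, label_map)
    return model.fit(X_train, y_train, X_val, y_val, config)


def evaluate(results: ConvNetResults, X_test, y_test) -> ClassMetrics:
    """Class-wise precision/recall of a fitted model on a test set."""
    if len(X_test) == 0:
        raise ConfigurationError("test set is empty")
    y_pred = results.predict(np.asarray(X_test, dtype=np.float32))
    return metrics_from_predictions(y_test, y_pred, results.label_map)


def inject_label_noise(labels, rate: float, classes, seed: int = 0) -> np.ndarray:
    """Replace a fraction ``rate`` of labels with a different random class."""
    labels = np.asarray(labels, dtype=object).copy()
    if rate == 0:
        return labels
    rng = np.random.default_rng(seed)
    n_flip = int(round(rate * labels.size))
    idx = rng.choice(labels.size, size=n_flip, replace=False)
    for i in idx:
        others = [c for c in classes if c != labels[i]]
        labels[i] = others[rng.integers(len(others))]
    return labels


@dataclass
class ExperimentReport:
    """Depth-sweep CV results for one task (and one or more segment lengths)."""

    task: str
    rows: list[dict] = field(default_factory=list)
    cells: dict[tuple[float, int], ClassMetrics] = field(default_factory=dict)
    config: TrainConfig | None = None
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def cell_score(self, seg_len_s: float, n_blocks: int) -> float:
        """Model-selection score: mean of weighted precision and recall."""
        m = self.cells[(seg_len_s, n_blocks)]
        return 0.5 * (m.weighted_precision + m.weighted_recall)

    def best_cell(self, seg_len_s: float | None = None) -> tuple[float, int]:
        keys = [k for k in self.cells if seg_len_s is None or k[0] == seg_len_s]
        return max(keys, key=lambda k: self.cell_score(*k))

    def summary(self) -> pd.DataFrame:
        df = self.to_dataframe()
        pivot = df[df["class"] == "weighted avg"][
            ["seg_len_s", "n_blocks", "precision", "recall"]
        ].reset_index(drop=True)
        return pivot

    def plot(self, ax=None):
        """Bar chart of class-wise precision/recall versus depth."""
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        df = df[df["class"] != "weighted avg"]
        seg_lens = sorted(df["seg_len_s"].unique())
        fig, axes = plt.subplots(len(seg_lens), 2, figsize=(10, 4 * len(seg_lens)),
                                 squeeze=False)
        for i, sl in enumerate(seg_lens):
            sub = df[df["seg_len_s"] == sl]
            for j, metric in enumerate(("precision", "recall")):
                piv = sub.pivot(index="n_blocks", columns="class", values=metric)
                piv.plot.bar(ax=axes[i][j], ylim=(0, 1.05))
                axes[i][j].set_title(f"{self.task} {metric}, {sl:g} s segments")
                axes[i][j].set_xlabel("number of Conv layers")
        fig.tight_layout()
        return fig


def task_arrays(dataset: SegmentDataset, task: str):
    if task == "quality":
        mask = np.array([q is not None for q in dataset.quality])
        labels = dataset.quality[mask]
        classes = QUALITY_LABELS
    elif task == "position":
        mask = np.array([q == "C1" and p is not None
                         for q, p in zip(dataset.quality, dataset.position)])
        labels = dataset.position[mask]
        classes = POSITION_LABELS
    else:
        raise ConfigurationError(f"unknown task {task!r}")
    if not mask.any():
        raise EmptyTaskError(f"no admissible segments for task {task!r}")
    return dataset.X[mask], labels, classes


def cross_validate(datasets, depth_grid=(3, 4, 5, 6, 7, 8), task: str = "quality",
                   config: TrainConfig | None = None, seed: int = 0,
                   k: int = 10, train_label_noise: float = 0.0,
                   restart_val_loss: float = 0.2, max_restarts: int = 2) -> ExperimentReport:
    """k-fold CV of every (depth, segment length) cell for one task.

    ``datasets`` is one SegmentDataset or a mapping seg_len_s -> dataset.
    Per cell, confusion counts are pooled over the k folds and class-wise
    precision/recall plus support-weighted averages are reported.

    ``train_label_noise`` corrupts that fraction of the *training* labels
    (uniformly to a different class, seeded); test and inner-validation
    labels stay clean, so the reported metrics measure robustness of the
    fit, not of the scoring.

    A fold whose best inner-validation loss stays above
    ``restart_val_loss`` is treated as an optimization stall (a bad
    initialization trapping the small network in a minimum that never
    separates the classes) and is retrained from a fresh seed, up to
    ``max_restarts`` times; the attempt with the lowest inner-validation
    loss is kept.  Label-noise runs raise the plateau bound accordingly,
    since noisy training labels inflate even a well-fitted model's loss.
    """
    if isinstance(datasets, SegmentDataset):
        datasets = {datasets.seg_len_s: datasets}
    config = config or TrainConfig()
    report = ExperimentReport(task=task, config=config, seed=seed)
    for seg_len_s, dataset in sorted(datasets.items()):
        X, labels, classes = task_arrays(dataset, task)
        plan = make_folds(labels, k=k, seed=seed)
        for n_blocks in depth_grid:
            spec = build_spec(n_blocks, X.shape[1], dataset.fs, n_classes=len(classes))
            pooled: ClassMetrics | None = None
            for fold in range(k):
                tr = plan.train_indices(fold)
                te = plan.test_indices(fold)
                n_val = max(len(classes), int(round(plan.inner_val_fraction * len(tr))))
                if n_val < len(tr) // 2:
                    try:
                        tr_in, tr_val = train_test_split(
                            tr, test_size=n_val, random_state=seed + fold,
                            stratify=[str(l) for l in labels[tr]],
                        )
                    except ValueError:  # stratum too small for the split
                        tr_in, tr_val = train_test_split(
                            tr, test_size=n_val, random_state=seed + fold)
                else:
                    tr_in, tr_val = tr, np.empty(0, dtype=int)
                y_tr = labels[tr_in]
                if train_label_noise > 0:
                    y_tr = inject_label_noise(y_tr, train_label_noise, classes,
                                              seed=seed + 7919 * fold)
                plateau_bound = restart_val_loss + 2.5 * train_label_noise
                best_results, best_val = None, np.inf
                for attempt in range(max_restarts + 1):
                    fold_config = TrainConfig(
                        optimizer=config.optimizer, learning_rate=config.learning_rate,
                        loss=config.loss, batch_size=config.batch_size,
                        max_epochs=config.max_epochs,
                        early_stop_patience=config.early_stop_patience,
                        seed=config.seed + 1000 * fold + n_blocks + 101 * attempt,
                    )
                    results = train_model(spec, X[tr_in], y_tr,
                                          X[tr_val], labels[tr_val],
                                          config=fold_config, label_map=classes)
                    val = min((h["val_loss"] for h in results.history
                               if "val_loss" in h), default=-np.inf)
                    if best_results is None or val < best_val:
                        best_results, best_val = results, val
                    if best_val <= plateau_bound:
                        break
                fold_metrics = evaluate(best_results, X[te], labels[te])
                pooled = fold_metrics if pooled is None else ClassMetrics.add(pooled, fold_metrics)
            report.cells[(seg_len_s, n_blocks)] = pooled
            for i, c in enumerate(classes):
                report.rows.append({
                    "task": task, "seg_len_s": seg_len_s, "n_blocks": n_blocks,
                    "class": c, "precision": float(pooled.precision[i]),
                    "recall": float(pooled.recall[i]), "support": int(pooled.support[i]),
                })
            report.rows.append({
                "task": task, "seg_len_s": seg_len_s, "n_blocks": n_blocks,
                "class": "weighted avg", "precision": pooled.weighted_precision,
                "recall": pooled.weighted_recall, "support": int(pooled.support.sum()),
            })
    return report
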