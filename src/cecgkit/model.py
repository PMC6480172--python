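"""Model / Results objects wrapping the CNN engine.

``ConvNet1D`` is the model: an architecture spec plus an ordered label
map.  ``fit`` trains with Adam on mini-batches of z-scored segments and
returns a ``ConvNetResults`` carrying the learned weights, the per-epoch
history and prediction methods; ``ConvNetResults.summary()`` renders a
short fit report.  Training minimizes categorical cross-entropy, holds
out nothing itself (callers pass an explicit validation split) and stops
early when the validation loss fails to improve for ``patience`` epochs,
restoring the best-validation weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .arch import ArchitectureSpec, build_network
from .errors import ConfigurationError, TrainingDivergenceError

__all__ = ["TrainConfig", "ConvNet1D", "ConvNetResults", "TrainedModel"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (the defaults are the package's own)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "categorical_crossentropy"
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ConfigurationError("batch_size must be >= 2 (batch norm needs >= 2)")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


class ConvNet1D:
    """A 1-D CNN classifier for fixed-length z-scored segments.

    Parameters
    ----------
    spec : ArchitectureSpec
        Structural description (depth, filter lengths, pooling plan, head).
    label_map : sequence of str
        Ordered class labels; network outputs follow this order.
    """

    def __init__(self, spec: ArchitectureSpec, label_map):
        label_map = tuple(label_map)
        if len(label_map) != spec.n_classes:
            raise ConfigurationError(
                f"label_map has {len(label_map)} labels, spec expects {spec.n_classes}"
            )
        self.spec = spec
        self.label_map = label_map

    def _encode(self, labels) -> np.ndarray:
        index = {lab: i for i, lab in enumerate(self.label_map)}
        try:
            idx = np.array([index[l] for l in labels], dtype=int)
        except KeyError as e:
            raise ConfigurationError(f"label {e.args[0]!r} not in label_map {self.label_map}")
        return idx

    def fit(self, X, y, X_val=None, y_val=None, config: TrainConfig | None = None) -> "ConvNetResults":
        """Train and return a results object.

        X : (n, input_len) z-scored segments; y : labels from label_map.
        When a validation split is given, early stopping watches its loss
        and the best-validation weights are restored.
        """
        config = config or TrainConfig()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.spec.input_len:
            raise ConfigurationError(
                f"X must be (n, {self.spec.input_len}), got {X.shape}"
            )
        yi = self._encode(y)
        if len(np.unique(yi)) < 2:
            raise ConfigurationError("training data must contain at least two classes")
        onehot = np.eye(self.spec.n_classes, dtype=np.float32)[yi]

        rng = np.random.default_rng(config.seed)
        net = build_network(self.spec, rng)
        opt = nn.Adam(net.params, lr=config.learning_rate)

        has_val = X_val is not None and len(X_val) > 0
        if has_val:
            X_val = np.asarray(X_val, dtype=np.float32)
            yv = self._encode(y_val)

        n = X.shape[0]
        Xb = X[:, :, None]
        history: list[dict] = []
        best_loss = np.inf
        best_weights = net.get_weights()
        best_epoch = 0
        since_best = 0
        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            ep_correct = 0
            ep_seen = 0
            for lo in range(0, n, config.batch_size):
                sel = order[lo : lo + config.batch_size]
                if sel.size < 2:
                    continue  # batch norm requires >= 2 samples
                loss, p = net.train_step(Xb[sel], onehot[sel])
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(
                        f"non-finite loss at epoch {epoch}", history=history
                    )
                opt.step(net.grads)
                ep_loss += loss * sel.size
                ep_correct += int((p.argmax(1) == yi[sel]).sum())
                ep_seen += sel.size
            entry = {
                "epoch": epoch,
                "loss": ep_loss / ep_seen,
                "accuracy": ep_correct / ep_seen,
            }
            if has_val:
                pv = net.predict_proba(X_val[:, :, None])
                val_loss = float(-np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12)))
                entry["val_loss"] = val_loss
                entry["val_accuracy"] = float((pv.argmax(1) == yv).mean())
                watch = val_loss
            else:
                watch = entry["loss"]
            history.append(entry)
            if watch < best_loss - 1e-6:
                best_loss = watch
                best_weights = net.get_weights()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break
        net.set_weights(best_weights)
        return ConvNetResults(model=self, network=net, config=config,
                              history=history, best_epoch=best_epoch)


@dataclass
class ConvNetResults:
    """Fit results: the trained network, its history and diagnostics."""

    model: ConvNet1D
    network: nn.Sequential
    config: TrainConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def spec(self) -> ArchitectureSpec:
        return self.model.spec

    @property
    def label_map(self):
        return self.model.label_map

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, rows summing to 1, columns per label_map."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.spec.input_len:
            raise ConfigurationError(f"X must be (n, {self.spec.input_len}), got {X.shape}")
        return self.network.predict_proba(X[:, :, None])

    def predict(self, X) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        return np.array([self.label_map[i] for i in idx], dtype=object)

    def summary(self) -> str:
        spec = self.spec
        hist = pd.DataFrame(self.history)
        lines = [
            "ConvNet1D fit results",
            "=" * 44,
            f"blocks:              {spec.n_blocks}",
            f"input length:        {spec.input_len} samples ({spec.input_len / spec.fs:.0f} s @ {spec.fs:.0f} Hz)",
            f"filter lengths:      {list(spec.filter_lengths)}",
            f"filters per layer:   {spec.filters_per_layer}",
            f"trainable params:    {spec.n_parameters()}",
            f"classes:             {list(self.label_map)}",
            f"epochs run:          {len(self.history)} (best: {self.best_epoch})",
            f"final train loss:    {hist['loss'].iloc[-1]:.4f}",
            f"final train acc:     {hist['accuracy'].iloc[-1]:.4f}",
        ]
        if "val_loss" in hist:
            lines.append(f"best val loss:       {hist['val_loss'].min():.4f}")
            lines.append(f"best val acc:        {hist['val_accuracy'].max():.4f}")
        return "\n".join(lines)

    def save(self, directory: str | Path) -> Path:
        """Persist spec JSON, label map and weights (text .npz-free: CSV of flats)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.spec.to_json(directory / "spec.json")
        (directory / "labels.json").write_text(json.dumps(list(self.label_map)))
        np.savez(directory / "weights.npz",
                 *[w for w in self.network.get_weights()])
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ConvNetResults":
        directory = Path(directory)
        spec = ArchitectureSpec.from_json(directory / "spec.json")
        labels = json.loads((directory / "labels.json").read_text())
        model = ConvNet1D(spec, labels)
        net = build_network(spec, np.random.default_rng(0))
        with np.load(directory / "weights.npz") as z:
            net.set_weights([z[k] for k in z.files])
        return cls(model=model, network=net, config=TrainConfig())


# Alias used in pipeline signatures: a fitted classifier ready for inference.
TrainedModel = ConvNetResults
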