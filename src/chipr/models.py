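"""The three interaction-strength regressors: DNN, random forest, gradient boosting.

All three map a feature row for an anchor pair to a predicted PET count.
The tree ensembles are scikit-learn regressors with pinned defaults; the
neural network is a compact numpy multilayer perceptron matching the fixed
architecture: three rectified hidden layers of 128 units, a rectified output
unit (so predictions are never negative), dropout 0.2, Adam at learning rate
1e-5, minibatches of 32, up to 750 epochs with early stopping after 50
epochs without improvement in validation mean squared error.
"""

from __future__ import annotations

import pickle
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from .features import FeatureSchema
from .io_formats import InteractionRecord

__all__ = [
    "DnnConfig",
    "TreeEnsembleConfig",
    "TrainedModel",
    "STRONG_THRESHOLD",
    "split_random",
    "split_by_chromosome_parity",
    "train",
    "predict",
    "is_strong",
    "save_model",
    "load_model",
]

STRONG_THRESHOLD = 3.0


@dataclass(frozen=True)
class DnnConfig:
    """Fixed hyper-parameters of the neural-network variant."""

    hidden_layers: int = 3
    units_per_layer: int = 128
    dropout_rate: float = 0.2
    batch_size: int = 32
    learning_rate: float = 1e-5
    max_epochs: int = 750
    early_stop_patience: int = 50
    validation_fraction: float = 0.10
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        for name in ("hidden_layers", "units_per_layer", "batch_size",
                     "learning_rate", "max_epochs", "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TreeEnsembleConfig:
    """Pinned defaults for the scikit-learn tree ensembles.

    rf: 100 bootstrap trees, unlimited depth, mean aggregation.
    gb: 100 stages, shrinkage 0.1, depth-3 trees, squared-error loss.
    """

    kind: str = "rf"
    n_estimators: int = 100
    learning_rate: float = 0.1  # gb shrinkage; ignored for rf
    max_depth: int | None = None  # rf: unlimited; gb uses 3

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "gb"):
            raise ValueError(f"unknown tree ensemble kind {self.kind!r}")
        if self.n_estimators <= 0:
            raise ValueError("tree count must be positive")


class _NumpyMlp:
    """Minimal MLP regressor: He init, inverted dropout, Adam, MSE loss."""

    def __init__(self, n_inputs: int, config: DnnConfig, rng: np.random.Generator):
        self.config = config
        sizes = [n_inputs] + [config.units_per_layer] * config.hidden_layers + [1]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        # Adam state
        self._m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._t = 0
        self.epochs_run = 0
        self.x_mean: np.ndarray | None = None
        self.x_std: np.ndarray | None = None

    def _forward(self, x, rng=None):
        """Forward pass; with rng, apply inverted dropout after hidden relus."""
        acts = [x]
        n = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ w + b
            a = np.maximum(z, 0.0)  # relu everywhere, including the output unit
            if rng is not None and i < n - 1 and self.config.dropout_rate > 0:
                keep = 1.0 - self.config.dropout_rate
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
            acts.append(a)
        return acts

    def _adam_step(self, grads):
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._t += 1
        params = self.weights + self.biases
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1**self._t)
            vhat = self._v[i] / (1 - b2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def _backward_step(self, xb, yb, rng):
        acts = self._forward(xb, rng=rng)
        pred = acts[-1][:, 0]
        n = len(xb)
        # d(MSE)/d(output pre-activation), relu output gate
        delta = (2.0 / n) * (pred - yb)[:, None] * (acts[-1] > 0)
        wgrads, bgrads = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            wgrads.append(acts[i].T @ delta)
            bgrads.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
        wgrads.reverse()
        bgrads.reverse()
        self._adam_step(wgrads + bgrads)
        return float(np.mean((pred - yb) ** 2))

    def fit(self, x: np.ndarray, y: np.ndarray, seed: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(seed)
        if cfg.standardize:
            self.x_mean = x.mean(axis=0)
            self.x_std = np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
            x = (x - self.x_mean) / self.x_std
        order = rng.permutation(len(x))
        x, y = x[order], y[order]
        n_val = max(1, int(round(cfg.validation_fraction * len(x))))
        x_tr, y_tr = x[:-n_val], y[:-n_val]
        x_val, y_val = x[-n_val:], y[-n_val:]

        best_val = np.inf
        best_params = None
        stale = 0
        for epoch in range(cfg.max_epochs):
            perm = rng.permutation(len(x_tr))
            for lo in range(0, len(x_tr), cfg.batch_size):
                idx = perm[lo : lo + cfg.batch_size]
                self._backward_step(x_tr[idx], y_tr[idx], rng)
            val_pred = self._forward(x_val)[-1][:, 0]
            val_mse = float(np.mean((val_pred - y_val) ** 2))
            self.epochs_run = epoch + 1
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_params = (
                    [w.copy() for w in self.weights],
                    [b.copy() for b in self.biases],
                )
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    break
        if best_params is not None:
            self.weights, self.biases = best_params

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.x_mean is not None:
            x = (x - self.x_mean) / self.x_std
        return self._forward(x)[-1][:, 0]


@dataclass
class TrainedModel:
    """A fitted regressor bound to a feature schema and its training metadata."""

    variant: str  # dnn | rf | gb
    schema: FeatureSchema
    estimator: object
    seed: int
    metadata: dict = field(default_factory=dict)


def split_random(
    interactions: list, train_fraction: float = 0.75, seed: int = 0
) -> tuple[list, list]:
    """Random disjoint train/test split; |train| = round(train_fraction * N)."""
    if len(interactions) < 4:
        raise ValueError("need at least 4 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(interactions))
    n_train = int(round(train_fraction * len(interactions)))
    train_idx = set(order[:n_train].tolist())
    train = [interactions[i] for i in sorted(train_idx)]
    test = [interactions[i] for i in range(len(interactions)) if i not in train_idx]
    return train, test


_CHROM_NUM = re.compile(r"^chr(\d+)$", re.IGNORECASE)


def split_by_chromosome_parity(
    interactions: list[InteractionRecord],
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Partition records into odd- and even-numbered autosomes.

    chrX/chrY/chrM and other non-numeric names are excluded (counted in a
    module-level log line). Used for the train-odd / test-even protocol.
    """
    odd, even, skipped = [], [], 0
    for rec in interactions:
        m = _CHROM_NUM.match(rec.chrom)
        if m is None:
            skipped += 1
            continue
        (odd if int(m.group(1)) % 2 else even).append(rec)
    if skipped:
        import logging

        logging.getLogger(__name__).info(
            "excluded %d non-autosomal record(s) from parity split", skipped
        )
    return odd, even


def _as_array(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def train(
    variant: str,
    features,
    targets,
    schema: FeatureSchema = FeatureSchema("full"),
    config: DnnConfig | TreeEnsembleConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one regressor variant on a feature matrix and PET-count targets."""
    x = _as_array(features)
    y = np.asarray(targets, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 training rows")
    if not np.isfinite(x).all():
        bad = np.where(~np.isfinite(x).all(axis=1))[0]
        raise ValueError(f"non-finite feature values in rows {bad.tolist()[:20]}")
    if (y < 0).any():
        raise ValueError("targets must be non-negative PET counts")
    if isinstance(features, pd.DataFrame) and tuple(features.columns) != schema.columns:
        raise ValueError(
            f"feature columns {list(features.columns)} do not match schema "
            f"{list(schema.columns)}"
        )

    meta: dict = {"n_rows": len(x), "seed": seed}
    if variant == "rf":
        cfg = config or TreeEnsembleConfig(kind="rf")
        est = RandomForestRegressor(
            n_estimators=cfg.n_estimators,
            max_depth=cfg.max_depth,
            bootstrap=True,
            random_state=seed,
        )
        est.fit(x, y)
    elif variant == "gb":
        cfg = config or TreeEnsembleConfig(kind="gb")
        est = GradientBoostingRegressor(
            n_estimators=cfg.n_estimators,
            learning_rate=cfg.learning_rate,
            max_depth=3,
            loss="squared_error",
            random_state=seed,
        )
        est.fit(x, y)
    elif variant == "dnn":
        cfg = config or DnnConfig()
        est = _NumpyMlp(x.shape[1], cfg, np.random.default_rng(seed))
        est.fit(x, y, seed=seed)
        meta["epochs_run"] = est.epochs_run
    else:
        raise ValueError(f"unknown variant {variant!r} (expected dnn|rf|gb)")
    return TrainedModel(variant=variant, schema=schema, estimator=est,
                        seed=seed, metadata=meta)


def predict(model: TrainedModel, features) -> np.ndarray:
    """Predicted interaction strengths; always finite and >= 0.

    A DataFrame input is checked against the model's schema columns; the
    tree models' outputs are clipped at zero (the network's output unit is
    rectified already).
    """
    if isinstance(features, pd.DataFrame):
        got, want = tuple(features.columns), model.schema.columns
        if got != want:
            missing = [c for c in want if c not in got]
            extra = [c for c in got if c not in want]
            raise ValueError(
                f"feature columns do not match model schema "
                f"(missing={missing}, extra={extra})"
            )
    x = _as_array(features)
    pred = np.asarray(model.estimator.predict(x), dtype=float)
    return np.clip(pred, 0.0, None)


def is_strong(strength: float, threshold: float = STRONG_THRESHOLD) -> bool:
    """Whether an interaction counts as strong (PET count >= 3 by default)."""
    return strength >= threshold


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize a trained model (schema, config, seed, fitted state) to one file."""
    payload = {
        "variant": model.variant,
        "schema_mode": model.schema.mode,
        "seed": model.seed,
        "metadata": model.metadata,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return TrainedModel(
        variant=payload["variant"],
        schema=FeatureSchema(payload["schema_mode"]),
        estimator=payload["estimator"],
        seed=payload["seed"],
        metadata=payload["metadata"],
    )
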