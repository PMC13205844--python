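"""Coordinate-regression landmark network as a scikit-learn estimator.

The architecture is four progressive convolutional blocks (Conv2D 3x3,
valid padding, stride 1, followed by 2x2 max pooling) with filter depths
32 -> 64 -> 128 -> 256, then Flatten, Dense(512, ReLU), Dropout(0.5) and
a sigmoid output of 44 (frontal) or 30 (profile) normalized coordinates.
With valid padding the spatial trace from 128 is
126 -> 63 -> 61 -> 30 -> 28 -> 14 -> 12 -> 6, so the flattened width is
6*6*256 = 9216.  Training minimizes mean squared error on normalized
coordinates with Adam (default learning rate 1e-4, batch size 16, up to
50 epochs) and early stopping on validation loss (patience 10, restoring
the best weights).  Inference is deterministic: dropout is inactive and
repeated predictions on a fixed input are bit-identical.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .pipeline import (
    INPUT_SIZE,
    PreprocessedSample,
    denormalize_landmarks,
    resize_normalize,
    samples_to_arrays,
)
from .schemas import (
    AnnotatedImage,
    LandmarkSchema,
    PointAnnotation,
    get_schema,
    points_from_array,
)


@dataclass(frozen=True)
class ModelSpec:
    """Static architecture description."""

    input_shape: tuple[int, int, int] = (INPUT_SIZE, INPUT_SIZE, 3)
    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    kernel: tuple[int, int] = (3, 3)
    stride: tuple[int, int] = (1, 1)
    padding: str = "valid"
    dense_units: int = 512
    dropout_rate: float = 0.5
    output_units: int = 44
    hidden_activation: str = "relu"
    output_activation: str = "sigmoid"

    def spatial_trace(self) -> list[int]:
        """Spatial side length after each conv and pool layer."""
        s = self.input_shape[0]
        trace = []
        for _ in self.conv_filters:
            s = s - (self.kernel[0] - 1)  # valid conv
            trace.append(s)
            s = s // 2                    # 2x2 pool
            trace.append(s)
        return trace

    def flatten_width(self) -> int:
        side = self.spatial_trace()[-1]
        return side * side * self.conv_filters[-1]


def spec_for_schema(schema: LandmarkSchema, **overrides) -> ModelSpec:
    return ModelSpec(output_units=schema.n_outputs, **overrides)


def count_parameters(spec: ModelSpec) -> int:
    """Layer-by-layer parameter count.

    conv: (kh*kw*c_in + 1) * c_out; dense: (n_in + 1) * n_out.
    """
    kh, kw = spec.kernel
    total = 0
    c_in = spec.input_shape[2]
    for c_out in spec.conv_filters:
        total += (kh * kw * c_in + 1) * c_out
        c_in = c_out
    total += (spec.flatten_width() + 1) * spec.dense_units
    total += (spec.dense_units + 1) * spec.output_units
    return total


def build_network(spec: ModelSpec, init_rng: np.random.Generator,
                  dropout_rng: np.random.Generator) -> nn.Network:
    """Instantiate the network with Glorot-uniform initial weights."""
    layers: list[nn.Layer] = []
    c_in = spec.input_shape[2]
    for c_out in spec.conv_filters:
        layers.append(nn.Conv2D(c_in, c_out, init_rng, kernel=spec.kernel[0]))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2D())
        c_in = c_out
    layers.append(nn.Flatten())
    layers.append(nn.Dense(spec.flatten_width(), spec.dense_units, init_rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(spec.dropout_rate, dropout_rng))
    layers.append(nn.Dense(spec.dense_units, spec.output_units, init_rng))
    layers.append(nn.Sigmoid())
    return nn.Network(layers)


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the reference protocol)."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 10
    early_stopping: bool = True
    data_seed: int = 42
    init_seed: int = 42

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be > 0")
        if self.early_stopping and self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


class LandmarkCNN(RegressorMixin, BaseEstimator):
    """Coordinate-regression CNN for facial soft-tissue landmarks.

    Parameters mirror :class:`TrainConfig` plus the view, which fixes the
    output width (44 coordinates frontal, 30 profile).

    Fitted attributes
    -----------------
    network_ : the trained layer stack
    spec_ : ModelSpec actually built
    history_ : dict with per-epoch ``train_loss`` and ``val_loss`` lists
    best_epoch_ : epoch index (0-based) whose weights were restored
    n_outputs_ : length of the output coordinate vector
    """

    def __init__(self, view: str = "frontal", learning_rate: float = 1e-4,
                 batch_size: int = 16, max_epochs: int = 50,
                 patience: int = 10, early_stopping: bool = True,
                 data_seed: int = 42, init_seed: int = 42,
                 conv_filters: tuple[int, ...] = (32, 64, 128, 256),
                 dense_units: int = 512, dropout_rate: float = 0.5,
                 verbose: int = 0):
        self.view = view
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.early_stopping = early_stopping
        self.data_seed = data_seed
        self.init_seed = init_seed
        self.conv_filters = conv_filters
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.verbose = verbose

    # -- internals ---------------------------------------------------------

    def _make_spec(self) -> ModelSpec:
        schema = get_schema(self.view)
        return ModelSpec(conv_filters=tuple(self.conv_filters),
                         dense_units=self.dense_units,
                         dropout_rate=self.dropout_rate,
                         output_units=schema.n_outputs)

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        expect = self._make_spec().input_shape
        if X.ndim != 4 or X.shape[1:] != expect:
            raise ValueError(f"X must have shape (n, {expect[0]}, {expect[1]},"
                             f" {expect[2]}); got {X.shape}")
        return X

    # -- estimator API -----------------------------------------------------

    def initialize(self) -> "LandmarkCNN":
        """Build the network with fresh Glorot-uniform weights (untrained)."""
        spec = self._make_spec()
        init_rng = np.random.default_rng(self.init_seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.data_seed, spawn_key=(1,)))
        self.network_ = build_network(spec, init_rng, self._dropout_rng)
        self.spec_ = spec
        self.n_outputs_ = spec.output_units
        self.history_ = {"train_loss": [], "val_loss": []}
        self.best_epoch_ = None
        return self

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on normalized samples; early-stop on validation loss.

        X : (n, 128, 128, 3) float in [0, 1]; y : (n, 2L) in [0, 1].
        Validation arrays are optional; without them early stopping
        monitors training loss.
        """
        X = self._validate_X(X)
        y = np.asarray(y, dtype=np.float32)
        if len(X) == 0:
            raise ValueError("training set is empty")
        schema = get_schema(self.view)
        if y.shape != (len(X), schema.n_outputs):
            raise ValueError(f"y must have shape ({len(X)}, {schema.n_outputs});"
                             f" got {y.shape}")
        has_val = X_val is not None and y_val is not None
        if has_val:
            X_val = self._validate_X(X_val)
            y_val = np.asarray(y_val, dtype=np.float32)

        self.initialize()
        net = self.network_
        opt = nn.Adam(net.params, lr=self.learning_rate)
        shuffle_rng = np.random.default_rng(self.data_seed)

        best_loss = np.inf
        best_weights = None
        best_epoch = 0
        wait = 0
        for epoch in range(self.max_epochs):
            order = shuffle_rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), self.batch_size):
                idx = order[start:start + self.batch_size]
                losses.append(net.train_step(X[idx], y[idx]))
                opt.step(net.grads)
            train_loss = float(np.mean(losses))
            monitor = (net.evaluate_loss(X_val, y_val) if has_val
                       else train_loss)
            self.history_["train_loss"].append(train_loss)
            self.history_["val_loss"].append(monitor if has_val else np.nan)
            if self.verbose:
                print(f"epoch {epoch + 1:3d}  train {train_loss:.6f}"
                      + (f"  val {monitor:.6f}" if has_val else ""))
            if monitor < best_loss:
                best_loss = monitor
                best_weights = net.get_weights()
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if self.early_stopping and wait >= self.patience:
                    break
        if best_weights is not None:
            net.set_weights(best_weights)
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_loss
        return self

    def predict(self, X, batch_size: int = 32) -> np.ndarray:
        """Normalized coordinate predictions, each strictly in (0, 1)."""
        if not hasattr(self, "network_"):
            raise RuntimeError("model is not fitted; call fit() or initialize()")
        X = self._validate_X(X)
        out = [self.network_.forward(X[i:i + batch_size], training=False)
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out, axis=0)

    def predict_image(self, img: AnnotatedImage) -> list[PointAnnotation]:
        """Predict landmarks for one image, in original pixel coordinates."""
        if img.view != self.view:
            raise ValueError(f"image view {img.view!r} does not match model "
                             f"view {self.view!r}")
        sample = resize_normalize(img)
        vec = self.predict(sample.input_array[None])[0]
        coords = denormalize_landmarks(vec, img.width, img.height)
        return points_from_array(coords, get_schema(self.view))

    def predict_samples(self, samples: list[PreprocessedSample]
                        ) -> list[np.ndarray]:
        """Predict original-resolution (L, 2) coordinates per sample."""
        X, _ = samples_to_arrays(samples)
        vecs = self.predict(X)
        return [denormalize_landmarks(v, s.width, s.height)
                for v, s in zip(vecs, samples)]

    # -- persistence -------------------------------------------------------

    def save(self, model_dir: str | os.PathLike) -> None:
        os.makedirs(model_dir, exist_ok=True)
        np.savez(os.path.join(model_dir, "weights.npz"),
                 *(p for p in self.network_.params))
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(self.spec_).items()},
            "best_epoch": self.best_epoch_,
        }
        with open(os.path.join(model_dir, "meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        with open(os.path.join(model_dir, "history.csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss"])
            for i, (tr, va) in enumerate(zip(self.history_["train_loss"],
                                             self.history_["val_loss"]), 1):
                writer.writerow([i, f"{tr:.8f}", f"{va:.8f}"])

    @classmethod
    def load(cls, model_dir: str | os.PathLike) -> "LandmarkCNN":
        with open(os.path.join(model_dir, "meta.json")) as fh:
            meta = json.load(fh)
        params = dict(meta["params"])
        for key in ("conv_filters",):
            if key in params:
                params[key] = tuple(params[key])
        est = cls(**params)
        est.initialize()
        with np.load(os.path.join(model_dir, "weights.npz")) as data:
            weights = [data[k] for k in sorted(data.files,
                                               key=lambda s: int(s.split("_")[1]))]
        est.network_.set_weights(weights)
        est.best_epoch_ = meta.get("best_epoch")
        return est


def train_model(train_samples: list[PreprocessedSample],
                val_samples: list[PreprocessedSample] | None,
                view: str, cfg: TrainConfig | None = None,
                verbose: int = 0) -> LandmarkCNN:
    """Fit a LandmarkCNN from preprocessed samples (functional front-end)."""
    cfg = cfg or TrainConfig()
    if not train_samples:
        raise ValueError("training set is empty")
    est = LandmarkCNN(view=view, learning_rate=cfg.learning_rate,
                      batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
                      patience=cfg.patience, early_stopping=cfg.early_stopping,
                      data_seed=cfg.data_seed, init_seed=cfg.init_seed,
                      verbose=verbose)
    X, y = samples_to_arrays(train_samples)
    if val_samples:
        X_val, y_val = samples_to_arrays(val_samples)
        return est.fit(X, y, X_val, y_val)
    return est.fit(X, y)
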