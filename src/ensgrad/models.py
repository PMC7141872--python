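"""The six enrichment-predictor architectures and their training loop.

Five architectures are small convolutional networks over the 20x20 one-hot
input; the sixth is a two-layer dense network.  Every convolution is
length-preserving ('same', stride 1) and is followed by window-2 stride-2
max-pooling, except the width-1 embedding layer of ``Seq_embed_32x1_16``
which feeds its 8-channel per-residue embedding straight into the width-5
layer.  The hidden dense layer(s) carry dropout; the default head has two
units, a real-valued enrichment regression output and a sign-classification
logit.  Under these conventions the trainable-parameter totals of the six
models are 13954, 8402, 18706, 16754, 7122 and 13082.

Training minimizes an equally weighted sum of squared error on enrichment
and logistic loss on its sign, with Adam, a validation split and
patience-based early stopping.  All randomness is seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from ensgrad import nn
from ensgrad.sequences import ALPHABET, MAX_POSITIONS, encode_batch


@dataclass(frozen=True)
class ConvLayerSpec:
    width: int
    n_filters: int
    pool_after: bool = True

    def __post_init__(self) -> None:
        if self.width not in (1, 3, 5):
            raise ValueError(f"conv width must be 1, 3 or 5, got {self.width}")


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    conv_layers: tuple[ConvLayerSpec, ...]
    dense_units: tuple[int, ...]
    n_outputs: int = 2
    dropout_rate: float = 0.2


#: The canonical six architectures, keyed by name.
ARCHITECTURES: dict[str, ArchitectureSpec] = {
    "Seq_32_32": ArchitectureSpec("Seq_32_32", (), (32, 32)),
    "Seq_32x1_16": ArchitectureSpec("Seq_32x1_16", (ConvLayerSpec(5, 32),), (16,)),
    "Seq_32x2_16": ArchitectureSpec(
        "Seq_32x2_16", (ConvLayerSpec(5, 32), ConvLayerSpec(5, 64)), (16,)
    ),
    "Seq_64x1_16": ArchitectureSpec("Seq_64x1_16", (ConvLayerSpec(5, 64),), (16,)),
    "Seq_32x1_16_filt3": ArchitectureSpec(
        "Seq_32x1_16_filt3", (ConvLayerSpec(3, 32),), (16,)
    ),
    # Width-1 embedding to 8 channels (no pooling there), then width-5 x 64.
    "Seq_embed_32x1_16": ArchitectureSpec(
        "Seq_embed_32x1_16",
        (ConvLayerSpec(1, 8, pool_after=False), ConvLayerSpec(5, 64)),
        (16,),
    ),
}


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    regression_weight: float = 1.0
    classification_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedModel:
    """An architecture instance with its weights and training metadata."""

    spec: ArchitectureSpec
    network: nn.Network
    metadata: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray | Sequence[str]) -> np.ndarray:
        """Deterministic forward pass; (n, n_outputs) array.

        Accepts either a batch of one-hot/relaxed matrices
        (n, 20, 20) or a sequence of strings (encoded on the fly).
        A single (20, 20) matrix is treated as a batch of one.
        """
        if not isinstance(x, np.ndarray):
            x = encode_batch(list(x))
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (MAX_POSITIONS, len(ALPHABET)):
            raise ValueError(f"expected (*, {MAX_POSITIONS}, {len(ALPHABET)}) input, got {x.shape}")
        return self.network.forward(x, training=False)

    def predict_enrichment(self, x) -> np.ndarray:
        """Regression output only (first head unit)."""
        return self.predict(x)[:, 0]

    def input_gradient(self, x: np.ndarray, output_index: int = 0) -> np.ndarray:
        if x.ndim == 2:
            return self.network.input_gradient(x[None], output_index)[0]
        return self.network.input_gradient(x, output_index)

    def n_parameters(self) -> int:
        return self.network.n_parameters()

    def save(self, path: str | Path) -> None:
        """Single-file .npz checkpoint: spec + metadata + weights."""
        header = {
            "spec": {
                "name": self.spec.name,
                "conv_layers": [
                    [c.width, c.n_filters, c.pool_after] for c in self.spec.conv_layers
                ],
                "dense_units": list(self.spec.dense_units),
                "n_outputs": self.spec.n_outputs,
                "dropout_rate": self.spec.dropout_rate,
            },
            "metadata": self.metadata,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.network.get_weights())}
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        header = json.loads(str(data["header"]))
        s = header["spec"]
        spec = ArchitectureSpec(
            name=s["name"],
            conv_layers=tuple(ConvLayerSpec(*c) for c in s["conv_layers"]),
            dense_units=tuple(s["dense_units"]),
            n_outputs=s["n_outputs"],
            dropout_rate=s["dropout_rate"],
        )
        model = build_from_spec(spec, seed=0)
        weights = [data[f"w{i}"] for i in range(len(model.network.params()))]
        model.network.set_weights(weights)
        model.metadata = header["metadata"]
        return model


def build_from_spec(spec: ArchitectureSpec, seed: int = 0) -> TrainedModel:
    """Instantiate a network from an explicit architecture spec."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    length, channels = MAX_POSITIONS, len(ALPHABET)
    for conv in spec.conv_layers:
        layers.append(nn.Conv1D(channels, conv.n_filters, conv.width, rng))
        layers.append(nn.ReLU())
        channels = conv.n_filters
        if conv.pool_after:
            layers.append(nn.MaxPool1D(2))
            length //= 2
    layers.append(nn.Flatten())
    features = length * channels
    for units in spec.dense_units:
        layers.append(nn.Dense(features, units, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout_rate, rng))
        features = units
    layers.append(nn.Dense(features, spec.n_outputs, rng))
    return TrainedModel(spec=spec, network=nn.Network(layers), metadata={"init_seed": seed})


def build_architecture(name: str, seed: int = 0) -> TrainedModel:
    """Build one of the six named architectures (untrained)."""
    if name not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {name!r}; valid names: {sorted(ARCHITECTURES)}"
        )
    return build_from_spec(ARCHITECTURES[name], seed=seed)


def build_multioutput(name: str, n_targets: int, seed: int = 0) -> TrainedModel:
    """Same trunk as ``build_architecture`` with one regression unit per target."""
    if n_targets < 2:
        raise ValueError(f"n_targets must be >= 2, got {n_targets}")
    if name not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {name!r}; valid names: {sorted(ARCHITECTURES)}"
        )
    spec = replace(ARCHITECTURES[name], n_outputs=n_targets)
    return build_from_spec(spec, seed=seed)


def count_parameters(model: TrainedModel) -> int:
    """Exact count of trainable scalars, biases included."""
    return model.n_parameters()


def _loss_and_grad(
    out: np.ndarray,
    y_reg: np.ndarray,
    y_label: np.ndarray | None,
    cfg: TrainingConfig,
) -> tuple[float, np.ndarray]:
    """Weighted squared-error + logistic loss and d(loss)/d(out).

    ``y_reg`` may be (n,) for the dual-head model or (n, T) for the
    multi-output model; NaN entries are masked out of the loss.
    """
    n = out.shape[0]
    dy = np.zeros_like(out)
    if y_reg.ndim == 1:
        resid = out[:, 0] - y_reg
        loss = cfg.regression_weight * float(np.mean(resid**2))
        dy[:, 0] = cfg.regression_weight * 2.0 * resid / n
        if y_label is not None:
            logit = out[:, 1]
            lab = y_label.astype(np.float64)
            # stable log(1 + exp(-|z|)) formulation
            bce = np.mean(np.maximum(logit, 0) - logit * lab + np.log1p(np.exp(-np.abs(logit))))
            loss += cfg.classification_weight * float(bce)
            p = 1.0 / (1.0 + np.exp(-logit))
            dy[:, 1] = cfg.classification_weight * (p - lab) / n
    else:
        mask = ~np.isnan(y_reg)
        n_valid = max(int(mask.sum()), 1)
        resid = np.where(mask, out - np.nan_to_num(y_reg), 0.0)
        loss = cfg.regression_weight * float((resid**2).sum() / n_valid)
        dy[...] = cfg.regression_weight * 2.0 * resid / n_valid
    return loss, dy


def train_model(
    model: TrainedModel,
    x: np.ndarray | Sequence[str],
    y_reg: np.ndarray,
    y_label: np.ndarray | None = None,
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainedModel:
    """Fit a model in place on (input, enrichment[, sign label]) data.

    A ``val_fraction`` split monitors the loss; training stops when it
    fails to improve for ``patience`` epochs and the best weights are
    restored.  Deterministic given ``cfg.seed``.  Returns the model with
    training metadata recorded.
    """
    if not isinstance(x, np.ndarray):
        x = encode_batch(list(x))
    y_reg = np.asarray(y_reg, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("empty training set")
    if y_label is not None:
        y_label = np.asarray(y_label)

    rng = np.random.default_rng(cfg.seed)
    for layer in model.network.layers:
        if isinstance(layer, nn.Dropout):
            layer.rng = rng

    n = len(x)
    n_val = int(round(n * cfg.val_fraction))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = perm, perm[:0]

    opt = nn.Adam(model.network.params(), lr=cfg.learning_rate)
    best_val = np.inf
    best_weights = model.network.get_weights()
    epochs_since_best = 0
    history: list[float] = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            out = model.network.forward(x[idx], training=True)
            loss, dy = _loss_and_grad(
                out, y_reg[idx], None if y_label is None else y_label[idx], cfg
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(architecture {model.spec.name})"
                )
            model.network.backward(dy)
            opt.step(model.network.grads())

        monitor_idx = val_idx if len(val_idx) else train_idx
        out = model.network.forward(x[monitor_idx], training=False)
        val_loss, _ = _loss_and_grad(
            out, y_reg[monitor_idx], None if y_label is None else y_label[monitor_idx], cfg
        )
        history.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.network.get_weights()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                break

    model.network.set_weights(best_weights)
    model.metadata.update(
        {
            "train_seed": cfg.seed,
            "n_train": int(len(train_idx)),
            "n_val": int(len(val_idx)),
            "epochs_run": len(history),
            "best_val_loss": float(best_val),
        }
    )
    return model
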