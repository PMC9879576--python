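"""Architecture grammars for the two secondary networks.

Two families classify sub-sequences as biting / not biting:

* ``lstm`` — stacked [LSTM + batch norm] blocks over the (n_obs, D)
  feature sequence, dropout after the last block, 2-unit softmax head.
  The total node budget comes from one of three rules of the input
  width D (with 2 the number of outputs): ``mean`` = round((D+2)/2),
  ``half_mean`` = round((D+2)/4), ``sum`` = D+2; with several layers
  the budget is divided equally over the layers (ceil, minimum 1).
* ``cnn`` — the (n_obs, D) sequence viewed as a 1-channel image, passed
  through stacked [3x3 conv + batch norm] blocks whose filter count
  doubles per layer (F, 2F, 4F), dropout, flatten, softmax head.

Both train with Adam (lr 0.001), batch size 16, categorical
cross-entropy and 10-epoch-patience early stopping on an unbalanced
validation pen; the training set is class-balanced by randomly
undersampling negatives first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from pentail import nn
from pentail.errors import BalanceError, ConfigurationError
from pentail.sequences import SequenceSet

NODE_RULES = ("mean", "half_mean", "sum")
FIRST_FILTER_CHOICES = (8, 16, 32, 64)


@dataclass(frozen=True)
class ModelSpec:
    """One point of the hyperparameter grid.

    ``n_pc is None`` selects the no-PCA baseline; the actual input
    width is then data-dependent and passed to :func:`build_model`.
    """

    family: str                    # "lstm" | "cnn"
    n_obs: int
    n_pc: int | None
    n_layers: int
    node_rule: str | None = None   # lstm only
    first_filters: int | None = None  # cnn only
    dropout: float = 0.0
    batch_size: int = 16
    learning_rate: float = 0.001
    patience: int = 10

    def __post_init__(self) -> None:
        if self.family not in ("lstm", "cnn"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.n_layers not in (1, 2, 3):
            raise ConfigurationError("n_layers must be 1, 2 or 3")
        if self.n_obs < 1 or (self.n_pc is not None and self.n_pc < 1):
            raise ConfigurationError("n_obs and n_pc must be positive")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.family == "lstm":
            if self.node_rule not in NODE_RULES or self.first_filters is not None:
                raise ConfigurationError(
                    "lstm specs take node_rule (mean|half_mean|sum), not first_filters"
                )
        else:
            if self.first_filters not in FIRST_FILTER_CHOICES or self.node_rule is not None:
                raise ConfigurationError(
                    "cnn specs take first_filters in {8,16,32,64}, not node_rule"
                )

    def key(self) -> str:
        """Stable string identity for seeding and restartable grids."""
        width = self.node_rule if self.family == "lstm" else self.first_filters
        return (
            f"{self.family}|n_obs={self.n_obs}|n_pc={self.n_pc}"
            f"|layers={self.n_layers}|width={width}|dropout={self.dropout}"
        )


def node_count(rule: str, input_width: int) -> int:
    """Total LSTM node budget from the rule and the input width.

    Half-integer values round half-to-even (Python ``round``).
    """
    if input_width < 1:
        raise ValueError("input_width must be >= 1")
    if rule == "mean":
        n = round((input_width + 2) / 2)
    elif rule == "half_mean":
        n = round((input_width + 2) / 4)
    elif rule == "sum":
        n = input_width + 2
    else:
        raise ValueError(f"unknown node rule {rule!r}")
    return max(1, int(n))


def units_per_layer(total_nodes: int, n_layers: int) -> int:
    """Equal split of the node budget over layers (ceil, minimum 1)."""
    return max(1, math.ceil(total_nodes / n_layers))


def build_model(spec: ModelSpec, input_dim: int | None = None, seed: int = 0) -> nn.Sequential:
    """Instantiate an untrained network for one grid point.

    ``input_dim`` defaults to ``spec.n_pc`` and must be given explicitly
    for the no-PCA baseline.  Identical (spec, input_dim, seed) yield
    bit-identical initial weights.
    """
    width = spec.n_pc if input_dim is None else input_dim
    if width is None:
        raise ConfigurationError("input_dim required when n_pc is None")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    if spec.family == "lstm":
        units = units_per_layer(node_count(spec.node_rule, width), spec.n_layers)
        d = width
        for layer_i in range(spec.n_layers):
            last = layer_i == spec.n_layers - 1
            layers.append(nn.LSTM(d, units, rng, return_sequences=not last))
            layers.append(nn.BatchNorm(units))
            d = units
        layers.append(nn.Dropout(spec.dropout, rng))
        layers.append(nn.Dense(units, 2, rng))
    else:
        c = 1
        filters = spec.first_filters
        for layer_i in range(spec.n_layers):
            layers.append(nn.Conv2D(c, filters, rng))
            layers.append(nn.BatchNorm(filters))
            c = filters
            filters *= 2
        layers.append(nn.Dropout(spec.dropout, rng))
        layers.append(nn.Flatten())
        layers.append(nn.Dense(spec.n_obs * width * c, 2, rng))
    return nn.Sequential(layers)


def parameter_count(spec: ModelSpec, input_dim: int | None = None) -> int:
    """Trainable-parameter count of :func:`build_model` without building it.

    LSTM layer: 4u(d + u + 1); batch norm: 2 channels; 3x3 conv:
    9*c_in*c_out + c_out; dense head: (d_in + 1) * 2.
    """
    width = spec.n_pc if input_dim is None else input_dim
    if width is None:
        raise ConfigurationError("input_dim required when n_pc is None")
    total = 0
    if spec.family == "lstm":
        u = units_per_layer(node_count(spec.node_rule, width), spec.n_layers)
        d = width
        for _ in range(spec.n_layers):
            total += 4 * u * (d + u + 1) + 2 * u
            d = u
        total += (u + 1) * 2
    else:
        c = 1
        f = spec.first_filters
        for _ in range(spec.n_layers):
            total += 9 * c * f + f + 2 * f
            c, f = f, 2 * f
        total += (spec.n_obs * width * c + 1) * 2
    return total


def balance_undersample(train: SequenceSet, seed: int) -> SequenceSet:
    """Balance classes 1:1 by random undersampling of negatives.

    All positives are retained; negatives are sampled uniformly without
    replacement down to the positive count.  Order of the output is the
    original order of the selected sequences.
    """
    labels = np.asarray(train.labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) == 0:
        raise BalanceError("training set has no positive sequences")
    rng = np.random.default_rng(seed)
    if len(neg_idx) > len(pos_idx):
        neg_idx = rng.choice(neg_idx, size=len(pos_idx), replace=False)
    keep = np.sort(np.concatenate([pos_idx, neg_idx]))
    return train.subset(keep)


def _as_input(x: np.ndarray, family: str) -> np.ndarray:
    """(n, T, D) float64 for lstm; add the channel axis for cnn."""
    x = np.asarray(x, dtype=np.float64)
    return x[..., None] if family == "cnn" else x


def train(
    model: nn.Sequential,
    train_set: SequenceSet,
    val_set: SequenceSet,
    spec: ModelSpec,
    seed: int,
    max_epochs: int = 200,
) -> tuple[nn.Sequential, nn.TrainLog]:
    """Train a built model on balanced sequences with early stopping.

    The validation set must be pen-disjoint from the training set and is
    not balanced.  Returns the model with best-epoch weights restored.
    """
    if len(val_set) == 0:
        raise ValueError("validation set must be non-empty")
    overlap = set(train_set.pens) & set(val_set.pens)
    if overlap:
        raise ValueError(f"validation pens overlap training pens: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    log = nn.fit(
        model,
        _as_input(train_set.x, spec.family),
        train_set.labels,
        _as_input(val_set.x, spec.family),
        val_set.labels,
        rng,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        patience=spec.patience,
        max_epochs=max_epochs,
    )
    return model, log


def predict_proba(model: nn.Sequential, sequences: SequenceSet | np.ndarray,
                  family: str) -> np.ndarray:
    """Softmax probability of the biting class, one value per sequence."""
    x = sequences.x if isinstance(sequences, SequenceSet) else sequences
    x = _as_input(x, family)
    probs = []
    for s in range(0, len(x), 256):
        logits = model.forward(x[s : s + 256], training=False)
        probs.append(nn.softmax(logits)[:, 1])
    return np.concatenate(probs) if probs else np.empty(0)
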