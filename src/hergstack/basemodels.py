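"""The five base architectures of the individual prediction stage.

Each base model consumes one molecular representation and emits a single
probability of hERG blockade:

* ``FCNND``      — fully connected net on normalized descriptors;
* ``GCNN``       — graph convolutional net on node matrix + adjacency;
* ``FCNNF``      — fully connected net on the 1905-bit combined fingerprint;
* ``C1D_SMILES`` — 1-D convolutional net on embedded SMILES token ids;
* ``C1D_FP``     — the same convolutional family on embedded fingerprint
  on-bit indices.

Hidden widths follow the published architecture family; exact widths are
reconstructions (the original figures are not fully specified in text) and
are configurable through :class:`BaseModelSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .metrics import MetricReport, auc_roc, compute_classification_metrics, confusion_counts
from .nn import (
    Conv1D,
    Dense,
    Dropout,
    Embedding,
    GlobalMaxPool1D,
    GraphNet,
    MaxPool1D,
    Sequential,
    TrainConfig,
)

__all__ = [
    "BASE_MODEL_KINDS",
    "BaseModelSpec",
    "TrainedBaseModel",
    "build_base_model",
    "train_base_model",
    "predict_probabilities",
    "graph_batch",
]

BASE_MODEL_KINDS = ("FCNND", "GCNN", "FCNNF", "C1D_SMILES", "C1D_FP")


@dataclass
class BaseModelSpec:
    """Architecture hyperparameters for one base model."""

    kind: str
    input_dim: int = 0            # FCNN input width / C1D sequence length
    vocab_size: int = 0           # C1D embedding rows (tokens or fp indices + pad)
    hidden: tuple[int, ...] = ()  # dense widths (FCNN) or dense head (C1D)
    l2: float = 0.01
    dropout: float = 0.5
    embed_dim: int = 200
    conv_filters: int = 192
    conv_kernels: tuple[int, ...] = (10, 5, 3)
    gcn_channels: int = 64
    pool_channels: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BASE_MODEL_KINDS:
            raise ValueError(f"unknown base model kind {self.kind!r}")
        if not self.hidden:
            self.hidden = {
                "FCNND": (512, 256, 128, 64),
                "FCNNF": (200, 100, 50, 25),
                "C1D_SMILES": (128, 64),
                "C1D_FP": (128, 64),
                "GCNN": (),
            }[self.kind]


@dataclass
class TrainedBaseModel:
    """A built network plus its learned state and validation summary."""

    spec: BaseModelSpec
    model: object
    train_log: list[dict] = field(default_factory=list)
    valid_report: Optional[MetricReport] = None


def _fcnn(spec: BaseModelSpec, rng: np.random.Generator) -> Sequential:
    layers: list = []
    widths = (spec.input_dim, *spec.hidden)
    n_hidden = len(spec.hidden)
    for i in range(n_hidden):
        layers.append(
            Dense(widths[i], widths[i + 1], rng, relu=True,
                  l2_kernel=spec.l2, l2_bias=spec.l2)
        )
        # dropout on the middle hidden layers only
        if 0 < i < n_hidden - 1 and spec.dropout > 0:
            layers.append(Dropout(spec.dropout, rng))
    layers.append(Dense(widths[-1], 1, rng, relu=False,
                        l2_kernel=spec.l2, l2_bias=spec.l2))
    return Sequential(layers)


def _c1d(spec: BaseModelSpec, rng: np.random.Generator) -> Sequential:
    layers: list = [Embedding(spec.vocab_size, spec.embed_dim, rng)]
    c_in = spec.embed_dim
    for i, k in enumerate(spec.conv_kernels):
        layers.append(Conv1D(c_in, spec.conv_filters, k, rng, relu=True))
        c_in = spec.conv_filters
        if i < len(spec.conv_kernels) - 1:
            layers.append(MaxPool1D(2))
    layers.append(GlobalMaxPool1D())
    width = spec.conv_filters
    for h in spec.hidden:
        layers.append(Dense(width, h, rng, relu=True))
        width = h
    layers.append(Dense(width, 1, rng, relu=False))
    return Sequential(layers)


def build_base_model(spec: BaseModelSpec):
    """Instantiate the untrained network described by ``spec`` (seeded init)."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind in ("FCNND", "FCNNF"):
        if spec.input_dim <= 0:
            raise ValueError(f"{spec.kind} requires input_dim > 0")
        return _fcnn(spec, rng)
    if spec.kind == "GCNN":
        return GraphNet(
            n_node_features=spec.input_dim or 65,
            rng=rng,
            channels=spec.gcn_channels,
            pool_channels=spec.pool_channels,
            l2_kernel=spec.l2,
        )
    # C1D variants
    if spec.vocab_size <= 0:
        raise ValueError(f"{spec.kind} requires vocab_size > 0")
    return _c1d(spec, rng)


def graph_batch(graphs: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack GraphFeatures into (nodes, normalized adjacency, node mask)."""
    nodes = np.stack([g.nodes for g in graphs])
    adj = np.stack([g.adjacency for g in graphs])
    mask = np.zeros(nodes.shape[:2])
    for i, g in enumerate(graphs):
        mask[i, : g.n_atoms] = 1.0
    return nodes, nn.normalize_adjacency(adj, mask), mask


def _check_shapes(spec: BaseModelSpec, features) -> None:
    if spec.kind == "GCNN":
        if not (isinstance(features, tuple) and len(features) == 3):
            raise ValueError("GCNN expects a (nodes, a_hat, mask) tuple")
        return
    arr = np.asarray(features)
    if arr.ndim != 2 or arr.shape[1] != spec.input_dim:
        raise ValueError(
            f"{spec.kind} expects (n, {spec.input_dim}) features, got {arr.shape}"
        )


def train_base_model(
    model,
    spec: BaseModelSpec,
    features,
    labels,
    valid_features=None,
    valid_labels=None,
    cfg: TrainConfig | None = None,
) -> TrainedBaseModel:
    """Train one base model; validation metrics use the 0.5 threshold."""
    _check_shapes(spec, features)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if valid_features is not None:
        _check_shapes(spec, valid_features)
    log = nn.train_model(model, features, labels, valid_features, valid_labels, cfg)
    report = None
    if valid_features is not None:
        probs = nn.predict_proba(model, valid_features)
        report = compute_classification_metrics(
            confusion_counts(valid_labels, (probs >= 0.5).astype(int))
        )
        report.auc = auc_roc(valid_labels, probs)
    return TrainedBaseModel(spec=spec, model=model, train_log=log, valid_report=report)


def predict_probabilities(trained: TrainedBaseModel, features) -> np.ndarray:
    """Per-molecule blocker probabilities in [0,1]."""
    _check_shapes(trained.spec, features)
    return nn.predict_proba(trained.model, features)
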