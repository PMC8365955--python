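"""Meta-ensemble stage: stacking the base-model probabilities.

The outputs of the base models on the meta-training partition are
concatenated column-wise into meta features; a small fully connected network
(two hidden layers, sigmoid output) is trained on them at a higher learning
rate. The combination search evaluates every nonempty subset of the five
base representations (31 combinations, grouped by size M1..M5) on the
meta-validation partition and picks the subset that improves the most
metrics over the best single-model baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from . import nn
from .featurize import BASE_FEATURE_NAMES
from .metrics import MetricReport
from .nn import Dense, Sequential, TrainConfig

__all__ = [
    "MetaFeatureMatrix",
    "CombinationResult",
    "assemble_meta_features",
    "build_meta_model",
    "train_meta_model",
    "enumerate_feature_combinations",
    "select_best_combination",
    "classify_threshold",
    "META_TRAIN_CONFIG",
]

#: published meta-model optimization settings
META_TRAIN_CONFIG = TrainConfig(learning_rate=1e-3, epochs=300, batch_size=32)

#: metrics counted in the improvement-over-baseline comparison
_IMPROVEMENT_METRICS = ("mcc", "npv", "acc", "ppv", "spe", "sen", "auc")


@dataclass
class MetaFeatureMatrix:
    """(n_molecules, k) base-model probabilities, one column per member."""

    values: np.ndarray
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.members):
            raise ValueError("values must be (n, k) with k = len(members)")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("meta features must be probabilities in [0,1]")


@dataclass
class CombinationResult:
    """Evaluation of one base-feature subset on the meta-validation set."""

    combination_id: str
    members: tuple[str, ...]
    report: MetricReport


def assemble_meta_features(
    base_probs: dict[str, np.ndarray],
    members: Sequence[str],
) -> MetaFeatureMatrix:
    """Concatenate member probability vectors in canonical base order."""
    if not members:
        raise ValueError("members must be nonempty")
    ordered = tuple(m for m in BASE_FEATURE_NAMES if m in set(members))
    if len(ordered) != len(set(members)):
        unknown = set(members) - set(BASE_FEATURE_NAMES)
        raise ValueError(f"unknown base features: {sorted(unknown)}")
    lengths = {m: len(base_probs[m]) for m in ordered}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"probability vector length mismatch: {lengths}")
    values = np.column_stack([base_probs[m] for m in ordered])
    return MetaFeatureMatrix(values=values, members=ordered)


def build_meta_model(k: int, hidden: tuple[int, int] = (32, 16), seed: int = 0) -> Sequential:
    """Width-k input, two hidden ReLU layers, single-logit output."""
    rng = np.random.default_rng(seed)
    h1, h2 = hidden
    return Sequential(
        [
            Dense(k, h1, rng, relu=True),
            Dense(h1, h2, rng, relu=True),
            Dense(h2, 1, rng, relu=False),
        ]
    )


def train_meta_model(
    meta: MetaFeatureMatrix,
    labels,
    cfg: TrainConfig | None = None,
    valid_meta: Optional[MetaFeatureMatrix] = None,
    valid_labels=None,
    hidden: tuple[int, int] = (32, 16),
) -> Sequential:
    """Train the stacking network on a meta-feature matrix."""
    cfg = cfg or META_TRAIN_CONFIG
    model = build_meta_model(meta.values.shape[1], hidden=hidden, seed=cfg.seed)
    vx = valid_meta.values if valid_meta is not None else None
    nn.train_model(model, meta.values, np.asarray(labels), vx, valid_labels, cfg)
    return model


def enumerate_feature_combinations(
    base_set: Sequence[str] = BASE_FEATURE_NAMES,
) -> list[tuple[str, tuple[str, ...]]]:
    """All 31 nonempty subsets as (id, members), grouped M1..M5.

    Ids are ``M<size>-<rank>`` with deterministic ordering: subsets of each
    size enumerated in canonical base order.
    """
    names = tuple(base_set)
    if len(names) != len(set(names)):
        raise ValueError("base_set must contain distinct names")
    out: list[tuple[str, tuple[str, ...]]] = []
    for size in range(1, len(names) + 1):
        for rank, members in enumerate(combinations(names, size), start=1):
            out.append((f"M{size}-{rank}", members))
    return out


def _improvement_count(
    report: MetricReport, baseline: dict[str, float]
) -> int:
    count = 0
    for metric in _IMPROVEMENT_METRICS:
        value = getattr(report, metric)
        base = baseline.get(metric)
        if value is not None and base is not None and value > base:
            count += 1
    return count


def best_single_baseline(results: Sequence[CombinationResult]) -> dict[str, float]:
    """Per-metric best value over the size-1 (M1) combinations."""
    baseline: dict[str, float] = {}
    for res in results:
        if len(res.members) != 1:
            continue
        for metric in _IMPROVEMENT_METRICS:
            value = getattr(res.report, metric)
            if value is not None and value > baseline.get(metric, -np.inf):
                baseline[metric] = value
    if not baseline:
        raise ValueError("no single-feature (M1) results to build a baseline from")
    return baseline


def select_best_combination(
    results: Sequence[CombinationResult],
    baseline: dict[str, float] | None = None,
) -> CombinationResult:
    """Winner = most metrics improved over the per-metric best single model.

    Ties break by higher MCC, then by smaller combination size.
    """
    if not results:
        raise ValueError("empty results")
    if baseline is None:
        baseline = best_single_baseline(results)

    def key(res: CombinationResult):
        mcc = res.report.mcc
        return (
            _improvement_count(res.report, baseline),
            mcc if mcc is not None else -np.inf,
            -len(res.members),
        )

    return max(results, key=key)


def classify_threshold(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Label 1 (blocker) iff probability >= threshold."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0,1]")
    return (p >= threshold).astype(int)
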