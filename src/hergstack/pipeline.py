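"""End-to-end step-wise training: featurize, base stage, meta stage.

Training proceeds in two isolated steps. The five base models see only the
base-training partition (validated on base-valid); their output
probabilities on the meta partitions become meta features; one stacking
network per base-feature combination is trained on meta-train and scored on
meta-valid; the winning combination is the one improving the most metrics
over the best single base model. Featurizer state (descriptor normalizer,
token vocabulary) is fitted on base-train only, so no statistic of the meta
or test partitions leaks into the base stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import featurize as fz
from .basemodels import (
    BASE_MODEL_KINDS,
    BaseModelSpec,
    TrainedBaseModel,
    build_base_model,
    graph_batch,
    predict_probabilities,
    train_base_model,
)
from .dataio import (
    ConfigurationError,
    CVFoldPlan,
    LabeledDataset,
    StepwiseSplit,
    consecutive_cv_folds,
    stepwise_split,
)
from .featurize import BASE_FEATURE_NAMES
from .metaensemble import (
    CombinationResult,
    assemble_meta_features,
    classify_threshold,
    enumerate_feature_combinations,
    select_best_combination,
    train_meta_model,
)
from .metrics import (
    MetricReport,
    auc_roc,
    compute_classification_metrics,
    confusion_counts,
)
from .nn import TrainConfig, predict_proba

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FeaturizerState",
    "FeatureBundle",
    "RunManifest",
    "run_stepwise_training",
    "run_cross_validation",
    "evaluate_on_test_set",
    "combination_grid_frame",
]

#: base feature name -> base model kind
FEATURE_TO_MODEL = {
    "DESC": "FCNND",
    "MGF": "GCNN",
    "MFP": "FCNNF",
    "SeV": "C1D_SMILES",
    "FPeV": "C1D_FP",
}


@dataclass
class PipelineConfig:
    """Single configuration object controlling a full run."""

    seed: int = 42
    fractions: tuple[float, float, float, float] = (0.7, 0.1, 0.1, 0.1)
    base_learning_rate: float = 1e-4
    base_epochs: int = 100
    meta_learning_rate: float = 1e-3
    meta_epochs: int = 300
    batch_size: int = 32
    l2: float = 0.01
    dropout: float = 0.5
    meta_hidden: tuple[int, int] = (32, 16)
    members: tuple[str, ...] = BASE_FEATURE_NAMES  # base features in play
    threshold: float = 0.5

    def base_train_config(self, seed_offset: int = 0) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.base_learning_rate,
            epochs=self.base_epochs,
            batch_size=self.batch_size,
            seed=self.seed + seed_offset,
        )

    def meta_train_config(self, seed_offset: int = 0) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.meta_learning_rate,
            epochs=self.meta_epochs,
            batch_size=self.batch_size,
            seed=self.seed + seed_offset,
        )


@dataclass
class FeatureBundle:
    """Aligned feature views for the usable molecules of one dataset."""

    features: dict[str, object]      # name -> array or (nodes, a_hat, mask)
    labels: np.ndarray
    smiles: list[str]
    n_dropped: int


class FeaturizerState:
    """Fitted featurization state: descriptor normalizer + token vocabulary."""

    def __init__(self) -> None:
        self.normalizer: Optional[fz.DescriptorNormalizer] = None
        self.vocab: Optional[fz.TokenVocabulary] = None

    def fit(self, train: LabeledDataset) -> "FeaturizerState":
        usable = [s for s in train.smiles if self._usable(s)]
        raw = np.stack([fz.compute_raw_descriptors(s) for s in usable])
        self.normalizer = fz.fit_descriptor_normalizer(raw)
        self.vocab = fz.build_token_vocabulary(usable)
        return self

    @staticmethod
    def _usable(smiles: str) -> bool:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        return (
            mol is not None
            and mol.GetNumAtoms() <= fz.MAX_ATOMS
            and len(fz.tokenize_smiles(smiles)) <= fz.MAX_TOKENS
        )

    def transform(self, dataset: LabeledDataset,
                  members: Sequence[str] = BASE_FEATURE_NAMES) -> FeatureBundle:
        """Compute the requested feature views, dropping unusable molecules.

        Molecules over the atom or token limits are dropped (with a logged
        count) rather than truncated, keeping all views row-aligned.
        """
        if self.normalizer is None or self.vocab is None:
            raise RuntimeError("FeaturizerState must be fitted first")
        kept_smiles: list[str] = []
        kept_labels: list[int] = []
        dropped = 0
        for rec in dataset:
            if self._usable(rec.smiles):
                kept_smiles.append(rec.smiles)
                kept_labels.append(rec.label)
            else:
                dropped += 1
        if dropped:
            logger.info("%s: dropped %d oversize/overlength molecules",
                        dataset.name, dropped)
        feats: dict[str, object] = {}
        members = tuple(members)
        if "DESC" in members:
            feats["DESC"] = np.stack(
                [fz.compute_descriptor_vector(s, self.normalizer) for s in kept_smiles]
            )
        if "MGF" in members:
            feats["MGF"] = graph_batch(
                [fz.featurize_graph(s) for s in kept_smiles]
            )
        if "MFP" in members:
            feats["MFP"] = np.stack(
                [fz.compute_combined_fingerprints(s) for s in kept_smiles]
            ).astype(float)
        if "SeV" in members:
            feats["SeV"] = np.stack(
                [fz.encode_smiles_tokens(s, self.vocab) for s in kept_smiles]
            )
        if "FPeV" in members:
            feats["FPeV"] = np.stack(
                [fz.compute_fp_index_vector(s) for s in kept_smiles]
            )
        return FeatureBundle(
            features=feats,
            labels=np.asarray(kept_labels, dtype=int),
            smiles=kept_smiles,
            n_dropped=dropped,
        )

    def base_spec(self, feature_name: str, config: PipelineConfig,
                  seed_offset: int = 0) -> BaseModelSpec:
        kind = FEATURE_TO_MODEL[feature_name]
        spec = BaseModelSpec(kind=kind, l2=config.l2, dropout=config.dropout,
                             seed=config.seed + seed_offset)
        if kind == "FCNND":
            spec.input_dim = fz.N_DESCRIPTORS
        elif kind == "FCNNF":
            spec.input_dim = fz.N_COMBINED_BITS
        elif kind == "GCNN":
            spec.input_dim = fz.N_ATOM_FEATURES
        elif kind == "C1D_SMILES":
            spec.input_dim = fz.MAX_TOKENS
            spec.vocab_size = len(self.vocab)
        elif kind == "C1D_FP":
            spec.input_dim = fz.MAX_FP_INDICES
            spec.vocab_size = fz.N_ECFP_BITS + 1  # 1-based indices + pad 0
        return spec


@dataclass
class RunManifest:
    """Everything needed to audit and reuse one step-wise training run."""

    config: PipelineConfig
    state: FeaturizerState
    base_models: dict[str, TrainedBaseModel]
    combination_results: list[CombinationResult]
    selected: CombinationResult
    meta_models: dict[str, object]
    role_smiles: dict[str, list[str]]
    partition_sizes: dict[str, int]
    drop_counts: dict[str, int]

    @property
    def selected_meta_model(self):
        return self.meta_models[self.selected.combination_id]

    def audit_isolation(self) -> bool:
        """True iff no molecule appears in more than one training role."""
        roles = list(self.role_smiles)
        for i, a in enumerate(roles):
            sa = set(self.role_smiles[a])
            for b in roles[i + 1 :]:
                if sa & set(self.role_smiles[b]):
                    return False
        return True

    def summary(self) -> dict:
        return {
            "seed": self.config.seed,
            "partition_sizes": self.partition_sizes,
            "drop_counts": self.drop_counts,
            "selected_combination": self.selected.combination_id,
            "selected_members": list(self.selected.members),
            "selected_metrics": self.selected.report.as_dict(),
            "base_validation": {
                name: tm.valid_report.as_dict() if tm.valid_report else None
                for name, tm in self.base_models.items()
            },
            "n_combinations": len(self.combination_results),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def _base_probabilities(
    base_models: dict[str, TrainedBaseModel], bundle: FeatureBundle
) -> dict[str, np.ndarray]:
    return {
        name: predict_probabilities(tm, bundle.features[name])
        for name, tm in base_models.items()
    }


def _run_on_split(split: StepwiseSplit, config: PipelineConfig) -> RunManifest:
    state = FeaturizerState().fit(split.base_train)
    bundles = {
        role: state.transform(ds, config.members)
        for role, ds in split.roles().items()
    }
    base_models: dict[str, TrainedBaseModel] = {}
    for offset, name in enumerate(config.members):
        spec = state.base_spec(name, config, seed_offset=offset)
        model = build_base_model(spec)
        logger.info("training base model %s (%s)", name, spec.kind)
        base_models[name] = train_base_model(
            model,
            spec,
            bundles["base_train"].features[name],
            bundles["base_train"].labels,
            bundles["base_valid"].features[name],
            bundles["base_valid"].labels,
            config.base_train_config(seed_offset=offset),
        )
    probs_mt = _base_probabilities(base_models, bundles["meta_train"])
    probs_mv = _base_probabilities(base_models, bundles["meta_valid"])
    y_mt = bundles["meta_train"].labels
    y_mv = bundles["meta_valid"].labels

    results: list[CombinationResult] = []
    meta_models: dict[str, object] = {}
    for combo_id, members in enumerate_feature_combinations(config.members):
        meta_train = assemble_meta_features(probs_mt, members)
        meta_valid = assemble_meta_features(probs_mv, members)
        model = train_meta_model(
            meta_train, y_mt,
            cfg=config.meta_train_config(),
            valid_meta=meta_valid, valid_labels=y_mv,
            hidden=config.meta_hidden,
        )
        pv = predict_proba(model, meta_valid.values)
        report = compute_classification_metrics(
            confusion_counts(y_mv, classify_threshold(pv, config.threshold))
        )
        report.auc = auc_roc(y_mv, pv)
        results.append(CombinationResult(combo_id, members, report))
        meta_models[combo_id] = model
    selected = select_best_combination(results)
    logger.info("selected combination %s: %s",
                selected.combination_id, selected.members)
    return RunManifest(
        config=config,
        state=state,
        base_models=base_models,
        combination_results=results,
        selected=selected,
        meta_models=meta_models,
        role_smiles={role: b.smiles for role, b in bundles.items()},
        partition_sizes={role: len(b.labels) for role, b in bundles.items()},
        drop_counts={role: b.n_dropped for role, b in bundles.items()},
    )


def run_stepwise_training(
    dataset: LabeledDataset, config: PipelineConfig | None = None
) -> RunManifest:
    """Split, featurize, train the base stage then the meta stage."""
    config = config or PipelineConfig()
    split = stepwise_split(dataset, config.fractions, config.seed)
    return _run_on_split(split, config)


def run_cross_validation(
    dataset: LabeledDataset,
    config: PipelineConfig | None = None,
    k: int = 10,
) -> tuple[list[RunManifest], pd.DataFrame]:
    """Consecutive-splitting k-fold CV: per-fold grids plus mean/sd summary."""
    config = config or PipelineConfig()
    plan = consecutive_cv_folds(dataset, k)
    manifests = [
        _run_on_split(plan.fold_split(dataset, fold, config.seed), config)
        for fold in range(k)
    ]
    rows = []
    for fold, manifest in enumerate(manifests):
        grid = combination_grid_frame(manifest)
        grid.insert(0, "fold", fold)
        rows.append(grid)
    all_folds = pd.concat(rows, ignore_index=True)
    metric_cols = [c for c in all_folds.columns
                   if c not in ("fold", "combination", "members")]
    summary = all_folds.groupby("combination", sort=False)[metric_cols].agg(
        ["mean", "std"]
    )
    return manifests, summary


def combination_grid_frame(manifest: RunManifest) -> pd.DataFrame:
    """Combination-search results as a table (one row per subset)."""
    rows = []
    for res in manifest.combination_results:
        row = {"combination": res.combination_id,
               "members": ", ".join(res.members)}
        row.update({k: (np.nan if v is None else v)
                    for k, v in res.report.as_dict().items()})
        rows.append(row)
    frame = pd.DataFrame(rows)
    metric_cols = frame.columns.difference(["combination", "members"])
    frame[metric_cols] = frame[metric_cols].astype(float)
    return frame


def evaluate_on_test_set(
    manifest: RunManifest, test: LabeledDataset
) -> MetricReport:
    """Score the selected ensemble on an external test set (0.5 threshold)."""
    bundle = manifest.state.transform(test, manifest.selected.members)
    if bundle.n_dropped:
        logger.warning("%s: %d molecules excluded from evaluation",
                       test.name, bundle.n_dropped)
    probs = {
        name: predict_probabilities(manifest.base_models[name],
                                    bundle.features[name])
        for name in manifest.selected.members
    }
    meta = assemble_meta_features(probs, manifest.selected.members)
    pv = predict_proba(manifest.selected_meta_model, meta.values)
    report = compute_classification_metrics(
        confusion_counts(
            bundle.labels,
            classify_threshold(pv, manifest.config.threshold),
        )
    )
    report.auc = auc_roc(bundle.labels, pv)
    return report
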