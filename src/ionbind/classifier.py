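"""Random-forest classification and the end-to-end evaluation protocols.

The forest uses the two parameters the method fixes — k trees
(default 500) and a random feature subset of size m = floor(sqrt(M)) at
each split — with all remaining tree hyperparameters at the library
defaults, recorded in the training summary.  Prediction is by vote: the
positive-vote fraction is returned alongside hard labels, and exact
ties go to the positive class.

:func:`run_protocol` wires the full pipeline, with folds nested inside
balanced repeats: segment -> balance (x n_repeats) -> split -> fit
PWMs/backgrounds on the training side only -> assemble features ->
train -> predict -> metrics -> average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import joblib
import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureExtractor, combine_dihedral_model
from .io import BindingAnnotation, ProteinChain
from .segmentation import SequenceSegment, default_window, segment_chains
from .validation import (
    ConfusionCounts,
    EvaluationResult,
    average_results,
    balance,
    chain_split,
    kfold,
    metrics,
)

logger = logging.getLogger("ionbind")

MODEL_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters and protocol settings for one ligand model."""

    n_trees: int = 500
    subset_size: int | None = None  # None -> floor(sqrt(M))
    seed: int = 0
    ligand_id: str | None = None
    window: int | None = None
    dihedral_model: int = 1
    include_dihedral: bool = True
    n_repeats: int = 10
    k_folds: int = 5
    train_fraction: float = 0.8
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_window(self) -> int:
        if self.window is not None:
            return self.window
        if self.ligand_id is None:
            raise ValueError("need either an explicit window length or a ligand id")
        return default_window(self.ligand_id)


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    schema: tuple[tuple[str, int], ...]
    config: ModelConfig
    training_summary: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return sum(d for _, d in self.schema)


def train(
    X: np.ndarray,
    y: Sequence[bool],
    config: ModelConfig,
    schema: tuple[tuple[str, int], ...] | None = None,
) -> TrainedModel:
    """Fit a k-tree forest with m = floor(sqrt(M)) features per split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("feature table and labels are inconsistent")
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("training requires at least two samples with both classes")
    M = X.shape[1]
    m = config.subset_size or max(1, int(np.sqrt(M)))
    if not 1 <= m <= M:
        raise ValueError(f"feature-subset size {m} outside [1, {M}]")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=m,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    if schema is None:
        schema = (("features", M),)
    summary = {
        "n_samples": int(X.shape[0]),
        "n_positive": int(y.sum()),
        "n_negative": int((1 - y).sum()),
        "n_features": M,
        "subset_size": m,
        "tree_params": forest.get_params(),
        "sklearn_version": sklearn.__version__,
    }
    return TrainedModel(forest=forest, schema=schema, config=config, training_summary=summary)


def predict(
    model: TrainedModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, positive-vote fractions); vote ties resolve positive."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature table has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.n_features}"
        )
    if X.shape[0] == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    proba = model.forest.predict_proba(X)
    pos_col = list(model.forest.classes_).index(1)
    votes = proba[:, pos_col]
    return votes >= 0.5, votes


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "forest": model.forest,
            "schema": model.schema,
            "config": model.config,
            "training_summary": model.training_summary,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive {path} has format version "
            f"{payload.get('format_version')!r}, expected {MODEL_FORMAT_VERSION}"
        )
    return TrainedModel(
        forest=payload["forest"],
        schema=payload["schema"],
        config=payload["config"],
        training_summary=payload["training_summary"],
    )


# ---------------------------------------------------------------------------
# Protocol runner

FitHook = Callable[[str, Sequence[SequenceSegment], Sequence[SequenceSegment]], None]


def _evaluate_split(
    train_segments: list[SequenceSegment],
    test_segments: list[SequenceSegment],
    config: ModelConfig,
    L: int,
    seed: int,
    fit_hook: FitHook | None,
) -> EvaluationResult:
    extractor = FeatureExtractor(
        L, dihedral_model=config.dihedral_model,
        include_dihedral=config.include_dihedral,
    )
    extractor.fit(train_segments)
    if fit_hook is not None:
        fit_hook("fit", train_segments, test_segments)
    X_train = extractor.transform(train_segments)
    y_train = np.array([s.label for s in train_segments])
    model = train(X_train, y_train, replace(config, seed=seed), extractor.schema)
    y_pred, _ = predict(model, extractor.transform(test_segments))
    y_true = np.array([s.label for s in test_segments])
    return metrics(ConfusionCounts.from_labels(y_true, y_pred))


def run_protocol(
    chains: Sequence[ProteinChain],
    annotation: BindingAnnotation,
    config: ModelConfig,
    protocol: Literal["cv5", "independent"] = "cv5",
    fit_hook: FitHook | None = None,
) -> EvaluationResult:
    """Full evaluation pipeline for one ligand under one configuration.

    ``cv5``: for each of n_repeats balanced sets, a k-fold segment-level
    cross-validation; the repeat result averages the folds and the final
    result averages the repeats.  ``independent``: whole chains split
    80/20; models trained on balanced training-side sets are evaluated
    on every test-side segment (the natural, imbalanced mixture).
    """
    L = config.resolve_window()
    phi_scheme, psi_scheme = combine_dihedral_model(config.dihedral_model)
    segments = segment_chains(
        chains, annotation, L, phi_scheme, psi_scheme, require_tracks=True
    )

    if protocol == "cv5":
        pos = [s for s in segments if s.label]
        neg = [s for s in segments if not s.label]
        per_repeat = []
        for r in range(config.n_repeats):
            balanced = balance(pos, neg, config.seed + r)
            labels = [s.label for s in balanced]
            plan = kfold(
                len(balanced), k=config.k_folds, seed=config.seed + 10_000 + r,
                labels=labels if config.stratified else None,
            )
            fold_results = []
            for f, test_idx in enumerate(plan.folds):
                test_mask = np.zeros(len(balanced), dtype=bool)
                test_mask[test_idx] = True
                train_segs = [s for s, t in zip(balanced, test_mask) if not t]
                test_segs = [s for s, t in zip(balanced, test_mask) if t]
                fold_results.append(
                    _evaluate_split(
                        train_segs, test_segs, config, L,
                        seed=config.seed + 100_000 + 100 * r + f, fit_hook=fit_hook,
                    )
                )
            per_repeat.append(average_results(fold_results))
        return average_results(per_repeat)

    if protocol == "independent":
        plan = chain_split(
            [c.chain_id for c in chains], config.train_fraction, config.seed
        )
        train_segs = [s for s in segments if s.source_chain in plan.train_chains]
        test_segs = [s for s in segments if s.source_chain in plan.test_chains]
        pos = [s for s in train_segs if s.label]
        neg = [s for s in train_segs if not s.label]
        if not any(s.label for s in test_segs):
            logger.warning("independent test side has no positive segments; metrics degenerate")
        per_repeat = []
        for r in range(config.n_repeats):
            balanced = balance(pos, neg, config.seed + r)
            per_repeat.append(
                _evaluate_split(
                    balanced, test_segs, config, L,
                    seed=config.seed + 100_000 + r, fit_hook=fit_hook,
                )
            )
        return average_results(per_repeat)

    raise ValueError(f"unknown protocol {protocol!r}")
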