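"""Training protocol: Adam + categorical cross-entropy, checkpoint on best
validation loss, and 5-fold cross-validation against a fixed external test set.

The cross-validation pools the train and validation segments, partitions them
into k folds, trains one model per fold (validating on the held-out fold), and
scores every checkpointed model on the same untouched test set; the spread of
those k test accuracies feeds the confidence interval in
:mod:`pulsestage.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold

from .model import ConcatCNNClassifier, ModelSpec
from .preprocess import LABEL_TO_CODE, LabeledSegment


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 100
    batch_size: int = 32
    patience: int = 15
    k_folds: int = 5
    class_weight: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class FoldResult:
    fold_index: int
    best_val_loss: float
    val_accuracy: float
    test_accuracy: float
    checkpoint_ref: Optional[str] = None


def kfold_indices(n: int, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled k-fold index pairs; validation folds partition 0..n-1."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in kf.split(np.arange(n))]


def segments_to_arrays(segments: Sequence[LabeledSegment], input_mode: str):
    """Stack LabeledSegments into (X, y) for the given input mode.

    concat -> X of shape (n, 2, 150) with channel 0 = PPG, channel 1 = ECG;
    single modes -> (n, 150).
    """
    ppg = np.stack([s.ppg for s in segments]).astype(np.float32)
    ecg = np.stack([s.ecg for s in segments]).astype(np.float32)
    y = np.array([LABEL_TO_CODE[s.label] for s in segments], dtype=int)
    if input_mode == "concat":
        X = np.stack([ppg, ecg], axis=1)
    elif input_mode == "ppg":
        X = ppg
    elif input_mode == "ecg":
        X = ecg
    else:
        raise ValueError(f"unknown input_mode {input_mode!r}")
    return X, y


def _estimator(spec: ModelSpec, config: TrainConfig, seed: int) -> ConcatCNNClassifier:
    return ConcatCNNClassifier(
        input_mode=spec.input_mode,
        depth=spec.depth,
        kernel_size=spec.kernel_size,
        pool_size=spec.pool_size,
        hidden_units=spec.hidden_units,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        patience=config.patience,
        class_weight=config.class_weight,
        random_state=seed,
    )


def train_model(spec: ModelSpec, train_set: Sequence[LabeledSegment],
                val_set: Sequence[LabeledSegment], config: TrainConfig):
    """Fit one model; returns ``(estimator, history)`` with checkpointed weights."""
    if not len(train_set) or not len(val_set):
        raise ValueError("train_set and val_set must be nonempty")
    X, y = segments_to_arrays(train_set, spec.input_mode)
    Xv, yv = segments_to_arrays(val_set, spec.input_mode)
    clf = _estimator(spec, config, config.seed)
    clf.fit(X, y, X_val=Xv, y_val=yv)
    return clf, clf.history_


def _segment_ids(segments) -> set:
    return {(s.source_record, s.beat_index) for s in segments}


def cross_validate(spec: ModelSpec, train_val_segments: Sequence[LabeledSegment],
                   test_segments: Sequence[LabeledSegment], config: TrainConfig,
                   run_dir: Optional[str] = None) -> list[FoldResult]:
    """k-fold CV on the pooled train+validation data with a fixed test set.

    Asserts (by record/beat identity) that the external test set never
    intersects the training pool.
    """
    overlap = _segment_ids(train_val_segments) & _segment_ids(test_segments)
    if overlap:
        raise ValueError(f"test set overlaps training pool: {sorted(overlap)[:5]} ...")
    n = len(train_val_segments)
    folds = kfold_indices(n, config.k_folds, seed=config.seed)
    Xt, yt = segments_to_arrays(test_segments, spec.input_mode)
    # independent per-fold seeds derived from the global seed
    fold_seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=config.k_folds)
    results = []
    for i, (tr_idx, va_idx) in enumerate(folds):
        tr = [train_val_segments[j] for j in tr_idx]
        va = [train_val_segments[j] for j in va_idx]
        fold_cfg = TrainConfig(**{**config.__dict__, "seed": int(fold_seeds[i])})
        clf, history = train_model(spec, tr, va, fold_cfg)
        val_acc = float(history["val_accuracy"][int(np.argmin(history["val_loss"]))])
        test_acc = clf.score(Xt, yt)
        ref = None
        if run_dir is not None:
            path = Path(run_dir) / f"fold{i}.npz"
            path.parent.mkdir(parents=True, exist_ok=True)
            clf.save(path)
            ref = str(path)
            hist_path = Path(run_dir) / f"fold{i}_history.tsv"
            cols = ["epoch"] + list(history)
            lines = ["\t".join(cols)]
            for e in range(len(history["train_loss"])):
                lines.append("\t".join([str(e)] + [f"{history[c][e]:.6f}" for c in history if len(history[c]) > e]))
            hist_path.write_text("\n".join(lines) + "\n")
        results.append(
            FoldResult(
                fold_index=i,
                best_val_loss=float(clf.best_val_loss_),
                val_accuracy=val_acc,
                test_accuracy=test_acc,
                checkpoint_ref=ref,
            )
        )
    return results
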