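"""Batch-aware repeated cross-validation and the label-permutation null.

Validation is unstratified k-fold (default k = 10): folds are built
regardless of class labels. When grouping by batch is enabled, whole
acquisition batches are kept on one side of every train/test split, so
systematic image-wide artifacts shared within a batch (illumination
drift, lamp warm-up) cannot leak class information from training into
testing. Experiments are repeated (default 100 runs) with fresh splits
and summarized by the median and standard deviation of the run
accuracies. A label-shuffling permutation null calibrates chance
performance and yields an empirical p-value.

The single stratified 75/25 split used by the WND-CHARM baseline
("lone 4-fold") is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .models import (
    fit_lda,
    fit_pca,
    predict_lda,
    shuffle_labels,
    transform_pca,
    wnd_fit,
    wnd_predict,
    DEFAULT_SELECT_FRACTION,
    DEFAULT_VARIANCE_THRESHOLD,
)

__all__ = [
    "CVConfig",
    "CVResult",
    "assign_folds",
    "lone_four_fold_split",
    "cross_validate",
    "repeat_validation",
    "permutation_null",
]


@dataclass
class CVConfig:
    """Cross-validation settings (defaults follow the method's published
    protocol: unstratified 10-fold, 100 repetitions)."""

    k: int = 10
    n_runs: int = 100
    grouping: str = "none"            # "none" | "by_batch"
    seed: int = 0
    pipeline: str = "pca_lda"         # "pca_lda" | "wnd"
    stratified: bool = False          # kept False: unstratified by design
    method: str = "kfold"             # "kfold" | "lone4"
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD
    select_fraction: float = DEFAULT_SELECT_FRACTION

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.grouping not in ("none", "by_batch"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if self.pipeline not in ("pca_lda", "wnd"):
            raise ValueError(f"unknown pipeline {self.pipeline!r}")


@dataclass
class CVResult:
    """Per-run accuracies, confusion matrices and a median/std summary."""

    accuracies: list[float]
    confusions: list[pd.DataFrame]
    fold_assignments: list[np.ndarray]
    warnings: list[str] = field(default_factory=list)
    p_value: float | None = None

    @property
    def summary(self) -> dict:
        acc = np.asarray(self.accuracies, dtype=np.float64)
        out = {
            "median": float(np.median(acc)),
            "std": float(np.std(acc)),
            "n_runs": int(acc.size),
        }
        if self.p_value is not None:
            out["p_value"] = self.p_value
        return out


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def assign_folds(
    sample_ids,
    batch_ids,
    k: int,
    seed,
    grouping: str = "none",
) -> np.ndarray:
    """Fold index per sample.

    With batch grouping, whole batches are assigned to folds greedily —
    batches visited largest first (random order within equal sizes),
    each into the currently smallest fold — so no batch ever spans a
    train/test boundary. Without grouping, samples are permuted and
    dealt round-robin. Class labels play no role (unstratified).
    """
    sample_ids = np.asarray(sample_ids)
    batch_ids = np.asarray(batch_ids)
    n = sample_ids.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if grouping == "by_batch":
        batches, counts = np.unique(batch_ids, return_counts=True)
        if k > batches.size:
            raise ValueError(
                f"k = {k} folds exceed the {batches.size} distinct batches"
            )
        order = rng.permutation(batches.size)
        order = order[np.argsort(-counts[order], kind="stable")]  # largest first
        fold_sizes = np.zeros(k, dtype=int)
        batch_fold = {}
        for bi in order:
            target = int(np.argmin(fold_sizes))  # ties -> lowest fold index
            batch_fold[batches[bi]] = target
            fold_sizes[target] += counts[bi]
        return np.array([batch_fold[b] for b in batch_ids])

    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % k
    return folds


def lone_four_fold_split(y, seed) -> tuple[np.ndarray, np.ndarray]:
    """Single stratified 75/25 split: per class, round(0.25 n_c) samples
    go to the test set (equivalent to one fold of stratified 4-fold CV)."""
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        if idx.size < 4:
            raise ValueError(f"class {c!r} has {idx.size} < 4 samples")
        n_test = _round_half_up(0.25 * idx.size)
        test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    test = np.array(sorted(test_idx), dtype=int)
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def _fit_predict(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    test_X: pd.DataFrame,
    config: CVConfig,
) -> np.ndarray:
    if config.pipeline == "pca_lda":
        pca = fit_pca(train_X, config.variance_threshold)
        lda = fit_lda(transform_pca(pca, train_X), train_y)
        return predict_lda(lda, transform_pca(pca, test_X))
    wnd = wnd_fit(train_X, train_y, fraction=config.select_fraction)
    return wnd_predict(wnd, test_X)


def cross_validate(
    features: FeatureMatrix, config: CVConfig, seed=None
) -> CVResult:
    """One cross-validation run: pooled (micro-averaged) accuracy over
    all held-out folds.

    Every statistic — standardization, PCA, Fisher weights, classifier
    fit — is computed on the training folds only. A training partition
    missing a class entirely scores that fold's test samples of the
    missing class as errors (with a warning) rather than aborting.
    """
    y = features.labels
    if y is None:
        raise ValueError("cross_validate: features carry no labels")
    y = y.to_numpy().astype(str)
    if np.unique(y).size < 2:
        raise ValueError("cross_validate: need at least 2 classes")
    run_seed = config.seed if seed is None else seed
    rng = (
        run_seed
        if isinstance(run_seed, np.random.Generator)
        else np.random.default_rng(run_seed)
    )

    classes = sorted(np.unique(y).tolist())
    warnings: list[str] = []

    if config.method == "lone4":
        train, test = lone_four_fold_split(y, rng)
        folds = np.zeros(y.size, dtype=int)
        folds[test] = 0
        folds[train] = -1  # train-only marker; single evaluation fold 0
        fold_ids = [0]
    else:
        folds = assign_folds(
            features.X.index.to_numpy(),
            features.batches.to_numpy(),
            config.k,
            rng,
            grouping=config.grouping,
        )
        fold_ids = sorted(set(folds.tolist()))

    pred = np.empty(y.size, dtype=object)
    evaluated = np.zeros(y.size, dtype=bool)
    for f in fold_ids:
        test_mask = folds == f
        train_mask = ~test_mask if config.method != "lone4" else folds == -1
        if not test_mask.any():
            continue
        if config.grouping == "by_batch":
            shared = set(features.batches[train_mask]) & set(
                features.batches[test_mask]
            )
            assert not shared, f"batch leak across fold {f}: {shared}"
        train_classes = np.unique(y[train_mask])
        missing = sorted(set(y[test_mask]) - set(train_classes))
        if missing:
            warnings.append(
                f"fold {f}: classes {missing} absent from training; "
                "their test samples scored as errors"
            )
        evaluated |= test_mask
        if train_classes.size < 2:
            warnings.append(
                f"fold {f}: training partition has a single class; "
                "all its test samples scored as errors"
            )
            pred[test_mask] = "__unclassified__"
            continue
        pred[test_mask] = _fit_predict(
            features.X[train_mask], y[train_mask], features.X[test_mask], config
        )

    correct = np.array(
        [p == t for p, t in zip(pred[evaluated], y[evaluated])]
    )
    accuracy = float(correct.mean())
    pred_classes = classes + (
        ["__unclassified__"] if "__unclassified__" in set(pred[evaluated]) else []
    )
    conf = pd.DataFrame(0, index=classes, columns=pred_classes)
    for t, p in zip(y[evaluated], pred[evaluated]):
        conf.loc[t, p] += 1
    return CVResult(
        accuracies=[accuracy],
        confusions=[conf],
        fold_assignments=[folds],
        warnings=warnings,
    )


def repeat_validation(features: FeatureMatrix, config: CVConfig) -> CVResult:
    """n_runs independent cross-validation runs (run r seeded seed + r);
    summary = median and standard deviation of the run accuracies."""
    accs, confs, folds, warns = [], [], [], []
    for r in range(config.n_runs):
        res = cross_validate(features, config, seed=config.seed + r)
        accs.extend(res.accuracies)
        confs.extend(res.confusions)
        folds.extend(res.fold_assignments)
        warns.extend(res.warnings)
    return CVResult(
        accuracies=accs, confusions=confs, fold_assignments=folds, warnings=warns
    )


def permutation_null(
    features: FeatureMatrix,
    config: CVConfig,
    observed_accuracy: float | None = None,
) -> CVResult:
    """Label-shuffling null distribution of cross-validated accuracy.

    Each run shuffles the class labels with a fresh seed and performs
    one full cross-validation. The one-sided empirical p-value uses the
    add-one convention: p = (1 + #{null >= observed}) / (n_runs + 1).
    If no observed accuracy is supplied, one unshuffled run at the base
    seed provides it.
    """
    y = features.labels
    if y is None:
        raise ValueError("permutation_null: features carry no labels")
    if observed_accuracy is None:
        observed_accuracy = cross_validate(
            features, config, seed=config.seed
        ).accuracies[0]

    accs, confs, folds, warns = [], [], [], []
    for r in range(config.n_runs):
        rng = np.random.default_rng(config.seed + r)
        shuffled = pd.Series(
            shuffle_labels(y.to_numpy(), int(rng.integers(2**31))), index=y.index
        )
        null_features = FeatureMatrix(
            X=features.X, labels=shuffled, batches=features.batches
        )
        res = cross_validate(null_features, config, seed=rng)
        accs.extend(res.accuracies)
        confs.extend(res.confusions)
        folds.extend(res.fold_assignments)
        warns.extend(res.warnings)
    null = np.asarray(accs)
    p = float((1 + np.sum(null >= observed_accuracy)) / (config.n_runs + 1))
    return CVResult(
        accuracies=accs,
        confusions=confs,
        fold_assignments=folds,
        warnings=warns,
        p_value=p,
    )
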