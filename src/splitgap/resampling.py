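"""Split and validation machinery.

Seed-indexed stratified train-test splitting (the object of study: every
split seed yields a different train-test pair), per-class undersampling to
emulate smaller studies, and the four internal-validation estimators a
practitioner might use on the training set:

* plain stratified k-fold CV,
* repeated CV (m fresh shuffles),
* nested CV (inner loop tunes, outer loop estimates),
* bootstrap out-of-bag (B resamples, scored on the left-out samples).

Per-class counts use floor rounding throughout so sizes are reproducible:
a 7:3 split of 109 vs. 58 always gives train (76, 40) and test (33, 18).
Every estimator refits the entire pipeline (standardizer + selector +
classifier) inside each fold or draw — no information leaks from the
held-out part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._seeds import child_seed, rng_from
from .datasets import FeatureTable
from .metrics import auc_mann_whitney
from .pipeline import (
    HyperGrid,
    PipelineConfig,
    fit_pipeline,
    grid_search,
    predict_scores,
)

__all__ = [
    "SplitPair",
    "FoldAssignment",
    "ValidationEstimate",
    "stratified_split",
    "undersample",
    "cv_estimate",
    "repeated_cv_estimate",
    "nested_cv_estimate",
    "bootstrap_draw",
    "bootstrap_oob_estimate",
]

_BOOTSTRAP_RETRY_CAP = 100


@dataclass(frozen=True)
class SplitPair:
    """One stratified train-test partition, reproducible from its seed."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    train_fraction: float


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold ids for stratified k-fold CV."""

    fold_of_sample: np.ndarray
    n_folds: int
    seed: int
    stratified: bool = True

    @classmethod
    def stratified(
        cls, labels: np.ndarray, n_folds: int, seed: int
    ) -> "FoldAssignment":
        labels = np.asarray(labels)
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for cls_label in (0, 1):
            if (labels == cls_label).sum() < n_folds:
                raise ValueError(
                    f"class {cls_label} has fewer than {n_folds} members"
                )
        splitter = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(seed)
        )
        fold_of_sample = np.empty(labels.size, dtype=int)
        for fold, (_, test_idx) in enumerate(
            splitter.split(np.zeros((labels.size, 1)), labels)
        ):
            fold_of_sample[test_idx] = fold
        return cls(fold_of_sample=fold_of_sample, n_folds=n_folds, seed=int(seed))


@dataclass(frozen=True)
class ValidationEstimate:
    """One estimator's point estimate with its per-replicate AUCs."""

    method: str
    point_estimate: float
    replicate_aucs: np.ndarray
    settings: dict

    @property
    def spread(self) -> float:
        if self.replicate_aucs.size < 2:
            return 0.0
        return float(np.std(self.replicate_aucs, ddof=1))

    @classmethod
    def from_replicates(
        cls, method: str, replicate_aucs: np.ndarray, settings: dict
    ) -> "ValidationEstimate":
        replicate_aucs = np.asarray(replicate_aucs, dtype=float)
        return cls(
            method=method,
            point_estimate=float(replicate_aucs.mean()),
            replicate_aucs=replicate_aucs,
            settings=settings,
        )


def stratified_split(
    table: FeatureTable, train_fraction: float, seed: int
) -> SplitPair:
    """Random stratified partition: per class, floor(n_c * fraction) samples
    go to training, chosen uniformly from the seeded stream.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = rng_from(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        cls_idx = np.where(table.labels == cls)[0]
        n_train = int(np.floor(cls_idx.size * train_fraction))
        if n_train < 1 or n_train >= cls_idx.size:
            raise ValueError(
                f"class {cls} would be absent from train or test at "
                f"fraction {train_fraction}"
            )
        perm = rng.permutation(cls_idx.size)
        train_parts.append(cls_idx[perm[:n_train]])
        test_parts.append(cls_idx[perm[n_train:]])
    return SplitPair(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        seed=int(seed),
        train_fraction=float(train_fraction),
    )


def undersample(table: FeatureTable, fraction: float, seed: int) -> FeatureTable:
    """Retain floor(n_c * fraction) samples per class, uniformly at random.

    Feature columns are untouched; retained rows keep the original table
    order.  Emulates running the same study on a smaller cohort.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    rng = rng_from(seed)
    keep_parts = []
    for cls in (0, 1):
        cls_idx = np.where(table.labels == cls)[0]
        n_keep = int(np.floor(cls_idx.size * fraction))
        if n_keep < 2:
            raise ValueError(
                f"class {cls} would retain fewer than 2 samples at "
                f"fraction {fraction}"
            )
        perm = rng.permutation(cls_idx.size)
        keep_parts.append(cls_idx[perm[:n_keep]])
    keep = np.sort(np.concatenate(keep_parts))
    return table.subset(keep)


def cv_estimate(
    train: FeatureTable,
    pipeline_config: PipelineConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> ValidationEstimate:
    """Stratified k-fold CV of a fixed configuration.

    The full pipeline is refit on each fold's complement and scored on the
    held-out fold; the point estimate is the mean of the fold AUCs.
    """
    folds = FoldAssignment.stratified(train.labels, n_folds, seed)
    fold_aucs = np.empty(n_folds)
    for fold in range(n_folds):
        tr = np.where(folds.fold_of_sample != fold)[0]
        te = np.where(folds.fold_of_sample == fold)[0]
        model = fit_pipeline(train.subset(tr), pipeline_config)
        scores = predict_scores(model, train.subset(te))
        fold_aucs[fold] = auc_mann_whitney(scores, train.labels[te])
    return ValidationEstimate.from_replicates(
        "cv", fold_aucs, {"n_folds": n_folds, "seed": int(seed)}
    )


def repeated_cv_estimate(
    train: FeatureTable,
    pipeline_config: PipelineConfig,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> ValidationEstimate:
    """CV repeated over ``n_repeats`` fresh shuffles; all fold AUCs pooled."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    replicate_aucs = []
    for rep in range(n_repeats):
        est = cv_estimate(
            train, pipeline_config, n_folds, child_seed(seed, "rep", rep)
        )
        replicate_aucs.append(est.replicate_aucs)
    return ValidationEstimate.from_replicates(
        "repeated_cv",
        np.concatenate(replicate_aucs),
        {"n_folds": n_folds, "n_repeats": n_repeats, "seed": int(seed)},
    )


def nested_cv_estimate(
    train: FeatureTable,
    grid: HyperGrid,
    n_folds_outer: int = 5,
    n_folds_inner: int = 5,
    seed: int = 0,
) -> ValidationEstimate:
    """Nested CV: inner grid search tunes, outer folds estimate.

    For each outer fold, the grid search (inner CV) runs on the outer-train
    portion alone, the winning configuration is refit on that portion, and
    the outer-held-out fold is scored — so the estimate prices in the cost
    of hyperparameter tuning itself.
    """
    folds = FoldAssignment.stratified(train.labels, n_folds_outer, seed)
    outer_aucs = np.empty(n_folds_outer)
    for fold in range(n_folds_outer):
        tr = np.where(folds.fold_of_sample != fold)[0]
        te = np.where(folds.fold_of_sample == fold)[0]
        inner_table = train.subset(tr)
        result = grid_search(
            inner_table,
            grid,
            n_folds=n_folds_inner,
            seed=child_seed(seed, "inner", fold),
        )
        model = fit_pipeline(inner_table, result.best_config)
        scores = predict_scores(model, train.subset(te))
        outer_aucs[fold] = auc_mann_whitney(scores, train.labels[te])
    return ValidationEstimate.from_replicates(
        "nested_cv",
        outer_aucs,
        {
            "n_folds_outer": n_folds_outer,
            "n_folds_inner": n_folds_inner,
            "seed": int(seed),
        },
    )


def bootstrap_draw(
    rng: np.random.Generator, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap resample: in-bag indices (with repeats) and the
    out-of-bag complement.  Draws lacking a class on either side are
    redrawn, up to 100 retries.
    """
    labels = np.asarray(labels)
    n = labels.size
    for _ in range(_BOOTSTRAP_RETRY_CAP):
        in_bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if (
            oob.size > 0
            and len(np.unique(labels[in_bag])) == 2
            and len(np.unique(labels[oob])) == 2
        ):
            return in_bag, oob
    raise RuntimeError("bootstrap draw kept producing single-class resamples")


def bootstrap_oob_estimate(
    train: FeatureTable,
    pipeline_config: PipelineConfig,
    n_draws: int = 10,
    seed: int = 0,
) -> ValidationEstimate:
    """Bootstrap out-of-bag estimate of a fixed configuration.

    Each draw resamples n rows with replacement, refits the pipeline on the
    in-bag rows, and scores the out-of-bag rows (about 36.8% of the sample
    at large n).  Draws whose in-bag or out-of-bag part lacks a class are
    redrawn, up to 100 retries per draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = rng_from(seed)
    oob_aucs = np.empty(n_draws)
    for b in range(n_draws):
        in_bag, oob = bootstrap_draw(rng, train.labels)
        oob_labels = train.labels[oob]
        # in-bag rows repeat, so build the resample with fresh sample ids
        in_bag_table = FeatureTable(
            values=train.values[in_bag],
            labels=train.labels[in_bag],
            feature_names=train.feature_names,
        )
        model = fit_pipeline(in_bag_table, pipeline_config)
        scores = predict_scores(model, train.subset(oob))
        oob_aucs[b] = auc_mann_whitney(scores, oob_labels)
    return ValidationEstimate.from_replicates(
        "bootstrap",
        oob_aucs,
        {"n_draws": n_draws, "seed": int(seed)},
    )
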