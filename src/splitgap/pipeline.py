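"""The per-split model: standardization, F-test feature selection, and an
L1-penalized linear classifier, plus grid-search tuning over (k, C).

The model deliberately mirrors a common radiomics recipe: (1) z-score each
feature with the training-set mean and SD, (2) keep the k features with the
largest two-group ANOVA F statistics, (3) fit an L1-penalized ("LASSO")
logistic regression on the selected features with inverse-regularization
strength C.  Everything is fit on training data only; applying the model to
new data reuses the frozen means/SDs and selected columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .datasets import FeatureTable

__all__ = [
    "PipelineConfig",
    "HyperGrid",
    "FittedPipeline",
    "GridSearchResult",
    "anova_f_scores",
    "select_top_k",
    "fit_pipeline",
    "predict_scores",
    "grid_search",
    "DEFAULT_GRID",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Hyperparameters of one pipeline fit."""

    k_features: int
    c_value: float
    classifier: str = "l1_logistic"

    def __post_init__(self) -> None:
        if self.k_features < 1:
            raise ValueError("k_features must be >= 1")
        if not self.c_value > 0:
            raise ValueError("c_value must be > 0")
        if self.classifier not in ("l1_logistic", "linear_svm"):
            raise ValueError("classifier must be 'l1_logistic' or 'linear_svm'")


@dataclass(frozen=True)
class HyperGrid:
    """Ordered candidate values for the (k, C) grid search."""

    k_values: tuple[int, ...]
    c_values: tuple[float, ...]

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.k_values)
        cs = tuple(float(c) for c in self.c_values)
        object.__setattr__(self, "k_values", ks)
        object.__setattr__(self, "c_values", cs)
        if not ks or not cs:
            raise ValueError("grid axes must be nonempty")
        if any(k < 1 for k in ks) or any(c <= 0 for c in cs):
            raise ValueError("grid contains invalid k or C values")
        if list(ks) != sorted(set(ks)) or list(cs) != sorted(set(cs)):
            raise ValueError("grid axes must be strictly increasing")

    def configs(self) -> Iterable[PipelineConfig]:
        """All (k, C) combinations in tie-break order: smaller k, then C."""
        for k in self.k_values:
            for c in self.c_values:
                yield PipelineConfig(k_features=k, c_value=c)


#: Default tuning grid.  Endpoints follow the study design (k from 20 to 55,
#: C from 0.01 to 10); interior points cover the optima that small-sample
#: radiomics fits typically land on.
DEFAULT_GRID = HyperGrid(
    k_values=(20, 25, 30, 35, 40, 45, 50, 55),
    c_values=(0.01, 0.03, 0.09, 0.3, 0.9, 1.5, 3.0, 8.0, 10.0),
)

_TOL = 1e-6
_MAX_ITER = 10_000


def anova_f_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-group one-way ANOVA F statistic per feature (vectorized).

    F = (between-group SS / 1) / (within-group SS / (n - 2)).  Degenerate
    features follow fixed rules: zero within- and between-group SS -> 0;
    zero within-group SS with separation -> +inf (ranked above any finite
    score).  Equals the squared pooled-variance two-sample t statistic.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.shape[0]
    mask1 = labels == 1
    n1 = int(mask1.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    if n < 3:
        raise ValueError("need at least 3 samples for a two-group F test")
    mean0 = values[~mask1].mean(axis=0)
    mean1 = values[mask1].mean(axis=0)
    grand = values.mean(axis=0)
    ssb = n0 * (mean0 - grand) ** 2 + n1 * (mean1 - grand) ** 2
    ssw = ((values[~mask1] - mean0) ** 2).sum(axis=0)
    ssw += ((values[mask1] - mean1) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / (n - 2))
    f = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    return np.asarray(f, dtype=float)


def select_top_k(f_scores: Sequence[float], k: int) -> np.ndarray:
    """Indices of the k largest scores; ties broken by lowest index."""
    scores = np.asarray(f_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, scores.size)
    # lexsort: primary key -scores (descending), secondary key index (asc).
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:k])  # return in feature order for stable columns


@dataclass(frozen=True)
class FittedPipeline:
    """Frozen training-set parameters of one fitted model."""

    feature_means: np.ndarray
    feature_sds: np.ndarray
    selected_idx: np.ndarray
    coefficients: np.ndarray
    intercept: float
    config: PipelineConfig
    converged: bool = True
    f_scores: np.ndarray = field(default=None, repr=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "selected_idx": self.selected_idx.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "config": {
                "k_features": self.config.k_features,
                "c_value": self.config.c_value,
                "classifier": self.config.classifier,
            },
            "converged": self.converged,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "FittedPipeline":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        d = json.loads(text)
        return cls(
            feature_means=np.asarray(d["feature_means"], float),
            feature_sds=np.asarray(d["feature_sds"], float),
            selected_idx=np.asarray(d["selected_idx"], int),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            config=PipelineConfig(**d["config"]),
            converged=bool(d["converged"]),
        )


def _standardize_params(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)  # zero-variance columns map to 0
    return means, sds


def _fit_classifier(
    x: np.ndarray, y: np.ndarray, config: PipelineConfig
) -> tuple[np.ndarray, float, bool]:
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if config.classifier == "l1_logistic":
            clf = LogisticRegression(
                penalty="l1",
                C=config.c_value,
                solver="liblinear",
                tol=_TOL,
                max_iter=_MAX_ITER,
                random_state=0,
            )
        else:
            clf = SVC(kernel="linear", C=config.c_value, tol=_TOL)
        clf.fit(x, y)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    return clf.coef_.ravel().copy(), float(clf.intercept_[0]), converged


def fit_pipeline(train: FeatureTable, config: PipelineConfig) -> FittedPipeline:
    """Fit standardizer, selector and classifier on the training table only.

    F scores are computed on the standardized features (the two-group F is
    invariant to per-feature affine maps, so this is equivalent to scoring
    the raw features); zero-variance columns get F = 0 and can never be
    selected.
    """
    means, sds = _standardize_params(train.values)
    z = (train.values - means) / sds
    f = anova_f_scores(z, train.labels)
    f = np.where(train.values.std(axis=0) == 0, 0.0, f)
    selected = select_top_k(f, config.k_features)
    coef, intercept, converged = _fit_classifier(
        z[:, selected], train.labels, config
    )
    return FittedPipeline(
        feature_means=means,
        feature_sds=sds,
        selected_idx=selected,
        coefficients=coef,
        intercept=intercept,
        config=config,
        converged=converged,
        f_scores=f,
    )


def predict_scores(model: FittedPipeline, table: FeatureTable) -> np.ndarray:
    """Continuous decision scores (monotone in class-1 probability)."""
    if table.n_features != model.feature_means.size:
        raise ValueError(
            f"table has {table.n_features} features; model was trained on "
            f"{model.feature_means.size}"
        )
    z = (table.values - model.feature_means) / model.feature_sds
    return z[:, model.selected_idx] @ model.coefficients + model.intercept


@dataclass(frozen=True)
class GridSearchResult:
    """Winning configuration of a grid search with its internal CV estimate."""

    best_config: PipelineConfig
    best_score: float  # mean CV AUC — the trial's internal estimate
    best_fold_aucs: np.ndarray
    scores: dict  # (k, C) -> mean CV AUC for the whole grid

    def __iter__(self):  # allow (config, score) unpacking
        return iter((self.best_config, self.best_score))


def grid_search(
    train: FeatureTable,
    grid: HyperGrid,
    n_folds: int = 5,
    seed: int = 0,
    classifier: str = "l1_logistic",
) -> GridSearchResult:
    """Stratified-CV grid search over (k, C) on a shared fold assignment.

    Every configuration is scored on the same folds; the winner maximizes
    the mean fold AUC, ties broken by smaller k then smaller C.  Per fold,
    standardization and F-ranking are computed once and shared across the
    grid — exactly what refitting the full pipeline per configuration would
    produce, since selection depends on the configuration only through k.
    """
    from .resampling import FoldAssignment  # deferred: avoid module cycle
    from .metrics import auc_mann_whitney

    folds = FoldAssignment.stratified(train.labels, n_folds, seed)
    fold_cache = []
    for fold in range(n_folds):
        tr_idx = np.where(folds.fold_of_sample != fold)[0]
        te_idx = np.where(folds.fold_of_sample == fold)[0]
        xtr, ytr = train.values[tr_idx], train.labels[tr_idx]
        means, sds = _standardize_params(xtr)
        ztr = (xtr - means) / sds
        f = anova_f_scores(ztr, ytr)
        f = np.where(xtr.std(axis=0) == 0, 0.0, f)
        zte = (train.values[te_idx] - means) / sds
        fold_cache.append((ztr, ytr, f, zte, train.labels[te_idx]))

    scores: dict = {}
    best = None
    for config in grid.configs():
        if config.classifier != classifier:
            config = PipelineConfig(
                config.k_features, config.c_value, classifier
            )
        fold_aucs = np.empty(n_folds)
        for i, (ztr, ytr, f, zte, yte) in enumerate(fold_cache):
            sel = select_top_k(f, config.k_features)
            coef, intercept, _ = _fit_classifier(ztr[:, sel], ytr, config)
            fold_aucs[i] = auc_mann_whitney(zte[:, sel] @ coef + intercept, yte)
        mean_auc = float(fold_aucs.mean())
        scores[(config.k_features, config.c_value)] = mean_auc
        if best is None or mean_auc > best[1]:  # strict: earlier config wins ties
            best = (config, mean_auc, fold_aucs.copy())
    return GridSearchResult(
        best_config=best[0],
        best_score=best[1],
        best_fold_aucs=best[2],
        scores=scores,
    )
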