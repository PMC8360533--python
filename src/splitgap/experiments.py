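"""Experiment orchestration: repeated-split trials, arms, the feature-count
sweep, the validation-method comparison, and the two-feature mismatch demo.

The central object of study is a *trial*: one random stratified train-test
split of a feature table, hyperparameter tuning by grid-search CV on the
training part, and evaluation on the held-out part.  Repeating the trial
over many split seeds exposes how much the internal estimate, the test
AUC, and the gap between them (the optimism) depend on the split alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .datasets import FeatureTable
from .metrics import (
    DeLongResult,
    GapRecord,
    TrialSummary,
    auc_mann_whitney,
    delong_variance_ci,
    generalization_gap,
    summarize_trials,
)
from .pipeline import (
    DEFAULT_GRID,
    HyperGrid,
    PipelineConfig,
    _fit_classifier,
    _standardize_params,
    anova_f_scores,
    fit_pipeline,
    grid_search,
    predict_scores,
    select_top_k,
)
from .resampling import (
    ValidationEstimate,
    bootstrap_oob_estimate,
    cv_estimate,
    nested_cv_estimate,
    repeated_cv_estimate,
    stratified_split,
    undersample,
)
from .synthetic import GeneratorConfig, generate_dataset

__all__ = [
    "ArmSpec",
    "TrialResult",
    "ArmResult",
    "SweepResult",
    "ComparisonReport",
    "MismatchDemo",
    "run_trial",
    "run_arm",
    "standard_arms",
    "select_mismatch_trials",
    "feature_count_sweep",
    "compare_validation_methods",
    "mismatch_demo",
]

logger = logging.getLogger("splitgap")


# ---------------------------------------------------------------------------
# Trials and arms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialResult:
    """Outcome of one random train-test split."""

    seed: int
    chosen_k: int
    chosen_c: float
    estimate_auc: float
    estimate_sd: float
    test_auc: float
    test_ci: DeLongResult
    gap: GapRecord
    converged: bool

    def as_row(self) -> dict:
        return {
            "seed": self.seed,
            "chosen_k": self.chosen_k,
            "chosen_c": self.chosen_c,
            "estimate_auc": self.estimate_auc,
            "estimate_sd": self.estimate_sd,
            "test_auc": self.test_auc,
            "test_ci_low": self.test_ci.ci_low,
            "test_ci_high": self.test_ci.ci_high,
            "optimism": self.gap.optimism,
            "printed_difference": self.gap.printed_difference,
            "converged": self.converged,
        }


def run_trial(
    table: FeatureTable,
    seed: int,
    train_fraction: float = 0.7,
    grid: HyperGrid = DEFAULT_GRID,
    n_folds: int = 5,
) -> TrialResult:
    """One split -> tune -> refit -> test cycle, fully determined by the seed.

    The internal estimate is the winning configuration's mean grid-search
    CV AUC; the test AUC comes with a DeLong 95% confidence interval.
    """
    split = stratified_split(table, train_fraction, seed)
    train = table.subset(split.train_idx)
    test = table.subset(split.test_idx)
    gs = grid_search(train, grid, n_folds=n_folds, seed=child_seed(seed, "grid"))
    model = fit_pipeline(train, gs.best_config)
    test_scores = predict_scores(model, test)
    test_ci = delong_variance_ci(test_scores, test.labels)
    gap = generalization_gap(gs.best_score, test_ci.auc)
    return TrialResult(
        seed=int(seed),
        chosen_k=gs.best_config.k_features,
        chosen_c=gs.best_config.c_value,
        estimate_auc=gs.best_score,
        estimate_sd=float(np.std(gs.best_fold_aucs, ddof=1)),
        test_auc=test_ci.auc,
        test_ci=test_ci,
        gap=gap,
        converged=model.converged,
    )


@dataclass(frozen=True)
class ArmSpec:
    """One dataset arm of the split-stability experiment.

    ``source`` is either a ready :class:`FeatureTable` or a
    :class:`GeneratorConfig` to draw one from.  Undersampling, when
    requested, happens once per arm (with a dedicated arm seed), after
    which every trial re-splits the same reduced table.
    """

    name: str
    source: FeatureTable | GeneratorConfig
    n_trials: int = 1000
    undersample_fraction: float | None = None
    train_fraction: float = 0.7
    grid: HyperGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def resolve_table(self, arm_seed: int = 0) -> FeatureTable:
        table = (
            generate_dataset(self.source)
            if isinstance(self.source, GeneratorConfig)
            else self.source
        )
        if self.undersample_fraction is not None:
            table = undersample(
                table,
                self.undersample_fraction,
                child_seed(arm_seed, "undersample", self.name),
            )
        return table


@dataclass(frozen=True)
class ArmResult:
    """All trials of one arm plus their across-trial summary."""

    arm: ArmSpec
    table: FeatureTable
    trials: tuple[TrialResult, ...]
    summary: TrialSummary
    failures: tuple[tuple[int, str], ...] = field(default=())

    def trials_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_row() for t in self.trials])

    def summary_dict(self) -> dict:
        return {
            "arm": self.arm.name,
            "n_trials": self.summary.n_trials,
            "n_samples": self.table.n_samples,
            "class_counts": list(self.table.class_counts()),
            "mean_test_auc": self.summary.mean_test_auc,
            "sd_test_auc": self.summary.sd_test_auc,
            "mean_optimism": self.summary.mean_optimism,
            "sd_optimism": self.summary.sd_optimism,
            "n_failures": len(self.failures),
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.trials_dataframe().to_csv(
            out_dir / f"{self.arm.name}_trials.csv", index=False
        )
        (out_dir / f"{self.arm.name}_summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2) + "\n"
        )


def run_arm(
    arm: ArmSpec,
    arm_seed: int = 0,
    n_folds: int = 5,
    out_dir: str | Path | None = None,
) -> ArmResult:
    """Run ``arm.n_trials`` trials with split seeds 0..n_trials-1.

    Individual trial failures are recorded and skipped; the arm fails if
    more than 5% of its trials do.
    """
    table = arm.resolve_table(arm_seed)
    trials: list[TrialResult] = []
    failures: list[tuple[int, str]] = []
    for seed in range(arm.n_trials):
        try:
            trials.append(
                run_trial(table, seed, arm.train_fraction, arm.grid, n_folds)
            )
        except Exception as exc:  # noqa: BLE001 — logged and counted
            logger.warning("arm %s trial seed=%d failed: %s", arm.name, seed, exc)
            failures.append((seed, str(exc)))
    if len(failures) > 0.05 * arm.n_trials:
        raise RuntimeError(
            f"arm {arm.name}: {len(failures)}/{arm.n_trials} trials failed"
        )
    summary = summarize_trials([t.gap for t in trials])
    result = ArmResult(
        arm=arm,
        table=table,
        trials=tuple(trials),
        summary=summary,
        failures=tuple(failures),
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def standard_arms(
    n_trials: int = 1000,
    p_total: int = 400,
    grid: HyperGrid = DEFAULT_GRID,
    generator_seed: int = 0,
    simple_auc: float | None = None,
    difficult_auc: float | None = None,
) -> list[ArmSpec]:
    """The four study arms: {simple, difficult} x {full, 50% undersampled}.

    The simple arm uses class counts 109 vs. 58 calibrated to oracle AUC
    0.95; the difficult arm 163 vs. 95 at oracle AUC 0.78.  Each task's
    undersampled variant shares the same generated table (the reduction
    happens once per arm inside :func:`run_arm`).
    """
    from dataclasses import replace

    from .synthetic import (
        DIFFICULT_TASK_AUC,
        SIMPLE_TASK_AUC,
        calibrate_shift,
    )

    tasks = {
        "simple": (109, 58, simple_auc or SIMPLE_TASK_AUC),
        "difficult": (163, 95, difficult_auc or DIFFICULT_TASK_AUC),
    }
    arms = []
    for task, (n0, n1, target) in tasks.items():
        skeleton = GeneratorConfig(
            n_class0=n0,
            n_class1=n1,
            p_total=p_total,
            seed=child_seed(generator_seed, "table", task),
        )
        config = replace(skeleton, delta=calibrate_shift(target, skeleton))
        arms.append(
            ArmSpec(name=f"{task}_full", source=config, n_trials=n_trials,
                    grid=grid)
        )
        arms.append(
            ArmSpec(
                name=f"{task}_under",
                source=config,
                n_trials=n_trials,
                undersample_fraction=0.5,
                grid=grid,
            )
        )
    return arms


# ---------------------------------------------------------------------------
# Feature-count sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """Internal-estimate and test AUC per (split seed, feature count k)."""

    k_values: np.ndarray
    seeds: np.ndarray
    estimate_aucs: np.ndarray  # shape (n_seeds, n_k)
    test_aucs: np.ndarray  # shape (n_seeds, n_k)
    fixed_c: float

    def percentage_gap_curve(self) -> pd.DataFrame:
        """Mean percentage gap 100*(estimate - test)/estimate vs. k, with a
        normal-approximation 95% CI across split seeds."""
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (self.estimate_aucs - self.test_aucs) / self.estimate_aucs
        mean = pct.mean(axis=0)
        n = pct.shape[0]
        se = pct.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
        return pd.DataFrame(
            {
                "k": self.k_values,
                "mean_pct_gap": mean,
                "ci_low": mean - 1.96 * se,
                "ci_high": mean + 1.96 * se,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, seed in enumerate(self.seeds):
            for j, k in enumerate(self.k_values):
                rows.append(
                    {
                        "seed": int(seed),
                        "k": int(k),
                        "estimate_auc": self.estimate_aucs[i, j],
                        "test_auc": self.test_aucs[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _cv_and_test_over_k(
    train: FeatureTable,
    test: FeatureTable,
    k_values: np.ndarray,
    c_value: float,
    n_folds: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean CV AUC and test AUC for every k at fixed C.

    Standardization and F-ranking are computed once per fold (and once on
    the full training set); only the classifier refits per k.  Identical to
    refitting the whole pipeline at each k, since the ranking is k-free.
    """
    from .resampling import FoldAssignment

    config_for = lambda k: PipelineConfig(k_features=int(k), c_value=c_value)
    folds = FoldAssignment.stratified(train.labels, n_folds, seed)
    cv_aucs = np.zeros((n_folds, k_values.size))
    for fold in range(n_folds):
        tr = np.where(folds.fold_of_sample != fold)[0]
        te = np.where(folds.fold_of_sample == fold)[0]
        xtr, ytr = train.values[tr], train.labels[tr]
        means, sds = _standardize_params(xtr)
        ztr = (xtr - means) / sds
        f = anova_f_scores(ztr, ytr)
        f = np.where(xtr.std(axis=0) == 0, 0.0, f)
        zte = (train.values[te] - means) / sds
        yte = train.labels[te]
        for j, k in enumerate(k_values):
            sel = select_top_k(f, int(k))
            coef, intercept, _ = _fit_classifier(ztr[:, sel], ytr, config_for(k))
            cv_aucs[fold, j] = auc_mann_whitney(zte[:, sel] @ coef + intercept, yte)
    means, sds = _standardize_params(train.values)
    ztr = (train.values - means) / sds
    f = anova_f_scores(ztr, train.labels)
    f = np.where(train.values.std(axis=0) == 0, 0.0, f)
    zte = (test.values - means) / sds
    test_aucs = np.empty(k_values.size)
    for j, k in enumerate(k_values):
        sel = select_top_k(f, int(k))
        coef, intercept, _ = _fit_classifier(ztr[:, sel], train.labels, config_for(k))
        test_aucs[j] = auc_mann_whitney(zte[:, sel] @ coef + intercept, test.labels)
    return cv_aucs.mean(axis=0), test_aucs


def feature_count_sweep(
    table: FeatureTable,
    seeds: Sequence[int],
    k_max: int,
    fixed_c: float = 1.0,
    train_fraction: float = 0.7,
    n_folds: int = 5,
    k_values: Sequence[int] | None = None,
) -> SweepResult:
    """For each split seed, sweep the number of selected features k.

    Records the 5-fold CV estimate and the test AUC at every k with the
    regularization strength held at ``fixed_c``; k runs 1..k_max unless an
    explicit ``k_values`` subset is given.
    """
    if k_max > table.n_features:
        raise ValueError("k_max exceeds the number of features")
    ks = (
        np.arange(1, k_max + 1)
        if k_values is None
        else np.asarray(sorted(set(int(k) for k in k_values)))
    )
    seeds = np.asarray(list(seeds), dtype=int)
    est = np.empty((seeds.size, ks.size))
    test_auc = np.empty((seeds.size, ks.size))
    for i, seed in enumerate(seeds):
        split = stratified_split(table, train_fraction, int(seed))
        train = table.subset(split.train_idx)
        test = table.subset(split.test_idx)
        est[i], test_auc[i] = _cv_and_test_over_k(
            train, test, ks, fixed_c, n_folds, child_seed(int(seed), "sweep")
        )
    return SweepResult(
        k_values=ks, seeds=seeds, estimate_aucs=est, test_aucs=test_auc,
        fixed_c=float(fixed_c),
    )


# ---------------------------------------------------------------------------
# Validation-method comparison
# ---------------------------------------------------------------------------

_METHODS = ("cv", "repeated_cv", "nested_cv", "bootstrap")


@dataclass(frozen=True)
class ComparisonReport:
    """Four validation estimators on moderately vs. severely optimistic trials.

    ``records`` holds one row per (group, trial, method) with the method's
    training estimate, the trial's test AUC, and their difference;
    ``table`` aggregates median (min, max) per group and method.
    """

    records: pd.DataFrame
    settings: dict

    def group_table(self) -> pd.DataFrame:
        rows = []
        for (group, method), sub in self.records.groupby(
            ["group", "method"], sort=False
        ):
            rows.append(
                {
                    "group": group,
                    "method": method,
                    "training_auc_median": sub["training_auc"].median(),
                    "training_auc_min": sub["training_auc"].min(),
                    "training_auc_max": sub["training_auc"].max(),
                    "test_auc_median": sub["test_auc"].median(),
                    "test_auc_min": sub["test_auc"].min(),
                    "test_auc_max": sub["test_auc"].max(),
                    "difference_median": sub["difference"].median(),
                    "difference_min": sub["difference"].min(),
                    "difference_max": sub["difference"].max(),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "settings": self.settings,
            "groups": self.group_table().to_dict(orient="records"),
            "records": self.records.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def select_mismatch_trials(
    trials: Sequence[TrialResult], n_select: int
) -> tuple[list[TrialResult], list[TrialResult]]:
    """Severe and moderate optimistic-trial groups.

    Among trials whose internal estimate exceeded the test AUC, *severe* is
    the ``n_select`` with the largest optimism; *moderate* is the
    ``n_select`` (of the rest) whose optimism lies closest to the median
    optimism of all optimistic trials.
    """
    optimistic = [t for t in trials if t.gap.optimism > 0]
    if len(optimistic) < 2 * n_select:
        raise ValueError(
            f"need at least {2 * n_select} optimistic trials, "
            f"found {len(optimistic)}"
        )
    by_optimism = sorted(optimistic, key=lambda t: -t.gap.optimism)
    severe = by_optimism[:n_select]
    median = float(np.median([t.gap.optimism for t in optimistic]))
    rest = by_optimism[n_select:]
    moderate = sorted(rest, key=lambda t: abs(t.gap.optimism - median))[:n_select]
    return severe, moderate


def _trial_estimates(
    trial: TrialResult,
    table: FeatureTable,
    grid: HyperGrid,
    train_fraction: float,
    n_folds: int,
    n_repeats: int,
    n_draws: int,
) -> dict[str, ValidationEstimate]:
    split = stratified_split(table, train_fraction, trial.seed)
    train = table.subset(split.train_idx)
    config = PipelineConfig(k_features=trial.chosen_k, c_value=trial.chosen_c)
    # Plain CV reuses the trial's tuning folds, so it reproduces the
    # internal estimate the trial actually reported (selection optimism
    # included); the other methods get independent derived streams.
    gs = grid_search(
        train, grid, n_folds=n_folds, seed=child_seed(trial.seed, "grid")
    )
    return {
        "cv": ValidationEstimate.from_replicates(
            "cv", gs.best_fold_aucs, {"n_folds": n_folds}
        ),
        "repeated_cv": repeated_cv_estimate(
            train, config, n_folds, n_repeats, child_seed(trial.seed, "rep")
        ),
        "nested_cv": nested_cv_estimate(
            train, grid, n_folds, n_folds, child_seed(trial.seed, "nested")
        ),
        "bootstrap": bootstrap_oob_estimate(
            train, config, n_draws, child_seed(trial.seed, "boot")
        ),
    }


def compare_validation_methods(
    trials: Sequence[TrialResult],
    table: FeatureTable,
    n_select: int = 10,
    grid: HyperGrid = DEFAULT_GRID,
    train_fraction: float = 0.7,
    n_folds: int = 5,
    n_repeats: int = 10,
    n_draws: int = 10,
) -> ComparisonReport:
    """Do fancier internal-validation estimators correct the optimism?

    Re-estimates the training performance of the severely and moderately
    optimistic trials with plain CV, repeated CV (m=10), nested CV, and
    bootstrap out-of-bag (B=10), and tabulates training estimate, test AUC,
    and their difference per group.
    """
    severe, moderate = select_mismatch_trials(trials, n_select)
    rows = []
    for group, members in (("moderate", moderate), ("severe", severe)):
        for trial in members:
            estimates = _trial_estimates(
                trial, table, grid, train_fraction, n_folds, n_repeats, n_draws
            )
            for method in _METHODS:
                est = estimates[method].point_estimate
                rows.append(
                    {
                        "group": group,
                        "trial_seed": trial.seed,
                        "method": method,
                        "training_auc": est,
                        "test_auc": trial.test_auc,
                        "difference": est - trial.test_auc,
                    }
                )
    return ComparisonReport(
        records=pd.DataFrame(rows),
        settings={
            "n_select": n_select,
            "n_folds": n_folds,
            "n_repeats": n_repeats,
            "n_draws": n_draws,
            "train_fraction": train_fraction,
        },
    )


# ---------------------------------------------------------------------------
# Two-feature mismatch demonstration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MismatchDemo:
    """Everything needed to redraw the two-feature decision-boundary plot."""

    points: pd.DataFrame  # sample_id, f1, f2 (standardized), label, in_test, score
    feature_names: tuple[str, str]
    boundary: tuple[float, float, float]  # w1, w2, b in standardized space
    cv_auc: float
    cv_sd: float
    test_ci: DeLongResult
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.points.to_csv(out_dir / f"mismatch_seed{self.seed}_points.csv",
                           index=False)
        payload = {
            "seed": self.seed,
            "feature_names": list(self.feature_names),
            "w1": self.boundary[0],
            "w2": self.boundary[1],
            "b": self.boundary[2],
            "cv_auc": self.cv_auc,
            "cv_sd": self.cv_sd,
            "test_auc": self.test_ci.auc,
            "test_ci_low": self.test_ci.ci_low,
            "test_ci_high": self.test_ci.ci_high,
        }
        (out_dir / f"mismatch_seed{self.seed}_boundary.json").write_text(
            json.dumps(payload, indent=2) + "\n"
        )


def mismatch_demo(
    table: FeatureTable,
    seed: int,
    train_fraction: float = 0.7,
    n_folds: int = 5,
    c_value: float = 1.0,
) -> MismatchDemo:
    """Fit a linear SVM on the top-2 F-ranked features for one split.

    Exposes how a particular random split can place the two classes
    differently in feature space: the boundary that separates the training
    points may sit badly for the test points, and vice versa.
    """
    if table.n_features < 2:
        raise ValueError("mismatch demo needs at least 2 features")
    split = stratified_split(table, train_fraction, seed)
    train = table.subset(split.train_idx)
    config = PipelineConfig(k_features=2, c_value=c_value, classifier="linear_svm")
    model = fit_pipeline(train, config)
    cv = cv_estimate(train, config, n_folds, child_seed(seed, "grid"))
    scores = predict_scores(model, table)
    z = (table.values - model.feature_means) / model.feature_sds
    f1, f2 = (int(i) for i in model.selected_idx)
    in_test = np.zeros(table.n_samples, dtype=bool)
    in_test[split.test_idx] = True
    points = pd.DataFrame(
        {
            "sample_id": list(table.sample_ids),
            "f1": z[:, f1],
            "f2": z[:, f2],
            "label": table.labels,
            "in_test": in_test,
            "score": scores,
        }
    )
    test_scores = scores[split.test_idx]
    test_ci = delong_variance_ci(test_scores, table.labels[split.test_idx])
    return MismatchDemo(
        points=points,
        feature_names=(table.feature_names[f1], table.feature_names[f2]),
        boundary=(
            float(model.coefficients[0]),
            float(model.coefficients[1]),
            float(model.intercept),
        ),
        cv_auc=cv.point_estimate,
        cv_sd=cv.spread,
        test_ci=test_ci,
        seed=int(seed),
    )
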