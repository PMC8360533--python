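"""Splits, undersampling, folds, and the four validation estimators."""

import numpy as np
import pytest

from splitgap import (
    FeatureTable,
    FoldAssignment,
    GeneratorConfig,
    HyperGrid,
    PipelineConfig,
    auc_mann_whitney,
    bootstrap_oob_estimate,
    cv_estimate,
    fit_pipeline,
    generate_dataset,
    nested_cv_estimate,
    predict_scores,
    repeated_cv_estimate,
    stratified_split,
    undersample,
)
from splitgap._seeds import child_seed
from splitgap.resampling import bootstrap_draw


def make_table(n0, n1, p=5, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureTable(
        values=rng.normal(size=(n0 + n1, p)),
        labels=np.concatenate([np.zeros(n0, int), np.ones(n1, int)]),
    )


class TestStratifiedSplit:
    def test_per_class_floor_counts(self):
        table = make_table(109, 58)
        split = stratified_split(table, 0.7, seed=0)
        train_labels = table.labels[split.train_idx]
        test_labels = table.labels[split.test_idx]
        assert ((train_labels == 0).sum(), (train_labels == 1).sum()) == (76, 40)
        assert ((test_labels == 0).sum(), (test_labels == 1).sum()) == (33, 18)

    def test_partition_and_determinism(self):
        table = make_table(30, 20)
        a = stratified_split(table, 0.6, seed=42)
        b = stratified_split(table, 0.6, seed=42)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)
        union = np.sort(np.concatenate([a.train_idx, a.test_idx]))
        np.testing.assert_array_equal(union, np.arange(50))
        assert np.intersect1d(a.train_idx, a.test_idx).size == 0

    def test_membership_frequency_matches_fraction(self):
        # class sizes with integral n_c * fraction, so the floor rule is
        # unbiased and each sample should land in train 70% of the time
        table = make_table(20, 10)
        hits = np.zeros(table.n_samples)
        n_seeds = 10_000
        for seed in range(n_seeds):
            split = stratified_split(table, 0.7, seed)
            hits[split.train_idx] += 1
        freq = hits / n_seeds
        assert np.abs(freq - 0.7).max() < 0.02

    def test_infeasible_split_raises(self):
        table = make_table(3, 3)
        with pytest.raises(ValueError):
            stratified_split(table, 0.1, seed=0)  # train would lose a class


class TestUndersample:
    def test_meningioma_counts(self):
        table = make_table(163, 95)
        reduced = undersample(table, 0.5, seed=1)
        assert reduced.class_counts() == (81, 47)

    def test_full_fraction_is_identity(self):
        table = make_table(10, 8)
        reduced = undersample(table, 1.0, seed=3)
        np.testing.assert_array_equal(reduced.values, table.values)
        np.testing.assert_array_equal(reduced.labels, table.labels)

    def test_retained_ids_are_a_subset(self):
        table = make_table(20, 12)
        reduced = undersample(table, 0.5, seed=9)
        assert set(reduced.sample_ids) <= set(table.sample_ids)

    def test_too_small_class_raises(self):
        table = make_table(10, 3)
        with pytest.raises(ValueError):
            undersample(table, 0.5, seed=0)


class TestFoldAssignment:
    def test_stratified_balance_and_determinism(self):
        labels = np.concatenate([np.zeros(23, int), np.ones(17, int)])
        a = FoldAssignment.stratified(labels, 5, seed=3)
        b = FoldAssignment.stratified(labels, 5, seed=3)
        np.testing.assert_array_equal(a.fold_of_sample, b.fold_of_sample)
        for cls in (0, 1):
            sizes = np.bincount(a.fold_of_sample[labels == cls], minlength=5)
            assert sizes.max() - sizes.min() <= 1
            assert sizes.min() >= 1

    def test_small_class_rejected(self):
        labels = np.concatenate([np.zeros(10, int), np.ones(3, int)])
        with pytest.raises(ValueError):
            FoldAssignment.stratified(labels, 5, seed=0)


class TestCVEstimate:
    def test_separable_data_scores_one(self, separable_table):
        est = cv_estimate(separable_table, PipelineConfig(3, 1.0), 5, seed=0)
        assert est.point_estimate == 1.0

    def test_point_estimate_is_mean_of_replicates(self, signal_table):
        est = cv_estimate(signal_table, PipelineConfig(5, 1.0), 5, seed=1)
        assert est.point_estimate == pytest.approx(
            est.replicate_aucs.mean(), abs=1e-15
        )
        assert np.all((est.replicate_aucs >= 0) & (est.replicate_aucs <= 1))

    def test_matches_explicit_fold_loop(self, signal_table):
        config = PipelineConfig(6, 0.9)
        seed = 21
        est = cv_estimate(signal_table, config, 4, seed=seed)
        folds = FoldAssignment.stratified(signal_table.labels, 4, seed)
        expected = []
        for fold in range(4):
            tr = np.where(folds.fold_of_sample != fold)[0]
            te = np.where(folds.fold_of_sample == fold)[0]
            model = fit_pipeline(signal_table.subset(tr), config)
            scores = predict_scores(model, signal_table.subset(te))
            expected.append(auc_mann_whitney(scores, signal_table.labels[te]))
        np.testing.assert_array_equal(est.replicate_aucs, expected)

    def test_permuted_labels_score_near_half(self):
        rng = np.random.default_rng(55)
        x = rng.normal(size=(60, 10))
        config = PipelineConfig(3, 1.0)
        estimates = []
        for rep in range(50):
            labels = np.concatenate([np.zeros(30, int), np.ones(30, int)])
            rng.shuffle(labels)
            table = FeatureTable(values=x, labels=labels)
            estimates.append(
                cv_estimate(table, config, 5, seed=rep).point_estimate
            )
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.05)


class TestRepeatedCV:
    def test_single_repeat_equals_cv_with_derived_seed(self, signal_table):
        config = PipelineConfig(5, 1.0)
        rep = repeated_cv_estimate(signal_table, config, 5, 1, seed=8)
        single = cv_estimate(signal_table, config, 5, child_seed(8, "rep", 0))
        np.testing.assert_array_equal(rep.replicate_aucs, single.replicate_aucs)

    def test_replicate_bookkeeping(self, signal_table):
        rep = repeated_cv_estimate(
            signal_table, PipelineConfig(5, 1.0), 4, 3, seed=2
        )
        assert rep.replicate_aucs.size == 4 * 3
        assert rep.point_estimate == pytest.approx(rep.replicate_aucs.mean())

    def test_repetition_reduces_fold_assignment_noise(self, signal_table):
        # over master seeds, the repeated-CV point estimate varies less
        # than single CV on the same fixed table
        config = PipelineConfig(5, 1.0)
        singles, repeated = [], []
        for seed in range(25):
            singles.append(
                cv_estimate(signal_table, config, 5, seed).point_estimate
            )
            repeated.append(
                repeated_cv_estimate(
                    signal_table, config, 5, 4, seed
                ).point_estimate
            )
        assert np.var(repeated) < np.var(singles)


class TestNestedCV:
    def test_degenerate_grid_equals_plain_cv(self, signal_table):
        grid = HyperGrid(k_values=(5,), c_values=(1.0,))
        nested = nested_cv_estimate(signal_table, grid, 5, 3, seed=4)
        plain = cv_estimate(signal_table, PipelineConfig(5, 1.0), 5, seed=4)
        np.testing.assert_array_equal(
            nested.replicate_aucs, plain.replicate_aucs
        )

    def test_separable_data_scores_one(self, separable_table):
        grid = HyperGrid(k_values=(2, 3), c_values=(0.5, 1.0))
        nested = nested_cv_estimate(separable_table, grid, 4, 3, seed=1)
        assert nested.point_estimate == 1.0


class TestBootstrapOOB:
    def test_separable_data_scores_one(self, separable_table):
        est = bootstrap_oob_estimate(
            separable_table, PipelineConfig(3, 1.0), 5, seed=6
        )
        assert est.point_estimate == 1.0

    def test_oob_fraction_identity(self):
        # mean out-of-bag fraction over draws -> 1 - (1 - 1/n)^n ~ e^-1
        rng = np.random.default_rng(0)
        n = 258
        labels = np.concatenate([np.zeros(163, int), np.ones(95, int)])
        fractions = [
            bootstrap_draw(rng, labels)[1].size / n for _ in range(2000)
        ]
        expected = (1.0 - 1.0 / n) ** n  # ~ e^-1 ~ 0.368 at large n
        assert np.mean(fractions) == pytest.approx(expected, abs=0.01)

    def test_replicate_count_and_determinism(self, signal_table):
        config = PipelineConfig(5, 1.0)
        a = bootstrap_oob_estimate(signal_table, config, 7, seed=3)
        b = bootstrap_oob_estimate(signal_table, config, 7, seed=3)
        assert a.replicate_aucs.size == 7
        np.testing.assert_array_equal(a.replicate_aucs, b.replicate_aucs)


class TestNoSignalEstimators:
    def test_all_estimators_average_half_on_label_independent_data(
        self, noise_config
    ):
        from dataclasses import replace

        grid = HyperGrid(k_values=(3, 6), c_values=(0.3, 1.0))
        config = PipelineConfig(3, 1.0)
        means = {"cv": [], "repeated_cv": [], "nested_cv": [], "bootstrap": []}
        for rep in range(20):
            table = generate_dataset(replace(noise_config, seed=rep))
            means["cv"].append(
                cv_estimate(table, config, 5, rep).point_estimate
            )
            means["repeated_cv"].append(
                repeated_cv_estimate(table, config, 5, 2, rep).point_estimate
            )
            means["nested_cv"].append(
                nested_cv_estimate(table, grid, 3, 3, rep).point_estimate
            )
            means["bootstrap"].append(
                bootstrap_oob_estimate(table, config, 5, rep).point_estimate
            )
        for method, values in means.items():
            assert np.mean(values) == pytest.approx(0.5, abs=0.05), method
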