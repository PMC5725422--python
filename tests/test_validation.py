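"""Resampling engines: k-fold CV, bootstrap strategies A/B, permutation
tests, seeding and aggregation."""
import numpy as np
import pytest

from diliforest.io_types import DataError, MOST_DILI, NO_DILI
from diliforest.synthetic_data import GeneratorSpec, generate
from diliforest.validation import (
    ValidationConfig,
    bootstrap_A,
    bootstrap_B,
    kfold_split,
    run_bootstrap_validation,
    run_cross_validation,
    run_permutation_tests,
    summarize,
)


class TestKFoldSplit:
    def test_even_split(self):
        folds = kfold_split(10, 5, 0)
        assert [len(f) for f in folds] == [2] * 5

    def test_uneven_split_sizes(self):
        folds = kfold_split(721, 5, 1)
        assert sorted(len(f) for f in folds) == [144, 144, 144, 144, 145]

    def test_partition(self):
        folds = kfold_split(37, 5, 2)
        combined = np.sort(np.concatenate(folds))
        assert np.array_equal(combined, np.arange(37))

    def test_deterministic_in_seed(self):
        a = kfold_split(50, 5, 9)
        b = kfold_split(50, 5, 9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            kfold_split(4, 5, 0)


class TestBootstrapA:
    def test_out_of_boot_size_is_constant(self):
        for seed in range(20):
            boot, oob = bootstrap_A(451, 0.632, seed)
            assert len(oob) == 451 - int(np.ceil(0.632 * 451))
            assert len(set(boot)) == int(np.ceil(0.632 * 451))

    def test_boot_and_oob_are_complementary(self):
        boot, oob = bootstrap_A(100, 0.632, 3)
        assert set(boot) | set(oob) == set(range(100))
        assert not set(boot) & set(oob)

    def test_mean_boot_size_matches_coupon_collector(self):
        """Mean draw count over many seeds matches n*(H_n - H_{n-u}) within 1%."""
        n, frac = 60, 0.632
        u = int(np.ceil(frac * n))
        H = np.cumsum(1.0 / np.arange(1, n + 1))
        expected = n * (H[n - 1] - H[n - u - 1])
        sizes = [len(bootstrap_A(n, frac, s)[0]) for s in range(3000)]
        assert np.mean(sizes) == pytest.approx(expected, rel=0.01)

    def test_high_unique_fraction_leaves_tiny_out_of_boot(self):
        boot, oob = bootstrap_A(5, 0.999, 0)
        assert len(oob) == 0


class TestBootstrapB:
    def test_boot_size_is_n(self):
        for seed in range(10):
            boot, oob = bootstrap_B(73, seed)
            assert len(boot) == 73
            assert set(oob) == set(range(73)) - set(boot)

    def test_out_of_boot_fraction_near_inverse_e(self):
        fr = [len(bootstrap_B(400, s)[1]) / 400 for s in range(500)]
        assert np.mean(fr) == pytest.approx(np.exp(-1), abs=0.01)

    def test_n2_empty_out_of_boot_probability_half(self):
        # four equally likely draw sequences; two leave nothing out of boot
        empties = sum(len(bootstrap_B(2, s)[1]) == 0 for s in range(4000))
        assert empties / 4000 == pytest.approx(0.5, abs=0.04)


@pytest.fixture(scope="module")
def cv_table():
    return generate(
        GeneratorSpec(class_sizes={NO_DILI: 60, MOST_DILI: 40}, d_informative=5, d_noise=20,
                      effect_size=3.0, seed=10)
    ).table


class TestCrossValidation:
    def test_each_compound_scored_exactly_once_per_iteration(self, cv_table):
        cfg = ValidationConfig(mode="crossval", iterations=3, master_seed=1)
        res = run_cross_validation(cv_table, cfg)
        assert len(res.iterations) == 3
        for it in res.iterations:
            assert sorted(it.predictions["compound_id"]) == sorted(cv_table.compound_ids)

    def test_separable_data_scores_high(self, cv_table):
        cfg = ValidationConfig(mode="crossval", iterations=5, master_seed=2)
        res = run_cross_validation(cv_table, cfg)
        s = summarize(res)
        assert s["metrics"]["accuracy"]["mean"] > 0.9

    def test_reproducible_bitwise(self, cv_table):
        cfg = ValidationConfig(mode="crossval", iterations=2, master_seed=7)
        a = run_cross_validation(cv_table, cfg)
        b = run_cross_validation(cv_table, cfg)
        for ia, ib in zip(a.iterations, b.iterations):
            assert ia.predictions.equals(ib.predictions)
            assert ia.metrics == ib.metrics
            assert ia.descriptor_usage == ib.descriptor_usage

    def test_descriptor_usage_one_set_per_fold_model(self, cv_table):
        cfg = ValidationConfig(mode="crossval", k=5, iterations=2, master_seed=3)
        res = run_cross_validation(cv_table, cfg)
        for it in res.iterations:
            assert len(it.descriptor_usage) == 5


class TestBootstrapValidation:
    def test_strategy_a_constant_test_size(self, cv_table):
        cfg = ValidationConfig(mode="bootstrapA", iterations=4, master_seed=4)
        res = run_bootstrap_validation(cv_table, cfg)
        n = cv_table.n
        expected = n - int(np.ceil(0.632 * n))
        for it in res.iterations:
            assert len(it.predictions) == expected

    def test_strategy_b_varying_test_size(self, cv_table):
        cfg = ValidationConfig(mode="bootstrapB", iterations=6, master_seed=5)
        res = run_bootstrap_validation(cv_table, cfg)
        sizes = {len(it.predictions) for it in res.iterations}
        assert len(sizes) > 1

    def test_separable_data_scores_high(self, cv_table):
        cfg = ValidationConfig(mode="bootstrapA", iterations=5, master_seed=6)
        res = run_bootstrap_validation(cv_table, cfg)
        assert summarize(res)["metrics"]["accuracy"]["mean"] > 0.9

    def test_crossval_mode_rejected(self, cv_table):
        with pytest.raises(DataError):
            run_bootstrap_validation(cv_table, ValidationConfig(mode="crossval", iterations=1))


class TestPermutationTests:
    def test_label_multiset_conserved(self, cv_table):
        cfg = ValidationConfig(mode="permutation", iterations=2, master_seed=8)
        res = run_permutation_tests(cv_table, cfg)
        for it in res.iterations:
            assert sorted(it.predictions["actual"]) == sorted(cv_table.labels)

    def test_informative_signal_destroyed(self, cv_table):
        true_cfg = ValidationConfig(mode="crossval", iterations=5, master_seed=9)
        perm_cfg = ValidationConfig(mode="permutation", iterations=5, master_seed=9)
        acc_true = summarize(run_cross_validation(cv_table, true_cfg))["metrics"]["accuracy"]["mean"]
        acc_perm = summarize(run_permutation_tests(cv_table, perm_cfg))["metrics"]["accuracy"]["mean"]
        assert acc_perm < acc_true - 0.2

    def test_null_mcc_near_zero_small_scale(self):
        table = generate(
            GeneratorSpec(class_sizes={NO_DILI: 60, MOST_DILI: 40}, d_noise=25, seed=11)
        ).table
        cfg = ValidationConfig(mode="permutation", iterations=20, master_seed=12)
        s = summarize(run_permutation_tests(table, cfg))
        assert abs(s["metrics"]["mcc"]["mean"]) < 0.1
        assert 0.4 < s["metrics"]["balanced_accuracy"]["mean"] < 0.6


class TestSummarize:
    def test_mean_and_sample_sd(self, cv_table):
        cfg = ValidationConfig(mode="crossval", iterations=2, master_seed=13)
        res = run_cross_validation(cv_table, cfg)
        accs = [it.metrics.accuracy for it in res.iterations]
        s = summarize(res)["metrics"]["accuracy"]
        assert s["mean"] == pytest.approx(np.mean(accs))
        assert s["sd"] == pytest.approx(np.std(accs, ddof=1))

    def test_histogram_counts_sum_to_iterations(self, cv_table):
        cfg = ValidationConfig(mode="crossval", iterations=3, master_seed=14)
        s = summarize(run_cross_validation(cv_table, cfg))
        for name, entry in s["metrics"].items():
            assert sum(entry["histogram"]["counts"]) + entry["undefined"] == 3

    def test_constant_metric_zero_sd(self):
        cfg = ValidationConfig(mode="crossval", iterations=1, master_seed=0)
        table = generate(
            GeneratorSpec(class_sizes={NO_DILI: 30, MOST_DILI: 30}, d_informative=3,
                          d_noise=5, effect_size=4.0, seed=15)
        ).table
        s = summarize(run_cross_validation(table, cfg))
        assert s["metrics"]["accuracy"]["sd"] == 0.0
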