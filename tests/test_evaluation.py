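import numpy as np
import pytest

from penbayes import empirical_bayes as eb
from penbayes import synthetic_data as syn
from penbayes.evaluation import (binary_labels, brier_score, curve_points,
                                 kfold_evaluate, loocv_evaluate,
                                 loocv_prior_means, pr_auc, roc_auc,
                                 weighted_spearman)
from penbayes.variant_data import VariantTable
from conftest import make_record


def brute_force_auc(scores, labels):
    """All-pairs concordance with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def small_synth():
    return syn.generate(syn.SimulationConfig(
        n_variants=60, protein_length=80, seed=5,
        covariate_effects={"revel": 2.0}))


class TestBrierScore:
    def test_perfect_forecast_zero(self):
        assert brier_score([0.1, 0.9, 0.4], [0.1, 0.9, 0.4]) == 0.0

    def test_constant_half_on_binary(self):
        assert brier_score([0.5] * 4, [0, 1, 1, 0]) == pytest.approx(0.25)

    def test_arithmetic(self):
        assert brier_score([0.8, 0.2], [1, 0]) == pytest.approx(0.04)

    def test_shrinkage_beats_constant_prior(self, small_synth):
        """Posterior forecasts of observed penetrance beat the prior mean."""
        table = small_synth.table
        prior = eb.fit_empirical_prior(table)
        obs = [r.counts.affected / r.counts.total for r in table]
        post = [eb.empirical_posterior(r.counts, prior) for r in table]
        const = [prior.mean] * len(obs)
        assert brier_score(post, obs) <= brier_score(const, obs)


class TestWeightedSpearman:
    def test_monotone_transform_is_one(self):
        x = np.array([0.1, 0.5, 0.2, 0.9, 0.7])
        assert weighted_spearman(x, np.exp(3 * x)) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert weighted_spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_three_point_arithmetic(self):
        assert weighted_spearman([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5)

    def test_weights_change_result(self):
        x = [1, 2, 3, 4]
        y = [2, 1, 3, 4]
        eq = weighted_spearman(x, y)
        wt = weighted_spearman(x, y, [10, 10, 1, 1])
        assert wt < eq

    def test_constant_input_undefined(self):
        with pytest.raises(ValueError):
            weighted_spearman([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            weighted_spearman([1, 2], [2, 1])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1],
                              n_boot=50, seed=0)
        assert auc == 1.0

    def test_worked_example(self):
        auc, *_ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1],
                          n_boot=50, seed=0)
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_all_pairs_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.uniform(size=n), 2)  # induce ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        auc, *_ = roc_auc(scores, labels, n_boot=10, seed=0)
        assert auc == pytest.approx(brute_force_auc(scores, labels),
                                    abs=1e-12)

    def test_null_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=3000)
        labels = rng.integers(0, 2, size=3000)
        auc, lo, hi = roc_auc(scores, labels, n_boot=200, seed=1)
        assert auc == pytest.approx(0.5, abs=0.04)
        assert lo < 0.5 < hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_order_invariance(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        a1, *_ = roc_auc(scores, labels, n_boot=10, seed=0)
        a2, *_ = roc_auc(scores[::-1], labels[::-1], n_boot=10, seed=0)
        assert a1 == pytest.approx(a2)


class TestPrAuc:
    def test_perfect_separation(self):
        auc, *_ = pr_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1],
                         n_boot=50, seed=0)
        assert auc == pytest.approx(1.0)

    def test_one_positive_ranked_last(self):
        auc, *_ = pr_auc([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1],
                         n_boot=50, seed=0)
        assert auc == pytest.approx(0.25)

    def test_null_baseline_equals_prevalence(self):
        rng = np.random.default_rng(3)
        n, prev = 4000, 0.3
        labels = (rng.uniform(size=n) < prev).astype(int)
        scores = rng.uniform(size=n)
        auc, *_ = pr_auc(scores, labels, n_boot=10, seed=0)
        assert auc == pytest.approx(labels.mean(), abs=0.05)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn_average_precision(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(size=80), 2)
        labels = rng.integers(0, 2, size=80)
        if labels.sum() == 0:
            labels[0] = 1
        auc, *_ = pr_auc(scores, labels, n_boot=10, seed=0)
        assert auc == pytest.approx(
            sklearn_metrics.average_precision_score(labels, scores),
            abs=1e-12)

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.5, 0.4], [0, 0])


class TestCurvePoints:
    def test_roc_points_end_at_unity(self):
        df = curve_points([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], kind="roc")
        assert df["fpr"].iloc[-1] == pytest.approx(1.0)
        assert df["tpr"].iloc[-1] == pytest.approx(1.0)
        assert (df["tpr"].diff().dropna() >= 0).all()

    def test_pr_area_matches_pr_auc(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[0] = 1
        df = curve_points(scores, labels, kind="pr")
        area = float(np.sum(df["precision"]
                            * np.diff(np.r_[0.0, df["recall"]])))
        auc, *_ = pr_auc(scores, labels, n_boot=5, seed=0)
        assert area == pytest.approx(auc, abs=1e-12)


class TestBinaryLabels:
    def test_affected_rule(self):
        t = VariantTable([make_record(1, "A", "T", 1, 22),
                          make_record(2, "A", "T", 0, 44)])
        labels = binary_labels(t)
        assert labels[(1, "A", "T")] == 1
        assert labels[(2, "A", "T")] == 0

    def test_posterior_threshold_mode(self):
        t = VariantTable([make_record(1, "A", "T", 1, 1)])
        labels = binary_labels(t, mode="posterior",
                               posteriors={(1, "A", "T"): 0.6},
                               threshold=0.5)
        assert labels[(1, "A", "T")] == 1


class TestLoocv:
    def test_fold_count_and_no_leakage(self, small_synth):
        table = small_synth.table
        preds, skipped = loocv_prior_means(table, covariates=["revel"])
        assert skipped == 0
        assert set(preds) == set(table.keys())
        # leakage check: prediction unchanged when the held-out variant's
        # own counts are altered (its counts are never seen by its fold)
        from dataclasses import replace
        from penbayes.variant_data import HeterozygoteCounts
        key = table.keys()[0]
        perturbed = VariantTable(
            replace(r, counts=HeterozygoteCounts(r.counts.affected + 5,
                                                 r.counts.unaffected))
            if r.key == key else r for r in table)
        preds2, _ = loocv_prior_means(perturbed, covariates=["revel"])
        assert preds2[key] == pytest.approx(preds[key], abs=1e-12)

    def test_three_variant_toy(self):
        t = VariantTable([
            make_record(1, "A", "T", 2, 3, weight=0.9, revel=0.8),
            make_record(2, "G", "S", 0, 9, weight=0.9, revel=0.2),
            make_record(3, "C", "Y", 1, 4, weight=0.9, revel=0.5),
        ])
        preds, skipped = loocv_prior_means(t, covariates=["revel"])
        assert len(preds) + skipped == 3

    def test_reports_assembled(self, small_synth):
        reports = loocv_evaluate(small_synth.table, covariates=["revel"],
                                 n_boot=25)
        names = {r.covariate for r in reports}
        assert "bayes_prior_loocv" in names
        for r in reports:
            if r.brier is not None:
                assert np.isfinite(r.brier)


class TestKfold:
    def test_partition_contract(self, small_synth):
        rep = kfold_evaluate(small_synth.table, k=5, seed=1,
                             covariates=["revel"])
        folds = rep.extra["folds"]
        all_keys = [k for f in folds for k in f]
        assert sorted(all_keys) == sorted(small_synth.table.keys())
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_seed_determinism_and_row_order_invariance(self, small_synth):
        table = small_synth.table
        shuffled = VariantTable(list(table)[::-1])
        r1 = kfold_evaluate(table, k=4, seed=9, covariates=["revel"])
        r2 = kfold_evaluate(shuffled, k=4, seed=9, covariates=["revel"])
        assert r1.extra["folds"] == r2.extra["folds"]
        assert r1.spearman_weighted == pytest.approx(r2.spearman_weighted,
                                                     abs=1e-12)

    def test_k_exceeding_n_rejected(self):
        t = VariantTable([make_record(i, "A", "T", 1, 1) for i in (1, 2, 3)])
        with pytest.raises(ValueError):
            kfold_evaluate(t, k=5)
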