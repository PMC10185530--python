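"""Metrics, stratified reports and model-comparison statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from esp.data_io import PairRecord
from esp.evaluation import (ConfusionCounts, confusion, compute_metrics,
                            learning_curve, mannwhitney, mcc, mcnemar,
                            molecule_occurrence_report, roc_auc, roc_curve,
                            score_band_report, stratified_report)


class TestConfusion:
    def test_basic_counts(self):
        c = confusion([0.9, 0.1], [1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_half_score_is_positive_prediction(self):
        c = confusion([0.5], [0])
        assert c.fp == 1  # score >= 0.5 goes to the positive class

    def test_all_missed(self):
        c = confusion([0.0] * 5, [1] * 5)
        assert c.fn == 5 and c.n == 5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestMCC:
    def test_perfect_and_inverted(self):
        assert mcc(ConfusionCounts(5, 5, 0, 0)) == 1.0
        assert mcc(ConfusionCounts(0, 0, 5, 5)) == -1.0

    def test_direct_arithmetic(self):
        assert mcc(ConfusionCounts(tp=4, tn=3, fp=1, fn=2)) == pytest.approx(
            10 / math.sqrt(600))

    def test_undefined_reported_missing(self):
        assert mcc(ConfusionCounts(0, 5, 0, 0)) is None

    def test_equals_pearson_of_binary_vectors(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        p = np.where(rng.random(200) < 0.3, 1 - y, y)
        c = confusion(p.astype(float), y)
        assert mcc(c) == pytest.approx(stats.pearsonr(p, y).statistic)


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        oracle = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0)
                          for p in pos for n in neg])
        assert roc_auc(scores, labels) == pytest.approx(oracle)

    def test_ties_get_half_credit(self):
        assert roc_auc([0.5, 0.5], [1, 0]) == 0.5
        assert roc_auc([0.8, 0.6, 0.4], [1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 10_000
        auc = roc_auc(rng.random(n), np.repeat([0, 1], n // 2))
        assert 0.48 < auc < 0.52

    def test_curve_monotone(self):
        rng = np.random.default_rng(3)
        fpr, tpr, _ = roc_curve(rng.random(100), rng.integers(0, 2, 100))
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestStratifiedReport:
    def test_single_stratum_equals_overall(self):
        scores = np.array([0.9, 0.2, 0.7, 0.4])
        labels = np.array([1, 0, 1, 0])
        rep = stratified_report(scores, labels, {"s": np.array(["a"] * 4)})
        assert rep["s"][0].accuracy == rep["overall"][0].accuracy
        assert rep["s"][0].n == 4

    def test_sizes_sum_to_total(self, bench_model):
        scores, labels = bench_model["scores"], bench_model["labels"]
        strata = np.array(["x" if i % 3 else "y"
                           for i in range(len(scores))])
        rep = stratified_report(scores, labels, {"s": strata})
        assert sum(b.n for b in rep["s"]) == len(scores)

    def test_coverage_mismatch_raises(self):
        with pytest.raises(ValueError, match="cover"):
            stratified_report(np.array([0.5, 0.6]), np.array([0, 1]),
                              {"s": np.array(["a"])})


class TestScoreBand:
    def test_no_scores_in_band(self):
        rep = score_band_report(np.array([0.1, 0.9]), np.array([0, 1]))
        assert rep.fraction_in_band == 0.0 and rep.in_band is None

    def test_all_scores_at_half(self):
        rep = score_band_report(np.array([0.5, 0.5]), np.array([0, 1]))
        assert rep.fraction_in_band == 1.0

    def test_closed_interval_edges(self):
        rep = score_band_report(np.array([0.4, 0.6, 0.39, 0.61]),
                                np.array([0, 1, 0, 1]))
        assert rep.fraction_in_band == 0.5

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            score_band_report(np.array([0.5]), np.array([1]), band=(0.7, 0.2))


class TestMcNemar:
    def test_identical_predictions(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([1, 0, 0, 0])
        assert mcnemar(p, p, y) == 1.0

    def test_exact_binomial_value(self):
        # b=10, c=2 -> two-sided exact p = 2 * P(X <= 2 | n=12) = 158/4096
        y = np.zeros(14)
        a = y.copy()
        a[12:] = 1  # a wrong only on the last 2
        b = y.copy()
        b[:10] = 1  # b wrong only on the first 10
        # a right & b wrong: 10 examples; a wrong & b right: 2 examples
        assert mcnemar(a, b, y) == pytest.approx(158 / 4096)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        a = np.where(rng.random(40) < 0.2, 1 - y, y)
        b = np.where(rng.random(40) < 0.3, 1 - y, y)
        assert mcnemar(a, b, y) == pytest.approx(mcnemar(b, a, y))

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(1)
        for flip_b, n in ((0.3, 40), (0.45, 400)):
            y = rng.integers(0, 2, n)
            a = np.where(rng.random(n) < 0.2, 1 - y, y)
            b = np.where(rng.random(n) < flip_b, 1 - y, y)
            right_a, right_b = a == y, b == y
            table = [[np.sum(right_a & right_b), np.sum(right_a & ~right_b)],
                     [np.sum(~right_a & right_b), np.sum(~right_a & ~right_b)]]
            exact = (table[0][1] + table[1][0]) < 25
            expected = sm_mcnemar(table, exact=exact,
                                  correction=True).pvalue
            assert mcnemar(a, b, y) == pytest.approx(expected)


class TestMannWhitney:
    def test_identical_samples(self):
        assert mannwhitney([1, 2, 3], [1, 2, 3]) == 1.0

    def test_fully_separated_exact(self):
        # all 3 low ranks vs all high: 2 of C(6,3)=20 splits are as extreme
        assert mannwhitney([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_monotone_transform_invariance(self):
        a = np.array([0.1, 0.5, 0.9, 0.3])
        b = np.array([0.2, 0.6, 0.8])
        assert mannwhitney(a, b) == pytest.approx(
            mannwhitney(np.exp(a), np.exp(b)))

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert mannwhitney(a, b) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mannwhitney([], [1.0])


class TestLearningCurve:
    def test_nested_subsets_and_full_fraction(self, bench_model):
        from esp.classifier import PairClassifier, assemble_features

        evecs = bench_model["enzyme_vectors"]
        fpd = bench_model["mol_vectors"]
        train_pairs = bench_model["train_pairs"]
        test_pairs = bench_model["test_pairs"]
        enzymes = sorted({p.enzyme_id for p in train_pairs})
        rng = np.random.default_rng(0)
        order = list(rng.permutation(enzymes))

        seen_subsets = []

        def trainer(pairs):
            seen_subsets.append({p.enzyme_id for p in pairs})
            X, y, _ = assemble_features(pairs, evecs, fpd)
            return PairClassifier(seed=0, n_estimators=60).fit(X, y)

        def test_scores(model):
            X, y, _ = assemble_features(test_pairs, evecs, fpd)
            from esp.classifier import predict_scores

            return predict_scores(model, X), y

        df = learning_curve([0.3, 0.6, 1.0], trainer, order, train_pairs,
                            test_scores)
        assert seen_subsets[0] <= seen_subsets[1] <= seen_subsets[2]
        assert seen_subsets[2] == set(enzymes)  # fraction 1.0 is the full set
        assert len(df) == 3 and "spearman_auc" in df.attrs

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            learning_curve([0.0], lambda p: None, [], [], lambda m: ([], []))


class TestMoleculeOccurrence:
    def test_buckets_partition(self):
        scores = np.array([0.9, 0.1, 0.8, 0.3, 0.7, 0.2])
        labels = np.array([1, 0, 1, 0, 1, 0])
        mids = ["a", "a", "b", "b", "c", "d"]
        counts = {"b": 1, "c": 4, "d": 9}  # a absent -> bucket 0
        df = molecule_occurrence_report(scores, labels, mids, counts)
        assert df["n"].sum() == 6
        assert set(df["bucket"]) == {"0", "1", "3-5", ">5"}
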