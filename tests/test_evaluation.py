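import math

import numpy as np
import pytest

from eguard.chem import parse_and_canonicalize
from eguard.evaluation import (
    ConfusionCounts,
    classification_report,
    compare_strategies,
    confusion_from_predictions,
    count_pains,
    enrichment_factor,
    imbalance_rate,
    internal_diversity,
    mcc,
    qed_and_summary,
    scaffold_similarity,
)


def mols(*smiles):
    return [parse_and_canonicalize(s) for s in smiles]


class TestMcc:
    def test_perfect_agreement(self):
        assert mcc(ConfusionCounts(10, 0, 90, 0)) == 1.0

    def test_chance_level(self):
        assert mcc(ConfusionCounts(25, 25, 25, 25)) == 0.0

    def test_direct_formula_evaluation(self):
        # (3*5 - 1*1) / sqrt(4*4*6*6) = 14/24
        assert mcc(ConfusionCounts(3, 1, 5, 1)) == pytest.approx(14 / 24)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(0, 0, 5, 5)) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 1, 0)


class TestEnrichmentFactor:
    def test_precision_equal_prevalence_is_one(self):
        # precision 0.5, prevalence 0.5
        assert enrichment_factor(ConfusionCounts(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert enrichment_factor(ConfusionCounts(8, 2, 88, 2)) == pytest.approx(8.0)

    def test_perfect_precision_attains_inverse_prevalence(self):
        c = ConfusionCounts(10, 0, 90, 0)
        assert enrichment_factor(c) == pytest.approx(10.0)  # 1 / 0.1

    def test_no_predicted_positives_is_undefined_marker(self):
        assert math.isnan(enrichment_factor(ConfusionCounts(0, 0, 9, 1)))

    def test_no_actual_positives_rejected(self):
        with pytest.raises(ValueError):
            enrichment_factor(ConfusionCounts(0, 5, 5, 0))


class TestMetricOracles:
    def test_brute_force_formula_agreement_over_small_confusion_space(self):
        """mcc and EF agree with direct evaluation of the printed formulas
        over every confusion matrix with entries 0..5."""
        for tp in range(6):
            for fp in range(6):
                for tn in range(6):
                    for fn in range(6):
                        if tp + fp + tn + fn == 0:
                            continue
                        c = ConfusionCounts(tp, fp, tn, fn)
                        denom = math.sqrt(
                            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
                        )
                        expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
                        assert mcc(c) == pytest.approx(expected, abs=1e-12)
                        if tp + fn > 0:
                            got = enrichment_factor(c)
                            if tp + fp == 0:
                                assert math.isnan(got)
                            else:
                                precision = tp / (tp + fp)
                                prevalence = (tp + fn) / (tp + fp + tn + fn)
                                assert got == pytest.approx(
                                    precision / prevalence, abs=1e-12
                                )

    def test_ef_upper_bound(self):
        for tp, fp, tn, fn in [(3, 2, 4, 1), (5, 0, 5, 0), (1, 4, 0, 2)]:
            c = ConfusionCounts(tp, fp, tn, fn)
            bound = c.total / (tp + fn)
            assert enrichment_factor(c) <= bound + 1e-12


class TestImbalanceRate:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [(50, 50, 0.0), (0, 100, 1.0), (811, 3035, 2224 / 3846)],
    )
    def test_values(self, pos, neg, expected):
        assert imbalance_rate(pos, neg) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            imbalance_rate(0, 0)


class TestInternalDiversity:
    def test_identical_set_is_zero(self):
        assert internal_diversity(mols("CCO", "CCO", "CCO")) == pytest.approx(0.0)

    def test_two_disjoint_fingerprints_p1(self):
        M = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        # ordered pairs: (1+0+0+1)/4 = 0.5 -> IntDiv = 0.5
        assert internal_diversity(M, p=1) == pytest.approx(0.5)

    def test_two_disjoint_fingerprints_p2(self):
        M = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        assert internal_diversity(M, p=2) == pytest.approx(1 - math.sqrt(0.5))

    def test_order_invariance_and_bounds(self, pool_mols, rng):
        subset = pool_mols[:20]
        a = internal_diversity(subset)
        shuffled = [subset[i] for i in rng.permutation(20)]
        b = internal_diversity(shuffled)
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            internal_diversity(np.zeros((0, 8), dtype=np.uint8))


class TestPains:
    def test_clean_molecules_count_zero(self):
        assert count_pains(mols("C", "CCO")) == 0

    def test_quinone_family_flagged(self):
        # catechol-type chemotype from the PAINS catalog
        catechol = mols("Oc1ccccc1O", "O=C1C=CC(=O)C=C1")
        assert count_pains(catechol) >= 1

    def test_duplicates_count_per_instance(self):
        hits = mols("Oc1ccc(O)cc1", "Oc1ccc(O)cc1")
        once = count_pains(hits[:1])
        assert count_pains(hits) == 2 * once


class TestScaffoldSimilarity:
    def test_subset_scaffolds_score_one(self):
        new = mols("Cc1ccccc1")
        ref = mols("CCc1ccccc1", "CC1CCCCC1")
        assert scaffold_similarity(new, ref).mean == pytest.approx(1.0)

    def test_acyclic_molecules_excluded_and_counted(self):
        new = mols("CCO", "Cc1ccccc1")
        ref = mols("c1ccccc1")
        res = scaffold_similarity(new, ref)
        assert res.n_acyclic_excluded == 1
        assert res.n_scored == 1
        assert res.mean == pytest.approx(1.0)

    def test_all_acyclic_new_set_is_undefined(self):
        res = scaffold_similarity(mols("CCO", "CCC"), mols("c1ccccc1"))
        assert math.isnan(res.mean)

    def test_two_by_two_matches_brute_force_max_mean(self):
        new = mols("Cc1ccccc1", "CC1CCNCC1")
        ref = mols("CCc1ccncc1", "OC1CCCCC1")
        from eguard.chem import fingerprint_matrix, murcko_scaffold, tanimoto_matrix

        new_s = [murcko_scaffold(m) for m in new]
        ref_s = [murcko_scaffold(m) for m in ref]
        S = tanimoto_matrix(
            fingerprint_matrix(new_s, radius=2), fingerprint_matrix(ref_s, radius=2)
        )
        expected = S.max(axis=1).mean()
        assert scaffold_similarity(new, ref).mean == pytest.approx(expected)


class TestQed:
    def test_bounds_and_determinism(self, pool_mols):
        vals, mean = qed_and_summary(pool_mols[:10])
        assert np.all((vals >= 0) & (vals <= 1))
        vals2, _ = qed_and_summary(pool_mols[:10])
        assert np.array_equal(vals, vals2)

    def test_druglike_beats_huge_polyaromatic(self):
        druglike = mols("CC(=O)Oc1ccccc1C(=O)O")
        greasy = mols("c1ccc2cc3cc4ccc5cc6ccccc6cc5c4cc3cc2c1")
        _, m1 = qed_and_summary(druglike)
        _, m2 = qed_and_summary(greasy)
        assert m1 > m2


class TestClassificationReport:
    def test_perfect_classifier(self):
        labels = np.array([0, 0, 1, 1])
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        rep = classification_report(probs, labels)
        assert rep["mcc"] == 1.0
        assert rep["pr_auc"] == 1.0
        assert rep["balanced_accuracy"] == 1.0

    def test_random_scores_pr_auc_near_prevalence(self, rng):
        labels = (rng.random(4000) < 0.5).astype(int)
        probs = rng.random(4000)
        rep = classification_report(probs, labels)
        prevalence = labels.mean()
        assert abs(rep["pr_auc"] - prevalence) < 0.05

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            classification_report(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_confusion_counting(self):
        c = confusion_from_predictions(
            np.array([1, 1, 0, 0, 1]), np.array([1, 0, 0, 1, 1])
        )
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)


class TestCompareStrategies:
    def test_welch_closed_form_example(self):
        res = compare_strategies([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674234614)
        assert res.df == pytest.approx(4.0)

    def test_identical_samples_with_spread_give_t_zero_p_one(self):
        res = compare_strategies([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_arm_swap_flips_sign(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        assert compare_strategies(a, b).t == pytest.approx(
            -compare_strategies(b, a).t
        )

    def test_zero_variance_both_arms_rejected(self):
        with pytest.raises(ValueError):
            compare_strategies([2, 2, 2], [3, 3, 3])

    def test_single_run_arm_rejected(self):
        with pytest.raises(ValueError):
            compare_strategies([1], [2, 3])
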