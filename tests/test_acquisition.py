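import math

import numpy as np
import pytest
from scipy import stats

from eguard.acquisition import (
    AcquisitionConfig,
    acquire,
    acquire_greedy,
    acquire_random,
    acquire_with_skill,
    combined_score,
    epig_from_votes,
    epig_scores,
    prepare_pool,
)
from eguard.expert import CallableExpertScorer, HeuristicExpertScorer
from eguard.generation import CandidatePool


def make_pool(mols, m=None):
    n = len(mols)
    m = np.asarray(m, dtype=float) if m is not None else np.full(n, 0.5)
    return CandidatePool(
        molecules=mols,
        reward=m.copy(),
        m=m,
        wt=np.ones(n),
        step=np.zeros(n, dtype=int),
    )


class TestCombinedScore:
    def test_beta_zero_reduces_to_predictor(self):
        a_pred = np.array([0.2, 0.9, 0.4])
        out = combined_score(a_pred, np.array([1.0, 0.0, 0.5]), alpha=1, beta=0)
        assert np.array_equal(out, a_pred)

    def test_addition_with_unit_weights(self):
        assert combined_score(0.7, 0.2, 1, 1) == pytest.approx(0.9)

    def test_zero_components_give_zero(self):
        assert combined_score(0.0, 0.0, 1, 1) == 0.0

    def test_out_of_range_components_rejected(self):
        with pytest.raises(ValueError):
            combined_score(np.array([1.5]), np.array([0.5]))


class TestRandomAcquisition:
    def test_whole_pool_when_k_equals_size(self, pool_mols, rng):
        pool = make_pool(pool_mols[:6])
        res = acquire_random(pool, 6, rng)
        assert sorted(res.smiles) == sorted(pool.smiles)

    def test_uniformity_over_seeded_draws(self):
        mols = None
        from eguard.synthetic_data import fixture_pool

        mols = fixture_pool(4, seed=0)
        pool = make_pool(mols)
        counts = {m.smiles: 0 for m in mols}
        rng = np.random.default_rng(123)
        for _ in range(10_000):
            res = acquire_random(pool, 1, rng)
            counts[res.smiles[0]] += 1
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 0.01

    def test_oversized_k_rejected(self, pool_mols, rng):
        with pytest.raises(ValueError):
            acquire_random(make_pool(pool_mols[:3]), 4, rng)

    def test_determinism_per_seed(self, pool_mols):
        pool = make_pool(pool_mols[:20])
        a = acquire_random(pool, 5, np.random.default_rng(9))
        b = acquire_random(pool, 5, np.random.default_rng(9))
        assert a.smiles == b.smiles


class TestGreedyAcquisition:
    def test_top_k_by_score(self, pool_mols):
        pool = make_pool(pool_mols[:3], m=[0.9, 0.8, 0.1])
        res = acquire_greedy(pool, 2)
        assert res.smiles == [pool_mols[0].smiles, pool_mols[1].smiles]

    def test_ties_broken_by_canonical_smiles_order(self, pool_mols):
        pool = make_pool(pool_mols[:4], m=[0.5, 0.5, 0.5, 0.5])
        res = acquire_greedy(pool, 2)
        assert res.smiles == sorted(pool.smiles)[:2]
        assert res.tie_breaks >= 2

    def test_k_zero_empty_selection(self, pool_mols):
        assert len(acquire_greedy(make_pool(pool_mols[:3]), 0)) == 0


class TestEpig:
    def test_deterministic_ensemble_scores_zero(self):
        votes = np.ones((5, 8))  # every tree votes class 1 everywhere
        out = epig_from_votes(votes, votes[:3])
        assert np.allclose(out, 0.0)

    def test_two_tree_aligned_disagreement_gives_ln2(self):
        # candidate votes (1,0), target votes (1,0): joint mass on
        # (1,1) and (0,0) only, 0.5 each; marginals 0.5/0.5 -> KL = ln 2
        cand = np.array([[1, 0]])
        target = np.array([[1, 0]])
        out = epig_from_votes(cand, target)
        assert out[0] == pytest.approx(math.log(2))

    def test_two_tree_independent_target_gives_zero(self):
        # target votes (1,1) are deterministic: joint = product
        cand = np.array([[1, 0]])
        target = np.array([[1, 1]])
        assert epig_from_votes(cand, target)[0] == pytest.approx(0.0)

    def test_nonnegative_and_tree_reorder_invariant(self, rng):
        votes = rng.integers(0, 2, size=(20, 16))
        targets = votes[:6]
        base = epig_from_votes(votes, targets)
        assert np.all(base >= 0)
        perm = rng.permutation(16)
        again = epig_from_votes(votes[:, perm], targets[:, perm])
        assert np.allclose(base, again)

    def test_brute_force_oracle_agreement(self, rng):
        """Exhaustive vectorized EPIG equals a per-pair loop over trees."""
        votes = rng.integers(0, 2, size=(6, 10))
        targets = rng.integers(0, 2, size=(4, 10))
        fast = epig_from_votes(votes, targets)
        for i in range(6):
            kls = []
            for j in range(4):
                joint = np.zeros((2, 2))
                for t in range(10):
                    joint[votes[i, t], targets[j, t]] += 1
                joint /= 10
                px = joint.sum(axis=1)
                qy = joint.sum(axis=0)
                kl = 0.0
                for a in (0, 1):
                    for b in (0, 1):
                        if joint[a, b] > 0:
                            kl += joint[a, b] * math.log(
                                joint[a, b] / (px[a] * qy[b])
                            )
                kls.append(kl)
            assert fast[i] == pytest.approx(np.mean(kls))

    def test_sampled_estimator_tracks_exhaustive(self, toy_model, split, rng):
        mols = split.test.molecules()[:40]
        pool = make_pool(mols, m=rng.random(40))
        exact = epig_scores(toy_model, pool, target_size=20, pair_samples=None)
        sampled = epig_scores(
            toy_model, pool, target_size=20, pair_samples=400, rng=rng
        )
        assert np.corrcoef(exact, sampled)[0, 1] > 0.9 or np.allclose(
            exact, sampled, atol=0.02
        )

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError):
            epig_from_votes(np.ones((2, 4)), np.ones((0, 4)))


class TestSkillAcquisition:
    def test_constant_expert_matches_pure_predictor_ranking(self, pool_mols):
        pool = make_pool(pool_mols[:10], m=np.linspace(0, 1, 10))
        expert = CallableExpertScorer(fn=lambda m: 1.0)
        cfg = AcquisitionConfig(strategy="greedy_skill", k=4, beta=1.0)
        res = acquire_with_skill(pool, pool.m, expert, cfg)
        pure = acquire_greedy(pool, 4)
        assert res.smiles == pure.smiles

    def test_constant_predictor_matches_expert_ranking(self, pool_mols):
        pool = make_pool(pool_mols[:8], m=np.full(8, 0.5))
        prefs = {m.smiles: i for i, m in enumerate(pool.molecules)}
        expert = CallableExpertScorer(fn=lambda m: prefs[m.smiles])
        cfg = AcquisitionConfig(strategy="greedy_skill", k=3, beta=1.0)
        res = acquire_with_skill(pool, pool.m, expert, cfg)
        want = [m.smiles for m in pool.molecules[-3:]][::-1]
        assert res.smiles == want

    def test_five_molecule_pool_matches_brute_force(self, pool_mols):
        pool = make_pool(pool_mols[:5], m=[0.1, 0.9, 0.4, 0.7, 0.2])
        expert = HeuristicExpertScorer()
        cfg = AcquisitionConfig(strategy="greedy_skill", k=2, beta=1.0)
        res = acquire_with_skill(pool, pool.m, expert, cfg)
        # brute force: enumerate A(x) by explicit min-max arithmetic
        from eguard.expert import normalize_preferences

        a_pred = normalize_preferences(pool.m)
        a_hum = normalize_preferences(expert.score(pool.molecules), True)
        totals = a_pred + a_hum
        order = sorted(
            range(5), key=lambda i: (-totals[i], pool.molecules[i].smiles)
        )
        assert res.smiles == [pool.molecules[i].smiles for i in order[:2]]


class TestDispatchAndLeakage:
    def test_test_set_matches_excluded_before_selection(self, pool_mols, rng,
                                                        toy_model):
        pool = make_pool(pool_mols[:10], m=np.linspace(0.1, 1.0, 10))
        pool.in_test = np.zeros(10, dtype=bool)
        pool.in_test[9] = True  # the highest-scoring molecule is a test match
        cfg = AcquisitionConfig(strategy="greedy", k=3)
        res = acquire(pool, cfg, toy_model, None, rng)
        assert pool_mols[9].smiles not in res.smiles
        assert len(res) == 3

    def test_selected_are_pool_members(self, pool_mols, rng, toy_model):
        pool = make_pool(pool_mols[:30], m=rng.random(30))
        for strategy in ("random", "greedy", "greedy_skill"):
            cfg = AcquisitionConfig(
                strategy=strategy, k=5, beta=1.0 if "skill" in strategy else 0.0
            )
            res = acquire(pool, cfg, toy_model, HeuristicExpertScorer(), rng)
            assert len(res) == 5
            assert set(res.smiles) <= set(pool.smiles)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            AcquisitionConfig(strategy="bogus")

    def test_duplicates_removed_before_selection(self, pool_mols):
        mols = pool_mols[:3] + pool_mols[:3]
        pool = make_pool(mols, m=[0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        prepared = prepare_pool(pool)
        assert len(prepared) == 3
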