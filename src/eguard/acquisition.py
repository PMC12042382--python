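"""Acquisition strategies: selecting the k most informative molecules from
the generated pool U_r.

Five strategies are provided.  Random, Greedy (highest predicted
interference probability) and EPIG use only the predictor-side score
(beta = 0); GreedySkill and EPIGSkill add a min-max-normalized expert
preference with alpha = beta = 1:

    A(x) = alpha * A_predictor(x) + beta * A_human(x)

EPIG — expected predictive information gain — scores a candidate x by the
mutual information between its label and the label of a random target x*
drawn from the 1000 highest-m(x) molecules of the pool: the expected KL
divergence between the joint predictive distribution p(y, y* | x, x*) and
the product of its marginals.  For a forest, each tree is treated as one
posterior sample, so the joint is the fraction of trees jointly voting
(y, y*) while marginals are tree-vote frequencies; a deterministic
ensemble therefore has EPIG identically 0.

Ties are broken by canonical-SMILES lexicographic order (deterministic and
seed-independent); tie-break events are recorded on the result.  Molecules
flagged as exact test-set matches are excluded before any selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem import Molecule
from .expert import ExpertScorerProtocol, normalize_preferences
from .generation import CandidatePool
from .qsir import QSIRModel

logger = logging.getLogger(__name__)

STRATEGIES = ("random", "greedy", "epig", "greedy_skill", "epig_skill")


@dataclass(frozen=True)
class AcquisitionConfig:
    strategy: str = "greedy"
    k: int = 250
    alpha: float = 1.0
    beta: float = 0.0
    epig_target_size: int = 1000
    epig_pair_samples: int | None = 100  # None = exhaustive over the target set

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass
class AcquisitionResult:
    molecules: list[Molecule]
    a_total: np.ndarray
    a_predictor: np.ndarray
    a_human: np.ndarray
    tie_breaks: int = 0

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def smiles(self) -> list[str]:
        return [m.smiles for m in self.molecules]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "smiles": self.smiles,
                "a_total": self.a_total,
                "a_predictor": self.a_predictor,
                "a_human": self.a_human,
            }
        )


def combined_score(
    a_pred: np.ndarray, a_human: np.ndarray, alpha: float = 1.0, beta: float = 1.0
) -> np.ndarray:
    """A(x) = alpha * A_predictor(x) + beta * A_human(x)."""
    a_pred = np.asarray(a_pred, dtype=float)
    a_human = np.asarray(a_human, dtype=float)
    if np.any((a_pred < 0) | (a_pred > 1)) or np.any((a_human < 0) | (a_human > 1)):
        raise ValueError("component scores must lie in [0, 1]")
    return alpha * a_pred + beta * a_human


def _filter_test_matches(pool: CandidatePool) -> CandidatePool:
    if pool.in_test is None or not pool.in_test.any():
        return pool
    keep = np.flatnonzero(~pool.in_test)
    logger.info("excluding %d exact test-set matches from acquisition",
                int(pool.in_test.sum()))
    return CandidatePool(
        molecules=[pool.molecules[i] for i in keep],
        reward=pool.reward[keep],
        m=pool.m[keep],
        wt=pool.wt[keep],
        step=pool.step[keep],
        in_train=None if pool.in_train is None else pool.in_train[keep],
        in_test=np.zeros(len(keep), dtype=bool),
    )


def prepare_pool(pool: CandidatePool) -> CandidatePool:
    """Deduplicate by canonical SMILES and drop exact test-set matches."""
    return _filter_test_matches(pool.deduplicate())


def _top_k(
    mols: list[Molecule], scores: np.ndarray, k: int
) -> tuple[np.ndarray, int]:
    """Indices of the k largest scores; ties broken by canonical SMILES."""
    if k > len(mols):
        raise ValueError(f"k={k} exceeds pool size {len(mols)}")
    smiles = [m.smiles for m in mols]
    order = sorted(range(len(mols)), key=lambda i: (-scores[i], smiles[i]))
    chosen = order[:k]
    tie_breaks = 0
    if 0 < k < len(mols) and scores[order[k - 1]] == scores[order[k]]:
        boundary = scores[order[k - 1]]
        tie_breaks = int(np.sum(scores == boundary))
        logger.debug("tie at selection boundary (score %.6g, %d tied)",
                     boundary, tie_breaks)
    return np.array(chosen, dtype=int), tie_breaks


def _result(pool, idx, a_total, a_pred, a_human, tie_breaks=0) -> AcquisitionResult:
    return AcquisitionResult(
        molecules=[pool.molecules[i] for i in idx],
        a_total=np.asarray(a_total)[idx],
        a_predictor=np.asarray(a_pred)[idx],
        a_human=np.asarray(a_human)[idx],
        tie_breaks=tie_breaks,
    )


def acquire_random(
    pool: CandidatePool, k: int, rng: np.random.Generator
) -> AcquisitionResult:
    """Uniform sample of k molecules without replacement."""
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    idx = rng.choice(len(pool), size=k, replace=False)
    zeros = np.zeros(len(pool))
    return _result(pool, idx, zeros, zeros, zeros)


def acquire_greedy(pool: CandidatePool, k: int) -> AcquisitionResult:
    """Top-k by predicted interference probability m(x)."""
    idx, ties = _top_k(pool.molecules, pool.m, k)
    zeros = np.zeros(len(pool))
    return _result(pool, idx, pool.m, pool.m, zeros, ties)


def epig_from_votes(
    candidate_votes: np.ndarray,
    target_votes: np.ndarray,
    pair_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """EPIG from binary per-tree vote matrices.

    ``candidate_votes`` is (N, T), ``target_votes`` (M, T); trees are joint
    posterior samples, so the joint predictive p(y, y* | x, x*) is the
    fraction of trees voting (y, y*) with same-tree pairing, and EPIG(x) is
    the mean over targets of KL(joint || product of marginals).  With
    ``pair_samples`` set, the target average is Monte-Carlo estimated over
    that many targets sampled with replacement.
    """
    votes = np.asarray(candidate_votes, dtype=np.float64)
    votes_t = np.asarray(target_votes, dtype=np.float64)
    if votes.ndim != 2 or votes_t.ndim != 2 or votes.shape[1] != votes_t.shape[1]:
        raise ValueError("vote matrices must be 2-D with equal tree counts")
    if votes_t.shape[0] == 0:
        raise ValueError("empty EPIG target set")
    T = votes.shape[1]
    if pair_samples is not None:
        if rng is None:
            raise ValueError("pair sampling requires an rng")
        sel = rng.integers(0, votes_t.shape[0], size=pair_samples)
        votes_t = votes_t[sel]

    p1 = votes.mean(axis=1)  # (N,) candidate marginals
    q1 = votes_t.mean(axis=1)  # (S,) target marginals

    # joint cell frequencies via same-tree pairing
    c11 = votes @ votes_t.T / T
    c10 = votes @ (1.0 - votes_t).T / T
    c01 = (1.0 - votes) @ votes_t.T / T
    c00 = (1.0 - votes) @ (1.0 - votes_t).T / T

    def _kl_term(joint, px, qy):
        prod = px[:, None] * qy[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = joint * (np.log(joint) - np.log(prod))
        return np.where(joint > 0, term, 0.0)

    kl = (
        _kl_term(c11, p1, q1)
        + _kl_term(c10, p1, 1 - q1)
        + _kl_term(c01, 1 - p1, q1)
        + _kl_term(c00, 1 - p1, 1 - q1)
    )
    scores = kl.mean(axis=1)
    return np.maximum(scores, 0.0)


def epig_scores(
    model: QSIRModel,
    pool: CandidatePool,
    target_size: int = 1000,
    pair_samples: int | None = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """EPIG score per pool molecule against the top-``target_size`` targets.

    The target set is the ``target_size`` highest-m(x) molecules of the
    pool (canonical-SMILES tie-break).  ``pair_samples=None`` evaluates the
    expectation exhaustively over the target set.  Scores are non-negative;
    exactly 0 when every tree votes identically (deterministic ensemble).
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    n_target = min(target_size, len(pool))
    order = sorted(
        range(len(pool)), key=lambda i: (-pool.m[i], pool.molecules[i].smiles)
    )
    target_idx = np.array(order[:n_target])
    X = model.featurize(pool.molecules)
    votes = model.forest.tree_votes(X)
    return epig_from_votes(votes, votes[target_idx], pair_samples, rng)


def acquire_epig(
    pool: CandidatePool,
    model: QSIRModel,
    cfg: AcquisitionConfig,
    rng: np.random.Generator,
) -> AcquisitionResult:
    """Top-k by EPIG score."""
    scores = epig_scores(
        model, pool, cfg.epig_target_size, cfg.epig_pair_samples, rng
    )
    idx, ties = _top_k(pool.molecules, scores, cfg.k)
    zeros = np.zeros(len(pool))
    return _result(pool, idx, scores, scores, zeros, ties)


def acquire_with_skill(
    pool: CandidatePool,
    predictor_scores: np.ndarray,
    expert: ExpertScorerProtocol,
    cfg: AcquisitionConfig,
) -> AcquisitionResult:
    """GreedySkill / EPIGSkill: min-max-normalize both components over the
    pool, combine with alpha/beta, take the top k."""
    a_pred = normalize_preferences(predictor_scores, higher_is_better=True)
    raw = expert.score(pool.molecules)
    a_human = normalize_preferences(raw, expert.higher_is_better)
    total = combined_score(a_pred, a_human, cfg.alpha, cfg.beta)
    idx, ties = _top_k(pool.molecules, total, cfg.k)
    return _result(pool, idx, total, a_pred, a_human, ties)


def acquire(
    pool: CandidatePool,
    cfg: AcquisitionConfig,
    model: QSIRModel,
    expert: ExpertScorerProtocol | None,
    rng: np.random.Generator,
) -> AcquisitionResult:
    """Dispatch on the configured strategy over a prepared (deduplicated,
    leakage-filtered) pool."""
    pool = prepare_pool(pool)
    if cfg.strategy == "random":
        return acquire_random(pool, cfg.k, rng)
    if cfg.strategy == "greedy":
        return acquire_greedy(pool, cfg.k)
    if cfg.strategy == "epig":
        return acquire_epig(pool, model, cfg, rng)
    if expert is None:
        raise ValueError(f"strategy {cfg.strategy} requires an expert scorer")
    if cfg.strategy == "greedy_skill":
        return acquire_with_skill(pool, pool.m, expert, cfg)
    scores = epig_scores(
        model, pool, cfg.epig_target_size, cfg.epig_pair_samples, rng
    )
    return acquire_with_skill(pool, scores, expert, cfg)
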