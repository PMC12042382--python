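"""Evaluation metrics for interference classifiers and generated molecule sets.

Classifier side: Matthews correlation coefficient (the primary measure),
enrichment factor (precision divided by positive prevalence), balanced
accuracy and PR-AUC.  Dataset/chemistry side: imbalance rate, internal
Tanimoto diversity, PAINS alert counting, QED drug-likeness and Murcko
scaffold similarity to a reference set.  Strategy comparisons use Welch's
two-sample t-test (fractional degrees of freedom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, balanced_accuracy_score

from .chem import (
    EMPTY_SCAFFOLD,
    Fingerprint,
    Molecule,
    fingerprint_matrix,
    murcko_scaffold,
    tanimoto_matrix,
)

# diversity and scaffold similarity use Morgan2/2048 by convention
DIVERSITY_RADIUS = 2
DIVERSITY_NBITS = 2048


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    Convention: if any factor of the denominator is zero the coefficient is
    defined as 0 (chance level).
    """
    denom_sq = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom_sq == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom_sq)


def enrichment_factor(c: ConfusionCounts) -> float:
    """Enrichment factor: precision / positive-class prevalence.

    EF > 1 means the model enriches interfering compounds beyond random
    picking; the maximum is 1/prevalence (perfect precision).  With no
    predicted positives the quantity is undefined and NaN is returned
    (never 0, which would wrongly signal anti-enrichment).
    """
    if c.tp + c.fn == 0:
        raise ValueError("enrichment factor requires at least one actual positive")
    if c.tp + c.fp == 0:
        return math.nan
    precision = c.tp / (c.tp + c.fp)
    prevalence = (c.tp + c.fn) / c.total
    return precision / prevalence


def imbalance_rate(n_pos: int, n_neg: int) -> float:
    """IR = |pos - neg| / (pos + neg), in [0, 1]; 0 is perfect balance."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    if n_pos + n_neg == 0:
        raise ValueError("empty set has no imbalance rate")
    return abs(n_pos - n_neg) / (n_pos + n_neg)


def _as_fp_matrix(fps) -> np.ndarray:
    if isinstance(fps, np.ndarray):
        return fps
    if fps and isinstance(fps[0], Fingerprint):
        return np.stack([f.bits for f in fps])
    if fps and isinstance(fps[0], Molecule):
        return fingerprint_matrix(fps, radius=DIVERSITY_RADIUS, nbits=DIVERSITY_NBITS)
    raise TypeError("expected fingerprint matrix, Fingerprints or Molecules")


def internal_diversity(fps, p: int = 1) -> float:
    """IntDiv_p = 1 - (mean over all ordered pairs of Tanimoto^p)^(1/p).

    The mean runs over all |G|^2 ordered pairs including self-pairs, which
    keeps the value in [0, 1]; an all-identical set scores 0.
    """
    M = _as_fp_matrix(fps)
    if M.shape[0] == 0:
        raise ValueError("internal diversity of an empty set is undefined")
    if p < 1:
        raise ValueError("p must be >= 1")
    sim = tanimoto_matrix(M, M)
    return float(1.0 - np.mean(sim**p) ** (1.0 / p))


_PAINS_CATALOG = None


def _pains_catalog():
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog(params)
    return _PAINS_CATALOG


def count_pains(mols: list[Molecule]) -> int:
    """Number of molecules matching >= 1 PAINS alert (families A/B/C).

    Each molecule instance counts at most once, however many alerts it hits.
    """
    catalog = _pains_catalog()
    return sum(1 for m in mols if catalog.HasMatch(m.to_rdkit()))


@dataclass(frozen=True)
class ScaffoldSimilarityResult:
    mean: float  # NaN when every new molecule is acyclic
    n_scored: int
    n_acyclic_excluded: int


def scaffold_similarity(
    new_mols: list[Molecule], ref_mols: list[Molecule]
) -> ScaffoldSimilarityResult:
    """Mean, over new molecules, of the maximum Tanimoto similarity between
    the molecule's Murcko scaffold and any reference scaffold (Morgan2/2048).

    Acyclic molecules have no scaffold; they are excluded from the mean and
    reported in ``n_acyclic_excluded``.
    """
    if not new_mols or not ref_mols:
        raise ValueError("both molecule sets must be non-empty")
    ref_scaffolds = {
        s.smiles: s
        for s in (murcko_scaffold(m) for m in ref_mols)
        if s is not EMPTY_SCAFFOLD
    }
    if not ref_scaffolds:
        raise ValueError("reference set contains no ring systems")
    new_scaffolds = [murcko_scaffold(m) for m in new_mols]
    scored = [s for s in new_scaffolds if s is not EMPTY_SCAFFOLD]
    n_acyclic = len(new_scaffolds) - len(scored)
    if not scored:
        return ScaffoldSimilarityResult(math.nan, 0, n_acyclic)
    ref_M = fingerprint_matrix(
        list(ref_scaffolds.values()), radius=DIVERSITY_RADIUS, nbits=DIVERSITY_NBITS
    )
    new_M = fingerprint_matrix(scored, radius=DIVERSITY_RADIUS, nbits=DIVERSITY_NBITS)
    sims = tanimoto_matrix(new_M, ref_M).max(axis=1)
    return ScaffoldSimilarityResult(float(sims.mean()), len(scored), n_acyclic)


def qed_and_summary(mols: list[Molecule]) -> tuple[np.ndarray, float]:
    """Per-molecule QED drug-likeness (desirability product, in [0, 1]) and
    the set mean."""
    from rdkit.Chem import QED

    vals = np.array([QED.qed(m.to_rdkit()) for m in mols])
    return vals, float(vals.mean()) if len(vals) else math.nan


def classification_report(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """MCC, EF and balanced accuracy at ``threshold``, plus threshold-free
    PR-AUC (step-interpolated average precision)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if len(probs) != len(labels):
        raise ValueError("probs and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    pred = (probs >= threshold).astype(int)
    c = confusion_from_predictions(labels, pred)
    return {
        "mcc": mcc(c),
        "ef": enrichment_factor(c),
        "balanced_accuracy": float(balanced_accuracy_score(labels, pred)),
        "pr_auc": float(average_precision_score(labels, probs)),
    }


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


def compare_strategies(runs_a, runs_b) -> TTestResult:
    """Welch two-sample t-test on per-run metric values.

    Welch-Satterthwaite degrees of freedom are fractional, matching how
    unequal-variance comparisons between acquisition strategies are
    reported.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 runs per arm")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both arms; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=float(res.df))
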