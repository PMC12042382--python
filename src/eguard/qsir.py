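"""Quantitative structure-interference (QSIR) teacher/student classifier.

A balanced random forest on binary Morgan fingerprints (radius 3, 2048
bits): every tree is fit on a bootstrap that contains *equal numbers of
positive and negative compounds* (each class resampled with replacement to
the minority-class count), which counters the heavy class imbalance of
interference data without reweighting.

Hyperparameters are selected once by seeded random search (50 trials,
stratified five-fold cross-validation, mean MCC objective) and then frozen
for all self-distillation iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .chem import Molecule, fingerprint_matrix
from .synthetic_data import LabeledCompoundSet

FP_RADIUS = 3
FP_NBITS = 2048


@dataclass(frozen=True)
class Hyperparams:
    n_estimators: int = 200
    max_depth: int | None = None
    min_samples_split: int = 2
    max_features: str | float = "sqrt"

    def to_dict(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "min_samples_split": self.min_samples_split,
            "max_features": self.max_features,
        }


# declared random-search space
SEARCH_SPACE = {
    "n_estimators": (100, 1000),
    "max_depth": [None, 4, 8, 12, 16, 20, 24, 28, 32],
    "min_samples_split": (2, 16),
    "max_features": ["sqrt", "log2", "frac"],  # frac drawn from [0.1, 1.0]
}


def _sample_hyperparams(rng: np.random.Generator) -> Hyperparams:
    lo, hi = SEARCH_SPACE["n_estimators"]
    n_est = int(rng.integers(lo, hi + 1))
    max_depth = SEARCH_SPACE["max_depth"][
        int(rng.integers(len(SEARCH_SPACE["max_depth"])))
    ]
    lo, hi = SEARCH_SPACE["min_samples_split"]
    mss = int(rng.integers(lo, hi + 1))
    kind = SEARCH_SPACE["max_features"][
        int(rng.integers(len(SEARCH_SPACE["max_features"])))
    ]
    max_features: str | float
    if kind == "frac":
        max_features = float(np.round(rng.uniform(0.1, 1.0), 3))
    else:
        max_features = kind
    return Hyperparams(n_est, max_depth, mss, max_features)


class BalancedRandomForest:
    """Forest of CART trees, each trained on a class-balanced bootstrap.

    ``predict_proba`` is the soft-vote average of per-tree leaf class
    frequencies.  Fully deterministic given ``seed``.
    """

    def __init__(self, hp: Hyperparams, seed: int = 0):
        self.hp = hp
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.bootstrap_indices_: list[np.ndarray] = []
        self.classes_ = np.array([0, 1])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
        n_min = min(len(v) for v in idx_by_class.values())

        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(self.hp.n_estimators)
        self.trees_ = []
        self.bootstrap_indices_ = []
        for child in children:
            rng = np.random.default_rng(child)
            boot = np.concatenate(
                [
                    rng.choice(idx_by_class[c], size=n_min, replace=True)
                    for c in classes
                ]
            )
            tree_seed = int(rng.integers(0, 2**31 - 1))
            tree = DecisionTreeClassifier(
                max_depth=self.hp.max_depth,
                min_samples_split=self.hp.min_samples_split,
                max_features=self.hp.max_features,
                random_state=tree_seed,
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            self.bootstrap_indices_.append(boot)
        return self

    def _check_fitted(self) -> None:
        if not self.trees_:
            raise ValueError("forest is not fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) soft-vote class probabilities."""
        self._check_fitted()
        acc = np.zeros((X.shape[0], 2))
        for tree in self.trees_:
            p = tree.predict_proba(X)
            for j, c in enumerate(tree.classes_):
                acc[:, int(c)] += p[:, j]
        return acc / len(self.trees_)

    def tree_votes(self, X: np.ndarray) -> np.ndarray:
        """(n, n_trees) hard 0/1 predictions per tree."""
        self._check_fitted()
        return np.column_stack([t.predict(X).astype(np.int64) for t in self.trees_])

    def apply(self, X: np.ndarray) -> np.ndarray:
        """(n, n_trees) leaf indices."""
        self._check_fitted()
        return np.column_stack([t.apply(X) for t in self.trees_])


@dataclass
class QSIRModel:
    """A fitted balanced-random-forest interference model plus its
    fingerprint configuration and provenance seeds."""

    forest: BalancedRandomForest
    hyperparams: Hyperparams
    fp_radius: int = FP_RADIUS
    fp_nbits: int = FP_NBITS
    train_seed: int = 0

    def featurize(self, mols: list[Molecule]) -> np.ndarray:
        return fingerprint_matrix(mols, radius=self.fp_radius, nbits=self.fp_nbits)


def featurize_set(ds: LabeledCompoundSet) -> tuple[np.ndarray, np.ndarray]:
    X = fingerprint_matrix(ds.molecules(), radius=FP_RADIUS, nbits=FP_NBITS)
    return X, ds.labels


def train(ds: LabeledCompoundSet, hp: Hyperparams, seed: int = 0) -> QSIRModel:
    """Fit a balanced random forest on a labeled compound set."""
    X, y = featurize_set(ds)
    forest = BalancedRandomForest(hp, seed=seed).fit(X, y)
    return QSIRModel(forest=forest, hyperparams=hp, train_seed=seed)


def predict_proba(model: QSIRModel, mols: list[Molecule]) -> np.ndarray:
    """Interference probability m(x) per molecule (positive-class soft vote)."""
    X = model.featurize(mols)
    return model.forest.predict_proba(X)[:, 1]


def leaf_assignments(model: QSIRModel, mols: list[Molecule]) -> np.ndarray:
    """Leaf index per (molecule, tree); feeds the forest kernel and EPIG."""
    X = model.featurize(mols)
    return model.forest.apply(X)


def _mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    from .evaluation import ConfusionCounts, mcc

    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return mcc(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))


def cv_score(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    hp: Hyperparams,
    seed: int,
) -> float:
    """Mean cross-validated MCC of one hyperparameter configuration."""
    scores = []
    all_idx = np.arange(len(y))
    for i, val_idx in enumerate(folds):
        val_idx = np.asarray(val_idx)
        tr_idx = np.setdiff1d(all_idx, val_idx)
        if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
            raise ValueError(f"fold {i} is single-class; cannot cross-validate")
        forest = BalancedRandomForest(hp, seed=seed + i).fit(X[tr_idx], y[tr_idx])
        pred = (forest.predict_proba(X[val_idx])[:, 1] >= 0.5).astype(int)
        scores.append(_mcc(y[val_idx], pred))
    return float(np.mean(scores))


def optimize_hyperparams(
    train_set: LabeledCompoundSet,
    folds,
    n_trials: int = 50,
    seed: int = 0,
) -> Hyperparams:
    """Seeded random search maximizing mean cross-validated MCC.

    ``folds`` are validation-index tuples into ``train_set`` (from
    :func:`eguard.synthetic_data.stratified_split`).  The winning
    configuration is frozen for all later retraining.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X, y = featurize_set(train_set)
    rng = np.random.default_rng(seed)
    best_hp: Hyperparams | None = None
    best_score = -np.inf
    for _ in range(n_trials):
        hp = _sample_hyperparams(rng)
        score = cv_score(X, y, folds, hp, seed=seed)
        if score > best_score:
            best_score, best_hp = score, hp
    assert best_hp is not None
    return best_hp
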