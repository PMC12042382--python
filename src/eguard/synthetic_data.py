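"""Synthetic assay-interference benchmarks.

Real interference datasets (thiol/redox reactivity, luciferase inhibition)
are small (~4-5k compounds) and heavily imbalanced, with positive rates of
1.5-20%.  This module emulates that statistical structure with a fragment
grammar: molecules are assembled from scaffold templates and substituents,
and the positive label is *planted* — a compound is interfering iff it
carries at least one reactive substructure:

* an alpha,beta-unsaturated carbonyl (Michael acceptor; thiol reactivity),
* a para-quinone (redox cycling),
* a benzothiazole (luciferin-like heterocycle; luciferase interference).

Because labels are substructure-driven, a SMARTS search is a perfect oracle
for the noise-free labels, which makes every downstream stage testable.
Optional label noise flips each label independently.  Everything is fully
determined by the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import Molecule, parse_and_canonicalize

# planted interference rules (SMILES-syntax SMARTS)
MICHAEL_ACCEPTOR = "[CX3]=[CX3]-[CX3]=[OX1]"
QUINONE = "O=C1C=CC(=O)C=C1"
BENZOTHIAZOLE = "c1sc2ccccc2n1"

DEFAULT_PLANTED_RULES = (MICHAEL_ACCEPTOR, QUINONE, BENZOTHIAZOLE)

# --- fragment grammar ------------------------------------------------------

# scaffold templates with one or two substituent slots
_SCAFFOLDS_1 = [
    "c1ccc({0})cc1",
    "c1ccc2cc({0})ccc2c1",
    "c1cc({0})ncc1",
    "c1ccc2[nH]c({0})cc2c1",
    "C1CCC({0})CC1",
    "c1ccc(-c2ccc({0})cc2)cc1",
    "C1CCN({0})CC1",
    "c1cc({0})on1",
    "c1csc({0})c1",
    "C1COC({0})CN1",
    "c1oc({0})nc1",
    "c1nc({0})cs1",
]
_SCAFFOLDS_2 = [
    "c1cc({0})ccc1{1}",
    "c1cc({0})cc({1})c1",
    "c1ccc2cc({0})c({1})cc2c1",
    "c1c({0})cc({1})cn1",
    "C1CC({0})CCC1{1}",
    "c1ccc(-c2cc({0})ccc2{1})cc1",
    "c1cc({0})c({1})cn1",
    "C1CN({0})CCN1{1}",
]

# neutral substituents: none matches a planted rule (incl. near-miss
# saturated carbonyls and nitriles, which keep the task non-trivial)
_NEUTRAL_SUBS = [
    "C", "CC", "CCC", "C(C)C", "CCCC", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "CO", "CCO", "CCN", "C#N", "C(=O)C",
    "C(=O)CC", "C(=O)OC", "C(=O)N", "S(C)(=O)=O", "SC", "OC(C)C",
    "CC(C)O", "CN(C)C", "C(F)(F)F", "CC#N", "CC(C)C",
    "OCCO", "CCl", "NCC", "C(=O)NC", "OC(=O)C", "CCCO", "CSC",
    "N1CCCC1", "N1CCOCC1", "CCF",
]

# reactive substituents carrying a Michael acceptor
_REACTIVE_SUBS = [
    "C(=O)C=C",
    "C(=O)/C=C/C",
    "C=CC(C)=O",
    "/C=C/C(=O)OC",
    "C(=O)C=CC",
]

# reactive cores used directly as scaffolds
_REACTIVE_SCAFFOLDS_1 = [
    "O=C1C=CC(=O)C({0})=C1",       # substituted para-quinone
    "O=C1C=CC(=O)c2cc({0})ccc12",  # naphthoquinone
    "c1ccc2sc({0})nc2c1",          # benzothiazole, 2-substituted
]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of one synthetic benchmark dataset."""

    n_compounds: int = 2000
    positive_rate: float = 0.05
    label_noise: float = 0.0
    planted_rules: tuple[str, ...] = DEFAULT_PLANTED_RULES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_compounds < 2:
            raise ValueError("need at least 2 compounds")


@dataclass(frozen=True)
class LabeledCompound:
    smiles: str  # canonical
    label: int
    provenance: str = "original"  # or "generated-iteration-<t>"


@dataclass
class LabeledCompoundSet:
    """A deduplicated set of labeled compounds."""

    compounds: list[LabeledCompound]
    provenance: str = "original"

    def __post_init__(self) -> None:
        smis = [c.smiles for c in self.compounds]
        if len(set(smis)) != len(smis):
            raise ValueError("duplicate canonical SMILES in compound set")
        if any(c.label not in (0, 1) for c in self.compounds):
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.compounds], dtype=np.int64)

    @property
    def smiles(self) -> list[str]:
        return [c.smiles for c in self.compounds]

    def molecules(self) -> list[Molecule]:
        out = []
        for c in self.compounds:
            m = parse_and_canonicalize(c.smiles)
            assert m is not None
            out.append(m)
        return out

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "smiles": self.smiles,
                "label": self.labels,
                "provenance": [c.provenance for c in self.compounds],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe()[["smiles", "label"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "original") -> "LabeledCompoundSet":
        import pandas as pd

        df = pd.read_csv(path)
        seen: dict[str, int] = {}
        for smi, lab in zip(df["smiles"], df["label"]):
            mol = parse_and_canonicalize(str(smi))
            if mol is None:
                continue
            seen.setdefault(mol.smiles, int(lab))
        comps = [
            LabeledCompound(s, l, provenance) for s, l in sorted(seen.items())
        ]
        return cls(compounds=comps, provenance=provenance)


def compile_rules(rules) -> list[Chem.Mol]:
    out = []
    for r in rules:
        patt = Chem.MolFromSmarts(r)
        if patt is None:
            raise ValueError(f"invalid SMARTS rule: {r!r}")
        out.append(patt)
    return out


def matches_any_rule(mol: Molecule, compiled_rules) -> bool:
    rd = mol.to_rdkit()
    return any(rd.HasSubstructMatch(p) for p in compiled_rules)


def _candidate_smiles() -> tuple[list[str], list[str]]:
    """Enumerate (intended-positive, intended-negative) raw SMILES."""
    positives = []
    for scaf in _SCAFFOLDS_1:
        for sub in _REACTIVE_SUBS:
            positives.append(scaf.format(sub))
    for scaf in _SCAFFOLDS_2:
        for sub in _REACTIVE_SUBS:
            for other in _NEUTRAL_SUBS:
                positives.append(scaf.format(sub, other))
    for scaf in _REACTIVE_SCAFFOLDS_1:
        for sub in _NEUTRAL_SUBS:
            positives.append(scaf.format(sub))
    negatives = []
    for scaf in _SCAFFOLDS_1:
        for sub in _NEUTRAL_SUBS:
            negatives.append(scaf.format(sub))
    for scaf in _SCAFFOLDS_2:
        for s1, s2 in itertools.product(_NEUTRAL_SUBS, _NEUTRAL_SUBS):
            negatives.append(scaf.format(s1, s2))
    return positives, negatives


def generate_benchmark(cfg: BenchmarkConfig) -> LabeledCompoundSet:
    """Assemble a labeled benchmark dataset from the fragment grammar.

    The structural label is 1 iff the molecule matches at least one planted
    rule (verified with a substructure oracle after assembly, not assumed
    from the construction); labels are then independently flipped with
    probability ``label_noise``.  With zero noise, the realized positive
    fraction equals ``round(n * positive_rate) / n``.
    """
    rng = np.random.default_rng(cfg.seed)
    compiled = compile_rules(cfg.planted_rules)

    raw_pos, raw_neg = _candidate_smiles()
    order_pos = rng.permutation(len(raw_pos))
    order_neg = rng.permutation(len(raw_neg))

    n_pos_target = int(round(cfg.n_compounds * cfg.positive_rate))
    n_neg_target = cfg.n_compounds - n_pos_target

    seen: set[str] = set()
    pos_pool: list[str] = []
    neg_pool: list[str] = []

    def _consume(raw: list[str], order: np.ndarray, want_pos: int, want_neg: int):
        for idx in order:
            if len(pos_pool) >= want_pos and len(neg_pool) >= want_neg:
                return
            mol = parse_and_canonicalize(raw[idx])
            if mol is None or mol.smiles in seen:
                continue
            seen.add(mol.smiles)
            # oracle classification of the assembled structure
            if matches_any_rule(mol, compiled):
                if len(pos_pool) < want_pos:
                    pos_pool.append(mol.smiles)
            else:
                if len(neg_pool) < want_neg:
                    neg_pool.append(mol.smiles)

    _consume(raw_pos, order_pos, n_pos_target, 0)
    _consume(raw_neg, order_neg, n_pos_target, n_neg_target)

    if len(pos_pool) < n_pos_target or len(neg_pool) < n_neg_target:
        max_pos = len(pos_pool)
        max_neg = len(neg_pool)
        raise ValueError(
            f"positive_rate {cfg.positive_rate} unreachable for "
            f"n={cfg.n_compounds}: grammar yielded {max_pos} positives / "
            f"{max_neg} negatives; achievable positive counts span "
            f"[{max(0, cfg.n_compounds - max_neg)}, {max_pos}]"
        )

    smis = pos_pool + neg_pool
    labels = np.array([1] * len(pos_pool) + [0] * len(neg_pool), dtype=np.int64)
    if cfg.label_noise > 0:
        flips = rng.random(len(labels)) < cfg.label_noise
        labels = np.where(flips, 1 - labels, labels)

    # deterministic presentation order
    perm = rng.permutation(len(smis))
    comps = [
        LabeledCompound(smis[i], int(labels[i]), "original") for i in perm
    ]
    return LabeledCompoundSet(compounds=comps, provenance="original")


@dataclass(frozen=True)
class SplitResult:
    train: LabeledCompoundSet
    test: LabeledCompoundSet
    folds: tuple[tuple[int, ...], ...]  # validation index tuples into train


def _largest_remainder(counts: dict[int, int], fraction: float) -> dict[int, int]:
    """Per-class test counts preserving overall class proportions."""
    quotas = {c: n * fraction for c, n in counts.items()}
    base = {c: int(np.floor(q)) for c, q in quotas.items()}
    total_target = int(round(sum(counts.values()) * fraction))
    remainder = total_target - sum(base.values())
    order = sorted(quotas, key=lambda c: (-(quotas[c] - base[c]), c))
    for c in order[:remainder]:
        base[c] += 1
    return base


def stratified_split(
    ds: LabeledCompoundSet,
    test_fraction: float = 0.25,
    n_folds: int = 5,
    seed: int = 0,
) -> SplitResult:
    """Stratified train/test split plus stratified CV folds over the train set.

    Class proportions are preserved exactly up to +-1 compound rounding; the
    folds partition the training set.  Fully deterministic given the seed:
    compounds are ordered by canonical SMILES before the seeded shuffle.
    """
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    labels = ds.labels
    classes = sorted(set(labels.tolist()))
    if test_fraction > 0 and len(classes) < 2:
        raise ValueError("both classes must be present for a stratified split")

    rng = np.random.default_rng(seed)
    order = np.array(sorted(range(len(ds)), key=lambda i: ds.compounds[i].smiles))

    by_class: dict[int, np.ndarray] = {}
    for c in classes:
        idx = order[labels[order] == c]
        by_class[c] = idx[rng.permutation(len(idx))]

    counts = {c: len(v) for c, v in by_class.items()}
    test_counts = _largest_remainder(counts, test_fraction)

    test_idx: list[int] = []
    train_idx: list[int] = []
    for c in classes:
        k = test_counts[c]
        test_idx.extend(by_class[c][:k].tolist())
        train_idx.extend(by_class[c][k:].tolist())

    for c in classes:
        n_train_c = counts[c] - test_counts[c]
        if n_train_c < n_folds:
            raise ValueError(
                f"class {c} has {n_train_c} training members < n_folds={n_folds}"
            )

    train = LabeledCompoundSet(
        [ds.compounds[i] for i in train_idx], provenance=ds.provenance
    )
    test = LabeledCompoundSet(
        [ds.compounds[i] for i in test_idx], provenance=ds.provenance
    )

    # round-robin fold assignment per class over the (already shuffled) order
    fold_lists: list[list[int]] = [[] for _ in range(n_folds)]
    pos_in_train = {smi: i for i, smi in enumerate(train.smiles)}
    for c in classes:
        members = [i for i in by_class[c][test_counts[c]:]]
        for j, orig_i in enumerate(members):
            fold_lists[j % n_folds].append(pos_in_train[ds.compounds[orig_i].smiles])
    folds = tuple(tuple(sorted(f)) for f in fold_lists)
    return SplitResult(train=train, test=test, folds=folds)


def fixture_pool(n: int, seed: int = 0) -> list[Molecule]:
    """Unlabeled pool of ``n`` unique molecules spanning reactive and
    rule-free chemotypes, with 120 <= MW <= 600 Da (the stub resampling
    generator draws from such a pool)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    raw_pos, raw_neg = _candidate_smiles()
    # interleave reactive and neutral chemotypes ~1:3
    raw = raw_pos + raw_neg
    weights = np.array([1.0] * len(raw_pos) + [1.0] * len(raw_neg))
    order = rng.permutation(len(raw))
    seen: set[str] = set()
    out: list[Molecule] = []
    for idx in order:
        mol = parse_and_canonicalize(raw[idx])
        if mol is None or mol.smiles in seen:
            continue
        if not 120 <= mol.mw <= 600:
            continue
        seen.add(mol.smiles)
        out.append(mol)
        if len(out) == n:
            return out
    raise ValueError(
        f"fixture grammar exhausted at {len(out)} molecules; requested {n}"
    )
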