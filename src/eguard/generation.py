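"""Goal-directed molecule generation behind a pluggable interface.

The guidance signal is the scalar reward

    f(x) = w1 * m(x) + w2 * wt(x)

where m(x) is the current teacher's predicted interference probability and
wt(x) a molecular-weight desirability that is 1 on the 160-480 Da window of
typical small-molecule drug discovery (trapezoidal 40 Da ramps outside, so
optimizers see a gradient).  Weights default to 0.8/0.2 and are normalized.

A production RL generator is deliberately out of scope; two desk-scale
stubs implement the :class:`GeneratorProtocol`:

* :class:`ResamplingGenerator` — Boltzmann resampling from a fixed pool
  with a sharpening temperature schedule, emulating reward exploitation
  (and the accompanying diversity decay) without learning anything.
* :class:`GAGenerator` — a small fragment-based genetic algorithm
  (attach/delete mutations plus single-cut crossover) with an elitist
  population and a scaffold-occurrence cap standing in for diversity
  filters.

One generation stage runs ``n_steps`` optimizer steps of ``batch_size``
molecules each (default 250 x 100 = 25,000 compounds, counted before any
deduplication; duplicates are resolved at acquisition time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from rdkit import Chem

from .chem import Molecule, murcko_scaffold, parse_and_canonicalize
from .qsir import QSIRModel, predict_proba

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RewardWeights:
    """Weights of the interference and molecular-weight reward terms,
    normalized to sum to 1."""

    w1: float = 0.8
    w2: float = 0.2

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights must be non-negative")
        total = self.w1 + self.w2
        if total == 0:
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "w1", self.w1 / total)
        object.__setattr__(self, "w2", self.w2 / total)


@dataclass(frozen=True)
class GenerationSchedule:
    n_steps: int = 250
    batch_size: int = 100

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.batch_size < 1:
            raise ValueError("schedule dimensions must be positive")

    @property
    def pool_size(self) -> int:
        return self.n_steps * self.batch_size


def mw_desirability(mw: float) -> float:
    """Trapezoidal weight score: 1 on [160, 480] Da, linear ramps to 0 at
    <=120 and >=520 Da."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if mw <= 120 or mw >= 520:
        return 0.0
    if mw < 160:
        return (mw - 120) / 40.0
    if mw > 480:
        return (520 - mw) / 40.0
    return 1.0


def reward(m: float, wt: float, w: RewardWeights = RewardWeights()) -> float:
    """Convex combination f(x) = w1*m(x) + w2*wt(x), bounded in [0, 1]."""
    if not (0 <= m <= 1 and 0 <= wt <= 1):
        raise ValueError("m and wt must lie in [0, 1]")
    return w.w1 * m + w.w2 * wt


@dataclass
class ScoredBatch:
    m: np.ndarray
    wt: np.ndarray
    reward: np.ndarray


class Scorer(Protocol):
    def score(self, mols: list[Molecule]) -> ScoredBatch: ...


class TeacherScorer:
    """Scores molecules with the current teacher model via the reward."""

    def __init__(self, model: QSIRModel, weights: RewardWeights = RewardWeights()):
        self.model = model
        self.weights = weights

    def score(self, mols: list[Molecule]) -> ScoredBatch:
        m = predict_proba(self.model, mols)
        wt = np.array([mw_desirability(x.mw) for x in mols])
        f = self.weights.w1 * m + self.weights.w2 * wt
        return ScoredBatch(m=m, wt=wt, reward=f)


class FunctionScorer:
    """Wraps an arbitrary m(x) callable (e.g. a planted-rule indicator)."""

    def __init__(self, fn, weights: RewardWeights = RewardWeights()):
        self.fn = fn
        self.weights = weights

    def score(self, mols: list[Molecule]) -> ScoredBatch:
        m = np.array([float(self.fn(x)) for x in mols])
        wt = np.array([mw_desirability(x.mw) for x in mols])
        f = self.weights.w1 * m + self.weights.w2 * wt
        return ScoredBatch(m=m, wt=wt, reward=f)


@dataclass
class CandidatePool:
    """The generated pool U_r: molecules with their reward decomposition."""

    molecules: list[Molecule]
    reward: np.ndarray
    m: np.ndarray
    wt: np.ndarray
    step: np.ndarray
    in_train: np.ndarray | None = None  # duplicate-of-training flags
    in_test: np.ndarray | None = None  # duplicate-of-test flags (leakage)

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def smiles(self) -> list[str]:
        return [m.smiles for m in self.molecules]

    def deduplicate(self) -> "CandidatePool":
        """Keep the first occurrence of each canonical SMILES."""
        seen: set[str] = set()
        keep = []
        for i, mol in enumerate(self.molecules):
            if mol.smiles not in seen:
                seen.add(mol.smiles)
                keep.append(i)
        idx = np.array(keep)
        return CandidatePool(
            molecules=[self.molecules[i] for i in keep],
            reward=self.reward[idx],
            m=self.m[idx],
            wt=self.wt[idx],
            step=self.step[idx],
            in_train=None if self.in_train is None else self.in_train[idx],
            in_test=None if self.in_test is None else self.in_test[idx],
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "smiles": self.smiles,
                "reward": self.reward,
                "m": self.m,
                "wt": self.wt,
                "step": self.step,
            }
        )


@runtime_checkable
class GeneratorProtocol(Protocol):
    def propose(
        self, scorer: Scorer, schedule: GenerationSchedule, rng: np.random.Generator
    ) -> CandidatePool: ...


def _concat_pool(parts: list[tuple[list[Molecule], ScoredBatch, int]]) -> CandidatePool:
    mols: list[Molecule] = []
    m, wt, f, step = [], [], [], []
    for batch_mols, scored, t in parts:
        mols.extend(batch_mols)
        m.append(scored.m)
        wt.append(scored.wt)
        f.append(scored.reward)
        step.append(np.full(len(batch_mols), t))
    return CandidatePool(
        molecules=mols,
        reward=np.concatenate(f),
        m=np.concatenate(m),
        wt=np.concatenate(wt),
        step=np.concatenate(step),
    )


class ResamplingGenerator:
    """Boltzmann resampling stub: draws from a fixed pool with probability
    proportional to exp(f(x)/tau).

    The temperature decays geometrically from ``tau_start`` to ``tau_end``
    across steps, so late batches concentrate on high-reward molecules —
    a mode-collapse-like diversity decay without any learned model.
    """

    def __init__(
        self,
        pool_source: list[Molecule],
        tau_start: float = 1.0,
        tau_end: float = 0.2,
    ):
        if not pool_source:
            raise ValueError("pool_source must be non-empty")
        self.pool_source = pool_source
        self.tau_start = tau_start
        self.tau_end = tau_end
        self._last_logp: np.ndarray | None = None

    def _tau(self, t: int, n_steps: int) -> float:
        if n_steps == 1:
            return self.tau_start
        ratio = self.tau_end / self.tau_start
        return self.tau_start * ratio ** (t / (n_steps - 1))

    def propose(
        self, scorer: Scorer, schedule: GenerationSchedule, rng: np.random.Generator
    ) -> CandidatePool:
        scored = scorer.score(self.pool_source)
        parts = []
        for t in range(schedule.n_steps):
            tau = self._tau(t, schedule.n_steps)
            logits = scored.reward / tau
            p = np.exp(logits - logits.max())
            p /= p.sum()
            idx = rng.choice(len(self.pool_source), size=schedule.batch_size, p=p)
            batch = [self.pool_source[i] for i in idx]
            batch_scored = ScoredBatch(
                m=scored.m[idx], wt=scored.wt[idx], reward=scored.reward[idx]
            )
            parts.append((batch, batch_scored, t))
        self._last_logp = np.log(p)
        return _concat_pool(parts)

    def log_likelihood(self, mols: list[Molecule]) -> np.ndarray:
        """Log-probability of each molecule under the final-step sampling
        distribution; -inf for molecules outside the source pool."""
        if self._last_logp is None:
            raise ValueError("call propose() first")
        index = {m.smiles: i for i, m in enumerate(self.pool_source)}
        out = np.full(len(mols), -np.inf)
        for j, mol in enumerate(mols):
            i = index.get(mol.smiles)
            if i is not None:
                out[j] = self._last_logp[i]
        return out


# fragment library for GA mutations (standalone-parseable fragments)
_GA_FRAGMENTS = [
    "C", "CC", "CCC", "CO", "CCO", "CN", "CCN", "CF", "CCl",
    "C=O", "C(C)=O", "CC(C)=O", "C(N)=O", "C#N", "C=C", "CC=C",
    "C(=O)C=C", "C(=O)/C=C/C", "C=CC(C)=O",
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1",
    "C1CCCCC1", "C1CCNCC1",
    "O=C1C=CC(=O)C=C1", "c1ccc2sc(nc2c1)C",
]


class GAGenerator:
    """Fragment-based genetic algorithm stub.

    Per step, ``batch_size`` offspring are bred from the current population:
    parents are chosen proportionally to reward, modified by one of
    attach-fragment / delete-terminal-atom mutations or a single-cut
    crossover, and the population is updated elitistically.  A scaffold
    occurrence cap bounds how often any Murcko scaffold may appear in the
    emitted pool (diversity-filter analogue).  Invalid offspring fall back
    to their parent.
    """

    def __init__(
        self,
        seed_mols: list[Molecule],
        fragments: list[str] | None = None,
        scaffold_cap: int | None = None,
        population_size: int | None = None,
    ):
        if not seed_mols:
            raise ValueError("seed_mols must be non-empty")
        self.seed_mols = list(seed_mols)
        frags = fragments if fragments is not None else _GA_FRAGMENTS
        self.fragments = [Chem.MolFromSmiles(f) for f in frags]
        self.fragments = [f for f in self.fragments if f is not None]
        self.scaffold_cap = scaffold_cap
        self.population_size = population_size or max(50, len(seed_mols))

    # --- mutation operators ------------------------------------------------

    def _attach(self, mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
        frag = self.fragments[int(rng.integers(len(self.fragments)))]
        sites = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetTotalNumHs() > 0 and a.GetAtomicNum() in (6, 7)
        ]
        if not sites:
            return None
        site = int(sites[int(rng.integers(len(sites)))])
        combo = Chem.RWMol(Chem.CombineMols(mol, frag))
        fa_candidates = [
            a.GetIdx()
            for a in combo.GetAtoms()
            if a.GetIdx() >= mol.GetNumAtoms() and a.GetTotalNumHs() > 0
        ]
        if not fa_candidates:
            return None
        combo.AddBond(site, fa_candidates[0], Chem.BondType.SINGLE)
        return combo.GetMol()

    def _delete_terminal(self, mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
        terminals = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetDegree() == 1 and not a.GetIsAromatic()
        ]
        if not terminals or mol.GetNumAtoms() <= 5:
            return None
        em = Chem.RWMol(mol)
        em.RemoveAtom(int(terminals[int(rng.integers(len(terminals)))]))
        return em.GetMol()

    @staticmethod
    def _cut_fragments(mol: Chem.Mol, rng: np.random.Generator):
        bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
        ]
        if not bonds:
            return None
        bid = int(bonds[int(rng.integers(len(bonds)))])
        frag = Chem.FragmentOnBonds(mol, [bid], addDummies=True)
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
        return pieces if len(pieces) == 2 else None

    @staticmethod
    def _join(fa: Chem.Mol, fb: Chem.Mol) -> Chem.Mol | None:
        combo = Chem.RWMol(Chem.CombineMols(fa, fb))
        dummies = [at for at in combo.GetAtoms() if at.GetAtomicNum() == 0]
        if len(dummies) != 2:
            return None
        n1 = dummies[0].GetNeighbors()[0].GetIdx()
        n2 = dummies[1].GetNeighbors()[0].GetIdx()
        d_idx = sorted((dummies[0].GetIdx(), dummies[1].GetIdx()), reverse=True)
        if n1 in d_idx or n2 in d_idx:
            return None
        combo.AddBond(n1, n2, Chem.BondType.SINGLE)
        for d in d_idx:
            combo.RemoveAtom(d)
        return combo.GetMol()

    def _offspring(
        self, parent: Molecule, mate: Molecule, rng: np.random.Generator
    ) -> Molecule:
        op = rng.random()
        raw = parent.to_rdkit()
        try:
            if op < 0.45:
                child = self._attach(raw, rng)
            elif op < 0.65:
                child = self._delete_terminal(raw, rng)
            else:
                child = self._join_crossover(raw, mate.to_rdkit(), rng)
            if child is None:
                return parent
            Chem.SanitizeMol(child)
            smi = Chem.MolToSmiles(child)
            if "." in smi:
                return parent
            out = parse_and_canonicalize(smi)
            return out if out is not None else parent
        except Exception:
            return parent

    def _join_crossover(
        self, a: Chem.Mol, b: Chem.Mol, rng: np.random.Generator
    ) -> Chem.Mol | None:
        pa = self._cut_fragments(a, rng)
        pb = self._cut_fragments(b, rng)
        if pa is None or pb is None:
            return None
        return self._join(pa[int(rng.integers(2))], pb[int(rng.integers(2))])

    # --- main loop ----------------------------------------------------------

    def propose(
        self, scorer: Scorer, schedule: GenerationSchedule, rng: np.random.Generator
    ) -> CandidatePool:
        population = list(self.seed_mols)
        pop_scores = scorer.score(population).reward
        scaffold_counts: dict[str, int] = {}
        parts = []
        for t in range(schedule.n_steps):
            weights = pop_scores + 1e-6
            p = weights / weights.sum()
            batch: list[Molecule] = []

            def _admit(mol: Molecule) -> bool:
                if self.scaffold_cap is None:
                    batch.append(mol)
                    return True
                scaf = murcko_scaffold(mol).smiles
                if scaffold_counts.get(scaf, 0) >= self.scaffold_cap:
                    return False
                scaffold_counts[scaf] = scaffold_counts.get(scaf, 0) + 1
                batch.append(mol)
                return True

            attempts = 0
            while len(batch) < schedule.batch_size and attempts < schedule.batch_size * 8:
                attempts += 1
                i = int(rng.choice(len(population), p=p))
                j = int(rng.choice(len(population), p=p))
                _admit(self._offspring(population[i], population[j], rng))
            if len(batch) < schedule.batch_size:
                # cap starved the batch: fall back to cap-compliant parents
                logger.warning("GA batch starved at step %d; refilling with parents", t)
                for parent in population:
                    if len(batch) == schedule.batch_size:
                        break
                    _admit(parent)
            if len(batch) < schedule.batch_size:
                raise ValueError(
                    f"scaffold cap {self.scaffold_cap} starved GA step {t}: "
                    f"only {len(batch)}/{schedule.batch_size} admissible offspring"
                )
            scored = scorer.score(batch)
            parts.append((batch, scored, t))
            # elitist update
            merged = population + batch
            merged_scores = np.concatenate([pop_scores, scored.reward])
            order = np.argsort(-merged_scores, kind="stable")[: self.population_size]
            population = [merged[i] for i in order]
            pop_scores = merged_scores[order]
        return _concat_pool(parts)


class CountingStubGenerator:
    """Emits unique heteroatom-chain molecules by enumeration.

    Carries no chemistry whatsoever — it exists to exercise the counting
    contracts of a generation stage (exact pool size, flagging) cheaply.
    """

    def __init__(self, chain_length: int = 16):
        self.chain_length = chain_length

    def _enumerate(self, n: int) -> list[Molecule]:
        out: list[Molecule] = []
        seen: set[str] = set()
        i = 0
        L = self.chain_length
        while len(out) < n:
            if i >= 2**L:
                L += 1
                i = 0
                continue
            bits = format(i, f"0{L}b")
            i += 1
            smi = "".join("C" if b == "0" else "N" for b in bits)
            mol = parse_and_canonicalize(smi)
            if mol is not None and mol.smiles not in seen:
                seen.add(mol.smiles)
                out.append(mol)
        return out

    def propose(
        self, scorer: Scorer, schedule: GenerationSchedule, rng: np.random.Generator
    ) -> CandidatePool:
        mols = self._enumerate(schedule.pool_size)
        parts = []
        for t in range(schedule.n_steps):
            batch = mols[t * schedule.batch_size : (t + 1) * schedule.batch_size]
            parts.append((batch, scorer.score(batch), t))
        return _concat_pool(parts)


def run_generation_stage(
    gen: GeneratorProtocol,
    scorer: Scorer,
    schedule: GenerationSchedule,
    rng: np.random.Generator,
    train_smiles: set[str] | None = None,
    test_smiles: set[str] | None = None,
) -> CandidatePool:
    """Run one full generation stage and flag known molecules.

    The returned pool has exactly ``schedule.pool_size`` molecules (counted
    before deduplication).  Molecules whose canonical SMILES already occur
    in the training or test set are flagged, not dropped — test-set matches
    are excluded later, at acquisition.
    """
    pool = gen.propose(scorer, schedule, rng)
    if len(pool) < schedule.pool_size:
        deficit = schedule.pool_size - len(pool)
        if deficit > 0.1 * schedule.pool_size:
            raise ValueError(
                f"generator produced {len(pool)}/{schedule.pool_size} molecules"
            )
        logger.warning("generator short by %d molecules; refilling", deficit)
        refill_steps = max(1, -(-deficit // schedule.batch_size))
        extra = gen.propose(
            scorer, GenerationSchedule(refill_steps, schedule.batch_size), rng
        )
        pool = CandidatePool(
            molecules=pool.molecules + extra.molecules[:deficit],
            reward=np.concatenate([pool.reward, extra.reward[:deficit]]),
            m=np.concatenate([pool.m, extra.m[:deficit]]),
            wt=np.concatenate([pool.wt, extra.wt[:deficit]]),
            step=np.concatenate([pool.step, extra.step[:deficit]]),
        )
    if len(pool) != schedule.pool_size:
        raise ValueError(
            f"pool size {len(pool)} != schedule contract {schedule.pool_size}"
        )
    if not np.all(np.isfinite(pool.reward)):
        raise ValueError("non-finite rewards in generated pool")
    train_smiles = train_smiles or set()
    test_smiles = test_smiles or set()
    pool.in_train = np.array([s in train_smiles for s in pool.smiles])
    pool.in_test = np.array([s in test_smiles for s in pool.smiles])
    return pool
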