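"""The iterative teacher-generate-acquire-retrain cycle.

One iteration: the current teacher guides a goal-directed generation stage;
an acquisition strategy selects the k most informative molecules from the
deduplicated pool (exact test-set matches excluded); selections are
pseudo-labeled by the current teacher at a probability threshold; the
training set is augmented; the student is retrained with the frozen
hyperparameters and becomes the next teacher.  Defaults follow the study
design: five iterations, ten independent repetitions, k = 250, a
250 x 100 generation schedule, reward weights 0.8/0.2.

Per-iteration records track the data-side effects (training imbalance rate,
internal diversity / PAINS / scaffold similarity of the acquired set) and
the model-side effects (test MCC, EF, balanced accuracy, PR-AUC, and
CKA_rf drift from the initial teacher).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import qsir
from .acquisition import AcquisitionConfig, AcquisitionResult, acquire
from .chem import Molecule
from .evaluation import (
    classification_report,
    count_pains,
    imbalance_rate,
    internal_diversity,
    scaffold_similarity,
)
from .expert import ExpertScorerProtocol, HeuristicExpertScorer
from .generation import (
    GAGenerator,
    GenerationSchedule,
    GeneratorProtocol,
    ResamplingGenerator,
    RewardWeights,
    TeacherScorer,
    run_generation_stage,
)
from .model_analysis import cka_between_models
from .qsir import Hyperparams, QSIRModel, predict_proba
from .synthetic_data import (
    LabeledCompound,
    LabeledCompoundSet,
    SplitResult,
    stratified_split,
)

logger = logging.getLogger(__name__)

#: generator factory signature: (training set, rng) -> generator
GeneratorFactory = Callable[[LabeledCompoundSet, np.random.Generator], GeneratorProtocol]


@dataclass(frozen=True)
class LoopConfig:
    n_iterations: int = 5
    n_repetitions: int = 10
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    schedule: GenerationSchedule = field(default_factory=GenerationSchedule)
    weights: RewardWeights = field(default_factory=RewardWeights)
    pseudo_label_threshold: float = 0.5
    master_seed: int = 0
    test_fraction: float = 0.25
    n_folds: int = 5
    hyperparams: Hyperparams | None = None  # None -> run the 50-trial search
    n_hyperparam_trials: int = 50

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if not 0 < self.pseudo_label_threshold < 1:
            raise ValueError("pseudo_label_threshold must be in (0, 1)")

    def hash(self) -> str:
        blob = json.dumps(
            {
                "n_iterations": self.n_iterations,
                "n_repetitions": self.n_repetitions,
                "acquisition": vars(self.acquisition),
                "schedule": vars(self.schedule),
                "weights": vars(self.weights),
                "pseudo_label_threshold": self.pseudo_label_threshold,
                "master_seed": self.master_seed,
                "test_fraction": self.test_fraction,
                "n_folds": self.n_folds,
                "hyperparams": None
                if self.hyperparams is None
                else self.hyperparams.to_dict(),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class IterationRecord:
    iteration: int
    acquired_smiles: list[str]
    pseudo_labels: list[int]
    ir: float
    intdiv: float
    pains_count: int
    scaffold_sim: float
    metrics: dict[str, float]
    cka_vs_teacher: float

    def row(self) -> dict:
        return {
            "iteration": self.iteration,
            "n_acquired": len(self.acquired_smiles),
            "ir": self.ir,
            "intdiv": self.intdiv,
            "pains_count": self.pains_count,
            "scaffold_sim": self.scaffold_sim,
            "cka_vs_teacher": self.cka_vs_teacher,
            **self.metrics,
        }


@dataclass
class RunRecord:
    config_hash: str
    seed: int
    baseline_metrics: dict[str, float]
    baseline_ir: float
    records: list[IterationRecord]

    def rows(self) -> list[dict]:
        base = {
            "iteration": 0,
            "n_acquired": 0,
            "ir": self.baseline_ir,
            "intdiv": float("nan"),
            "pains_count": 0,
            "scaffold_sim": float("nan"),
            "cka_vs_teacher": 1.0,
            **self.baseline_metrics,
        }
        out = [{"seed": self.seed, **base}]
        out += [{"seed": self.seed, **r.row()} for r in self.records]
        return out


def pseudo_label(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary self-distillation labels: 1 iff probability >= threshold."""
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs >= threshold).astype(np.int64)


def augment_training_set(
    train: LabeledCompoundSet,
    acquired: list[Molecule],
    labels: np.ndarray,
    iteration: int = 0,
    test_smiles: set[str] | None = None,
) -> LabeledCompoundSet:
    """Union of the training set and pseudo-labeled acquisitions.

    Canonical-SMILES deduplication; on collision the existing training
    label wins over the pseudo-label (logged).  Any overlap with the test
    set is a leakage bug and raises.
    """
    if len(acquired) != len(labels):
        raise ValueError("labels must align with acquired molecules")
    test_smiles = test_smiles or set()
    leaked = [m.smiles for m in acquired if m.smiles in test_smiles]
    if leaked:
        raise ValueError(f"acquired molecules overlap the test set: {leaked[:3]}")
    existing = {c.smiles for c in train.compounds}
    new_compounds = list(train.compounds)
    tag = f"generated-iteration-{iteration}"
    added = set()
    for mol, lab in zip(acquired, labels):
        if mol.smiles in existing:
            logger.debug("collision with training set, existing label kept: %s",
                         mol.smiles)
            continue
        if mol.smiles in added:
            continue
        added.add(mol.smiles)
        new_compounds.append(LabeledCompound(mol.smiles, int(lab), tag))
    return LabeledCompoundSet(new_compounds, provenance="augmented")


@dataclass
class LoopState:
    """Mutable state of one repetition of the cycle."""

    cfg: LoopConfig
    train_set: LabeledCompoundSet
    test_set: LabeledCompoundSet
    hyperparams: Hyperparams
    model: QSIRModel
    initial_teacher: QSIRModel
    initial_train: LabeledCompoundSet
    generator: GeneratorProtocol
    expert: ExpertScorerProtocol | None
    rng: np.random.Generator
    train_seed: int
    iteration: int = 0
    _test_mols: list[Molecule] | None = None
    _test_smiles: set[str] | None = None

    def test_molecules(self) -> list[Molecule]:
        if self._test_mols is None:
            self._test_mols = self.test_set.molecules()
        return self._test_mols

    def test_smiles(self) -> set[str]:
        if self._test_smiles is None:
            self._test_smiles = set(self.test_set.smiles)
        return self._test_smiles


def evaluate_model(model: QSIRModel, test_set: LabeledCompoundSet,
                   test_mols: list[Molecule] | None = None) -> dict[str, float]:
    mols = test_mols if test_mols is not None else test_set.molecules()
    probs = predict_proba(model, mols)
    return classification_report(probs, test_set.labels)


def run_iteration(state: LoopState) -> IterationRecord:
    """Advance the cycle by one iteration, mutating ``state`` in place."""
    t = state.iteration + 1
    cfg = state.cfg
    scorer = TeacherScorer(state.model, cfg.weights)
    try:
        pool = run_generation_stage(
            state.generator,
            scorer,
            cfg.schedule,
            state.rng,
            train_smiles=set(state.train_set.smiles),
            test_smiles=state.test_smiles(),
        )
        result: AcquisitionResult = acquire(
            pool, cfg.acquisition, state.model, state.expert, state.rng
        )
        probs = predict_proba(state.model, result.molecules)
        labels = pseudo_label(probs, cfg.pseudo_label_threshold)
        state.train_set = augment_training_set(
            state.train_set, result.molecules, labels, t, state.test_smiles()
        )
        state.model = qsir.train(
            state.train_set, state.hyperparams, seed=state.train_seed + t
        )
        metrics = evaluate_model(state.model, state.test_set, state.test_molecules())
        scaf = scaffold_similarity(result.molecules, state.initial_train.molecules())
        record = IterationRecord(
            iteration=t,
            acquired_smiles=result.smiles,
            pseudo_labels=labels.tolist(),
            ir=imbalance_rate(state.train_set.n_positive, state.train_set.n_negative),
            intdiv=internal_diversity(result.molecules),
            pains_count=count_pains(result.molecules),
            scaffold_sim=scaf.mean,
            metrics=metrics,
            cka_vs_teacher=cka_between_models(
                state.initial_teacher, state.model, state.test_molecules()
            ),
        )
    except Exception as exc:
        raise RuntimeError(f"iteration {t} failed") from exc
    state.iteration = t
    return record


def default_ga_factory(
    train_set: LabeledCompoundSet, rng: np.random.Generator, n_seeds: int = 100
) -> GAGenerator:
    """GA stub seeded with a random sample of training molecules."""
    mols = train_set.molecules()
    idx = rng.choice(len(mols), size=min(n_seeds, len(mols)), replace=False)
    return GAGenerator([mols[i] for i in idx])


def default_resampling_factory(
    train_set: LabeledCompoundSet, rng: np.random.Generator, pool_size: int = 2000
) -> ResamplingGenerator:
    from .synthetic_data import fixture_pool

    return ResamplingGenerator(
        fixture_pool(pool_size, seed=int(rng.integers(2**31 - 1)))
    )


def run_single(
    cfg: LoopConfig,
    split: SplitResult,
    hp: Hyperparams,
    generator_factory: GeneratorFactory,
    expert: ExpertScorerProtocol | None,
    seed_seq: np.random.SeedSequence,
) -> RunRecord:
    """One repetition: fresh teacher, ``n_iterations`` full cycles."""
    rng = np.random.default_rng(seed_seq)
    train_seed = int(rng.integers(0, 2**31 - 1 - cfg.n_iterations))
    teacher = qsir.train(split.train, hp, seed=train_seed)
    generator = generator_factory(split.train, rng)
    state = LoopState(
        cfg=cfg,
        train_set=split.train,
        test_set=split.test,
        hyperparams=hp,
        model=teacher,
        initial_teacher=teacher,
        initial_train=split.train,
        generator=generator,
        expert=expert,
        rng=rng,
        train_seed=train_seed,
    )
    baseline = evaluate_model(teacher, split.test, state.test_molecules())
    records = []
    for _ in range(cfg.n_iterations):
        records.append(run_iteration(state))
        n_train = len(state.train_set)
        assert n_train >= len(split.train), "training set must never shrink"
    return RunRecord(
        config_hash=cfg.hash(),
        seed=train_seed,
        baseline_metrics=baseline,
        baseline_ir=imbalance_rate(split.train.n_positive, split.train.n_negative),
        records=records,
    )


def run_experiment(
    cfg: LoopConfig,
    dataset: LabeledCompoundSet,
    generator_factory: GeneratorFactory = default_ga_factory,
    expert: ExpertScorerProtocol | None = None,
    out_dir: str | Path | None = None,
) -> list[RunRecord]:
    """Full experiment: split, (optional) hyperparameter search, then
    ``n_repetitions`` independent seeded runs.

    Results are a pure function of (config, dataset): per-run seeds are
    spawned from the master seed by counter-based splitting.  If
    ``out_dir`` is given, per-iteration acquisitions and a summary CSV are
    persisted there.
    """
    if expert is None and cfg.acquisition.strategy.endswith("_skill"):
        expert = HeuristicExpertScorer()
    split = stratified_split(
        dataset, cfg.test_fraction, cfg.n_folds, seed=cfg.master_seed
    )
    hp = cfg.hyperparams
    if hp is None:
        hp = qsir.optimize_hyperparams(
            split.train, split.folds, cfg.n_hyperparam_trials, seed=cfg.master_seed
        )
        logger.info("selected hyperparameters: %s", hp.to_dict())
    master = np.random.SeedSequence(cfg.master_seed)
    children = master.spawn(cfg.n_repetitions)
    runs: list[RunRecord] = []
    for r, child in enumerate(children):
        try:
            run = run_single(cfg, split, hp, generator_factory, expert, child)
        except Exception:
            if out_dir is not None and runs:
                write_run_outputs(runs, cfg, out_dir)
            raise
        runs.append(run)
        logger.info(
            "repetition %d/%d done (final EF %.3f)",
            r + 1, cfg.n_repetitions, run.records[-1].metrics["ef"],
        )
    if out_dir is not None:
        write_run_outputs(runs, cfg, out_dir)
    return runs


def summary_frame(runs: list[RunRecord]):
    import pandas as pd

    rows = []
    for r, run in enumerate(runs):
        for row in run.rows():
            rows.append({"run": r, **row})
    return pd.DataFrame(rows)


def write_run_outputs(
    runs: list[RunRecord], cfg: LoopConfig, out_dir: str | Path
) -> Path:
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({"hash": cfg.hash(), "master_seed": cfg.master_seed}, indent=2)
    )
    for r, run in enumerate(runs):
        run_dir = out / f"run_{r}"
        run_dir.mkdir(exist_ok=True)
        for rec in run.records:
            it_dir = run_dir / f"iter_{rec.iteration}"
            it_dir.mkdir(exist_ok=True)
            pd.DataFrame(
                {"smiles": rec.acquired_smiles, "pseudo_label": rec.pseudo_labels}
            ).to_csv(it_dir / "acquired.csv", index=False)
            (it_dir / "metrics.json").write_text(json.dumps(rec.row(), indent=2))
    df = summary_frame(runs)
    df.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    return out / "summary.csv"
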