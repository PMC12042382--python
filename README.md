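# eguard

Expert-guided data augmentation and self-distillation for
assay-interference classifiers.

High-throughput screening produces false readouts when compounds interfere
with the assay itself — by reacting with thiols, redox cycling, or
inhibiting reporter enzymes such as firefly and nano-luciferase.
Classifiers that flag such compounds (quantitative structure–interference
relationship models, QSIR) are hard to train: measured datasets are small
(~4–5k compounds) and interference rates run from 1.5% to 20%. `eguard`
is for cheminformaticians who want to counter that imbalance by
*generating* the missing positives: an iterative loop in which the current
classifier steers a molecule generator, an acquisition function picks the
most informative candidates, and the classifier retrains on its own
pseudo-labels.

## Method

A balanced random forest m(x) on Morgan-3/2048 fingerprints (every tree
fit on a class-balanced bootstrap) is the teacher. Each iteration:

1. **Generate.** A generator optimizes the reward
   f(x) = ω₁·m(x) + ω₂·wt(x) (ω = 0.8/0.2), where wt(x) is a 160–480 Da
   molecular-weight desirability, over a 250 × 100 schedule → a 25,000-
   molecule pool U_r.
2. **Acquire.** One of five criteria selects k = 250 molecules from the
   deduplicated pool via A(x) = α·A_predictor(x) + β·A_human(x):
   Random, Greedy (top m(x)), EPIG (expected predictive information gain
   against the pool's top-1000 molecules, with trees as posterior
   samples), or Greedy/EPIG combined with an expert preference score
   (α = β = 1).
3. **Distill.** Selections are pseudo-labeled at m(x) ≥ 0.5, appended to
   the training set, and the student retrains with frozen hyperparameters,
   becoming the next teacher.

Evaluation tracks MCC, enrichment factor EF = precision/prevalence,
balanced accuracy, PR-AUC, the training imbalance rate
IR = |pos − neg|/(pos + neg), internal Tanimoto diversity, PAINS counts,
Murcko-scaffold similarity, and CKA with a random-forest leaf-sharing
kernel (CKA_rf) to quantify teacher→student drift. Full definitions and
conventions are in [docs/methods.md](docs/methods.md).

Production-scale RL generators and trained preference networks are
deliberately behind interfaces (`GeneratorProtocol`,
`ExpertScorerProtocol`); the package ships a Boltzmann-resampling stub, a
fragment-GA stub, and a QED-based heuristic expert so the whole loop runs
on a desk in minutes. A seeded synthetic-benchmark generator plants
interference chemotypes (Michael acceptors, quinones, benzothiazoles)
into a fragment grammar so every stage is testable without external data.

## Worked example

```python
from eguard import loop, qsir
from eguard.acquisition import AcquisitionConfig
from eguard.generation import GenerationSchedule
from eguard.synthetic_data import BenchmarkConfig, generate_benchmark

dataset = generate_benchmark(
    BenchmarkConfig(n_compounds=1000, positive_rate=0.05, label_noise=0.05, seed=7)
)
cfg = loop.LoopConfig(
    n_iterations=3,
    n_repetitions=2,
    acquisition=AcquisitionConfig(strategy="greedy", k=40),
    schedule=GenerationSchedule(n_steps=10, batch_size=25),
    master_seed=0,
    hyperparams=qsir.Hyperparams(n_estimators=100),
)
runs = loop.run_experiment(cfg, dataset)
df = loop.summary_frame(runs)
print(df.groupby("iteration")[["ir", "ef", "mcc", "cka_vs_teacher"]]
        .mean().round(3).to_string())
```

prints

```
              ir      ef    mcc  cka_vs_teacher
iteration
0          0.821   7.710  0.683           1.000
1          0.732   9.114  0.742           0.924
2          0.652   9.330  0.752           0.912
3          0.579  10.101  0.787           0.909
```

Iteration 0 is the non-augmented baseline. Greedy acquisition adds
predicted positives each round, so the training imbalance rate falls
(0.82 → 0.58), the enrichment factor rises (7.7 → 10.1: predicted
positives are ~10× enriched in true interferers over the 5% base rate),
MCC improves, and CKA_rf shows the student drifting moderately from the
initial teacher while staying in a similar partition geometry.

The same experiment runs from the command line:

```bash
eguard benchmark bench.yaml --out dataset.csv   # synthetic dataset CSV
eguard run config.yaml                          # full experiment
eguard report runs/greedy runs/random           # tables + Welch t-tests
```

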