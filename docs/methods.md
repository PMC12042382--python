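# Methods

## Problem setting

Assay-interference compounds — thiol-reactive electrophiles, redox cyclers,
luciferase inhibitors — produce false readouts in high-throughput screens.
Classifiers that flag them (quantitative structure–interference
relationship models, QSIR) face two compounding obstacles: public
interference datasets are small (~4–5k compounds), and positives are rare
(1.5–20%). This package implements an iterative remedy: use the current
classifier to steer a molecule generator toward putative interfering
compounds, select the most informative ones with an acquisition function,
pseudo-label them with the classifier itself (self-distillation), and
retrain. Optionally, a simulated medicinal-chemist preference score is
added to the acquisition criterion to keep selected molecules drug-like.

## The classifier

The teacher/student model is a balanced random forest over binary Morgan
fingerprints (radius 3, 2048 bits). Every tree is fit on a bootstrap
containing equal numbers of positives and negatives: each class is
resampled with replacement to the minority-class count. This addresses
imbalance structurally rather than by reweighting, and it makes each tree
an exchangeable posterior sample used later by EPIG and the forest kernel.
`predict_proba` is the soft-vote mean of per-tree leaf class frequencies.

Hyperparameters (`n_estimators` ∈ [100, 1000], `max_depth` ∈ {None, 4–32},
`min_samples_split` ∈ [2, 16], `max_features` ∈ {sqrt, log2, 0.1–1.0}) are
chosen by seeded random search, 50 trials by default, scored by mean MCC
over stratified five-fold cross-validation, then frozen for all
self-distillation iterations. MCC is the objective because it is the
primary performance measure throughout and is robust under imbalance.

## Reward and generation

Generation is guided by the scalar reward

    f(x) = w₁·m(x) + w₂·wt(x),      w₁ = 0.8, w₂ = 0.2 (normalized),

where m(x) is the current teacher's interference probability and wt(x) a
molecular-weight desirability equal to 1 on 160–480 Da. The window is
implemented as a trapezoid with 40 Da linear ramps (0 at ≤120 and ≥520 Da):
a hard indicator would give optimizers no gradient at the boundary, and
the ramp width is small against the window so scores inside it are
unaffected.

A full-scale RL generator is out of scope; the `GeneratorProtocol`
interface accepts any generator honoring a schedule of `n_steps` ×
`batch_size` molecules (default 250 × 100 = 25,000 per stage, counted
before deduplication; duplicates are resolved at acquisition). Two stubs
are provided:

- **ResamplingGenerator** draws from a fixed molecule pool with
  probability ∝ exp(f(x)/τ), τ decaying geometrically 1.0 → 0.2 across
  steps. Late batches concentrate on high-reward molecules, reproducing
  qualitatively the diversity decay that reward exploitation causes in
  learned generators. Sampling is with replacement, so the exact pool-size
  contract holds and the τ→0 limit concentrates fully on the argmax.
- **GAGenerator** is a small fragment GA: parents drawn ∝ reward, one of
  attach-fragment / delete-terminal-atom mutations or a single-cut
  crossover, elitist population update. A Murcko-scaffold occurrence cap
  (optional) bounds any scaffold's frequency in the emitted pool, standing
  in for a diversity filter; when the cap starves a batch, cap-compliant
  parents are re-emitted, and an error is raised only if nothing is
  admissible. Invalid offspring fall back to their parent, so batches are
  always full and valid.

A `CountingStubGenerator` (unique heteroatom chains by enumeration) exists
purely to exercise counting contracts cheaply.

## Acquisition

From the deduplicated pool, with exact test-set matches removed (canonical
SMILES match — mirroring leakage removal by exact fingerprint match), the
selection criterion is

    A(x) = α·A_predictor(x) + β·A_human(x).

Random, Greedy (top m(x)) and EPIG use β = 0; GreedySkill and EPIGSkill
use α = β = 1 with both components min-max normalized over the pool
(the scale on which a preference score and a probability or an information
gain are commensurable is otherwise undefined). Ties are broken by
canonical-SMILES order: deterministic, seed-independent, and logged.

**EPIG.** A candidate's score is the mutual information between its
predicted label and that of a random target x\* from the 1000 highest-m(x)
pool molecules: the expected KL divergence between the joint predictive
distribution and the product of marginals. For a forest, each tree is one
joint posterior sample (same-tree pairing): p(y, y\*|x, x\*) is the
fraction of trees voting (y, y\*), marginals are vote frequencies. Under
this estimator the joint being positive implies both marginals are
positive, so the KL is always finite; 0·log 0 is taken as 0. KL uses
natural logs — base only rescales rankings. The target expectation is
either exhaustive or Monte-Carlo over `epig_pair_samples` targets
(default 100) for desk-scale runtime. A deterministic ensemble yields
EPIG ≡ 0, and scores are non-negative by construction.

The target set is ranked by m(x) rather than by the full reward f(x);
this is configurable in spirit (the ranking enters only through
`epig_scores`' target selection), and with the default weights the two
orderings rarely differ because wt(x) is near-constant in the relevant
window.

## Expert proxy

The default `A_human` is a deterministic heuristic: QED minus
0.05·max(0, rotatable_bonds − 8) minus 0.10·max(0, halogens − 3), larger
preferred. An adapter accepts any external preference model as a callable
with an orientation flag (some preference models emit lower-is-better
scores; the flag makes the sign convention explicit). Raw scores are
min-max normalized per pool.

## The loop

Each iteration: generate → deduplicate/leakage-filter → acquire k
(default 250) → pseudo-label with the *current* teacher at threshold 0.5
(inclusive: probability ≥ 0.5 maps to 1) → augment the training set
(existing labels win on collision) → retrain with frozen hyperparameters.
Pseudo-labels are model-assigned rather than fixed-positive because the
acquired set legitimately contains both classes — this is what allows the
training imbalance rate to fall without assuming every generated molecule
interferes. Defaults: 5 iterations, 10 repetitions. Per-run seeds are
spawned from the master seed via `numpy.random.SeedSequence`, so runs are
independent and the whole experiment is a pure function of
(config, dataset): two executions write byte-identical summary CSVs.

Per-iteration records track the training imbalance rate
IR = |pos − neg|/(pos + neg), the acquired set's internal diversity,
PAINS count and scaffold similarity to the initial training set, the
test-set MCC / EF / balanced accuracy / PR-AUC, and CKA_rf drift from the
initial teacher.

## Metrics

- **MCC** with the 0-denominator convention → 0 (chance level).
- **EF** = precision / positive prevalence; undefined (NaN) with no
  predicted positives — 0 would wrongly signal anti-enrichment. Maximum is
  1/prevalence.
- **IntDiv_p** = 1 − (mean over all |G|² ordered fingerprint pairs of
  Tanimoto^p)^(1/p), Morgan radius 2 / 2048 bits, p = 1 by default.
  Normalizing over all ordered pairs including self-pairs keeps the value
  in [0, 1]; a normalization by 1/|G| over |G|² pairs would escape that
  range. Two empty fingerprints have Tanimoto 1, so duplicated trivial
  molecules do not inflate diversity.
- **PAINS**: a molecule counts once if it matches ≥1 alert from the
  standard curated catalog (families A/B/C, ~480 patterns, via RDKit's
  FilterCatalog).
- **Scaffold similarity**: mean over new molecules of the max Tanimoto
  (Morgan2/2048) between the molecule's Murcko scaffold and any reference
  scaffold; acyclic molecules are excluded and counted. Max-then-mean is
  one of several defensible aggregations; it answers "how close is each
  new scaffold to its nearest known scaffold".
- **Strategy comparison**: Welch's two-sample t-test on per-run metric
  values (fractional Welch–Satterthwaite df), at the best-mean-MCC
  iteration when comparing run directories.

## CKA with a forest kernel

K[i,j] = fraction of trees in which probes i and j share a leaf — an
average of block-indicator kernels, hence PSD with unit diagonal.
CKA(K₁, K₂) = ⟨K₁ᶜ, K₂ᶜ⟩_F / (‖K₁ᶜ‖_F‖K₂ᶜ‖_F) on double-centered kernels
(biased HSIC form; no debiasing). The probe set is the held-out test set.
A constant kernel centers to zero and has undefined alignment (NaN).

## Synthetic benchmark

Real interference datasets cannot be redistributed, so benchmarks are
generated: molecules are assembled from a fragment grammar (aromatic,
heteroaromatic and aliphatic scaffold templates × ~45 substituents), and
the label is planted — positive iff the molecule contains an
α,β-unsaturated carbonyl, a quinone, or a benzothiazole. These three
chemotypes track the real interference mechanisms (thiol reactivity,
redox cycling, luciferin-like luciferase interference) and respond
differentially to PAINS counting. Labels are verified by a substructure
oracle after assembly, then optionally flipped independently with
probability `label_noise`. Near-miss negatives (saturated carbonyls,
nitriles, benzoxazole-free heterocycles) keep the task from being
trivially separable. At zero noise the realized positive count is exactly
round(n·rate); noise perturbs the realized rate around that value.

What the generator does *not* emulate: real chemical-space breadth
(the grammar spans ~10⁴ unique molecules), activity cliffs, assay-specific
label structure, or property-matched decoys. Passing the loop-improvement
test therefore shows that the machinery enriches a learnable planted
signal under realistic imbalance and noise — not that equivalent gains
transfer to any particular experimental dataset.

Splits are stratified exactly (largest-remainder per class, deterministic
remainder placement after ordering by canonical SMILES), with stratified
CV folds partitioning the training set.

## Desk-scale study sizes

The shipped verification study uses n = 2,000 compounds (5% positives, 5%
label noise), the GA generator at a 12 × 25 schedule, greedy acquisition
of k = 50 over 5 iterations, 10 repetitions, and a 100-tree forest with
otherwise default tree parameters. These sizes keep a full study in the
low minutes on one CPU while preserving the qualitative regime of
interest (heavy imbalance, noisy labels, pool ≫ k). Under these
conditions the final-iteration enrichment factor exceeds the baseline and
the imbalance rate falls in essentially all seeded runs; means are
reported by `scripts/acceptance.py`.

## Numerical and degenerate-input conventions

- Invalid SMILES are dropped and counted, never imputed.
- Tanimoto 0/0 → 1; MCC zero denominator → 0; EF with no predicted
  positives → NaN; CKA of constant kernels → NaN; all documented at the
  function level.
- Preference normalization of a constant vector → 0.5 everywhere.
- EPIG clips at 0 against floating-point underdraft; zero joint cells
  contribute 0.
- All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers; sklearn trees receive derived integer seeds.

## Known limitations

- The GA's chemistry is crude (no valence-aware fragment placement beyond
  RDKit sanitization, no ring mutations); it optimizes the reward well at
  desk scale but is not a substitute for a trained generative model's
  chemical quality.
- `log_likelihood` is implemented only by the resampling stub (its final
  sampling distribution); the GA has no meaningful likelihood.
- The expert proxy is a fixed heuristic; conclusions about
  "expert-guided" variants are conclusions about that heuristic.
- Balanced bootstraps subsample the majority class aggressively at
  extreme imbalance; with very few positives each tree sees few unique
  negatives, inflating variance — mitigated by more trees.
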