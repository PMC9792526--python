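# Methods

## Scope and data model

The package models four-state stroke-risk screening data. A record is a
row of 34 features whose names, kinds and codings are fixed by the schema
module: 22 documented clinical features (e.g. `LSBP` left systolic blood
pressure, normal band 80–140 mmHg; `Sm` smoking coded 2 = yes, 1 =
quitting, 0 = no; `Ys` years of smoking, defined only for (ex-)smokers),
right-arm pressures `RSBP`/`RDBP` coded analogously to the left-arm
readings, and ten *filler* features that pad the table to its full width —
these are labelled as filler in the schema because only part of the
registry's feature list is documented, and they carry invented but
plausible codings. Labels are the risk state `risk ∈ {0 low, 1 medium,
2 high, 3 attack}` and the derived binary `occurrence = 1{risk = 3}`.

## Synthetic registry generator

The real registry is not available, so all experiments run on synthetic
tables that reproduce its *structure*, not its marginals:

- categoricals are drawn uniformly from their codes; continuous features
  from a truncated normal centred at the midpoint of the plausible range
  with sd = width/6 (keeps essentially all mass inside the range without
  extra schema parameters);
- `Ys` is 0 for nonsmokers and uniform over its range otherwise;
- a latent score `s = Σ β_j z_j + Σ γ_ab z_a z_b + ε`, with z the
  per-column standardized values (so coefficients are comparable across
  features), ε Gaussian with sd `noise_scale`;
- risk labels are assigned by rank on the score with class sizes
  apportioned exactly (largest remainder) from the target proportions —
  default 7221 : 5868 : 5475 : 1967, i.e. attack ≈ 1 : 10 — so imbalance is
  controlled to ±1 sample per class. The registry's own labelling rule is
  unknown; quantile assignment was chosen because it makes class
  proportions exact and the planted structure recoverable.

The default study conditions (used by the pipeline, the recovery
experiments and the acceptance script) put moderate main effects on the
documented risk factors and two dominant planted pair effects,
γ(LSBP, Exs) = 2.0 and γ(Sm, LDBP) = 1.5, with noise sd 0.8. What passing
tests on these data show is that the pipeline can *recover known order-2
structure and known imbalance behaviour*; they say nothing about the
marginal distributions, missingness patterns or label noise of real
screening data, which the generator does not attempt to imitate.

## Preprocessing

Cleaning drops rows with a missing risk label, sets missing `Ys` to 0 for
nonsmokers, imputes other missing continuous values by the column median,
and drops rows with out-of-code categorical values (logged). Encoding
keeps one column per feature: categorical codes pass through as integers
(the models have one input neuron per feature, which rules out one-hot),
continuous columns are standardized with moments fitted on the training
split only and reused on test — the leakage-safe convention, adopted
because the original protocol is silent on scaling. A zero-variance column
gets sd clamped to 1 with a warning. The default test fraction is 0.15,
chosen because the printed test-set class counts are ≈ 15 % of the cleaned
totals; splits are stratified by risk.

## Architectures

- **Base DNN**: 34 (or 20) → 17 ReLU → dropout 0.2 → 4 logits; 667
  parameters at width 34.
- **QIDeep**: the same deep body; an embedding table with one latent
  vector `V_i ∈ R^4` per distinct feature appearing in a selected pair;
  `y_QI = Σ_{(i,j)∈pairs} ⟨V_i,V_j⟩ x_i x_j` (a flag switches to the full
  factorization-machine sum over the pool, computed by the ½[(Σvx)² −
  Σv²x²] reformulation). The concatenation [deep 4-vector ⊕ y_QI] feeds a
  trainable linear 5 → 4 head. Applying softmax directly to the 5-vector
  would create five pseudo-classes, so the head variant is the default —
  training and attribution both operate on pre-softmax logits. Continuous
  features enter the QI layer as value-scaled latent vectors (v·x);
  categorical codes are used as numeric x.
- **MMOE**: experts are the 11-neuron single-layer network and a QIDeep
  body whose last hidden layer ⊕ y_QI (width 18) is linearly projected to
  the common mixing width 11; one softmax gate per objective (a linear map
  from the input, 2 weights, rows sum to 1); towers omitted — linear heads
  read the mixed representation (1 sigmoid logit for occurrence, 4 softmax
  logits for risk). Joint loss = sum of BCE and CE; the trainer minimizes
  it scaled by 1/batch, which leaves the optimum unchanged.

All networks run on the package's own reverse-mode autodiff over float64
numpy arrays (dense layers, ReLU/sigmoid/softmax, embedding gather, fused
cross-entropy losses, inverted dropout, Adam). Everything is seeded through
`numpy.random.Generator`; single-threaded runs are bit-reproducible.

## Training

Adam, learning rate 0.01, batch size 256 (the protocol's batch size is
unstated; 256 is a standard choice at these sample sizes), at most
120–200 epochs. Early stopping monitors the loss on a stratified 10 %
validation slice of the training split (the validation protocol behind the
stated patience is unknown; 10 % stratified is the common convention):
training stops after `patience` (default 20) consecutive non-improving
epochs and the best-validation parameters are restored, so the returned
model never has validation loss above the best observed. A non-finite
training or validation loss aborts with diagnostics.

## Shapley layer

Attributions use the model-agnostic Shapley formulation with a background
set: v(S) is the mean model output with features in S taken from the
explained row and the rest from the background rows. The exact enumerator
(≤ 12 features, 2^m coalitions) is the canonical oracle and satisfies
efficiency, symmetry and dummy exactly. For the full table a
permutation-sampling estimator averages telescoping marginal gains along
random feature orders; any residual of the additive identity is
redistributed proportionally to |φ| so efficiency holds to 1e-9.
Attributions are computed on logits (pre-softmax), one explainer per risk
state; `y_base` is the per-state mean logit over a fixed background sample
(default 60–100 training rows).

Order-2 selection: the candidate pool is the top-7 features by overall
mean |φ|; pairwise Shapley interaction indices (inclusion–exclusion on the
exact coalition values, averaged over a sample of rows) are summed in
absolute value over the four states and the top-n pairs are taken, with a
lexicographic tie-break. A "dependency value" — the fraction of variance
of φ_j linearly explained by a partner feature's value, i.e. the spread
visible in a dependence plot — is reported alongside but does not enter
the ranking, since no principled combination rule presents itself.

## Evaluation

Per-state precision/recall/F1 in percent from the confusion matrix (0 on
degenerate denominators), unweighted macro means, accuracy, and
Mann–Whitney rank AUC (ties count ½) for binary scores. Repeated runs are
aggregated as mean ± sample sd (ddof = 1) with a 95 % normal CI,
mean ± 1.96·sd/√runs — the CI convention is the package's choice, stated
here because several conventions exist. Relative change
(100·(new−old)/old) and absolute percentage-point change are distinct
operations (`percent_change`, `point_change`) and reports label which is
used.

## Problem sizes

The package's own experiments run at n = 5000 rows (pipeline, acceptance
script; 3–5 training repeats per model) and n = 2500 (10-seed recovery and
multi-objective comparisons), with interaction screening on 20 evaluation
rows against a 20-row background. These sizes were chosen as the smallest
at which the planted structure is reliably recoverable and repeated-run
statistics are stable on a single CPU.

## Known limitations

- The generator reproduces codings, ranges, imbalance and planted
  interactions only; no real-data marginals, missingness or label noise.
- Interaction screening on a *trained* network inherits the network's
  estimation noise: the weaker planted pair occasionally ranks behind
  "halo" pairs formed by the strongest main-effect features, so top-3
  recovery of both pairs holds in most but not all seeds.
- The permutation estimator's error scales with the strength of
  interactions in the explained model; the exact enumerator is limited to
  12 features by the 2^m coalition count.
- MMOE is fixed at two experts and two objectives; towers, though
  config-flagged, are not implemented beyond the linear heads.
- Baselines (random forest, logistic regression, gradient boosting) are
  thin wrappers over scikit-learn inside the experiment runner and are not
  tuned.
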