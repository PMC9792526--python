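# qideep

Stroke-risk assessment models for four-state screening data: a
quadratic-interaction deep network (QIDeep), a two-objective multi-gate
mixture-of-experts (MMOE), Shapley-value explanations, and a synthetic
screening-registry generator with known ground truth.

## The problem

Population stroke screening assigns each participant one of four risk
states — low, medium, high, or *attack* (at least one stroke already
suffered) — from 34 mixed categorical/continuous clinical features (blood
pressure, smoking, physical inactivity, glycaemic and lipid panels, …).
Two things make this hard: the attack state is rare (attack : non-attack is
roughly 1 : 10, class counts about 7221 : 5868 : 5475 : 1967), and pairwise
*synergies* between risk factors (e.g. smoking × blood pressure) carry
signal that a plain feed-forward network extracts poorly from a small
table. Clinically, recall of the attack state matters most.

## The models

**Base DNN.** A multilayer perceptron `x → ReLU(34→17) → dropout(0.2) → 4
logits`, trained with four-class cross entropy.

**QIDeep.** The base DNN body plus a quadratic-interaction (QI) component
in the style of a factorization machine. Each selected feature of the
order-2 pairs gets a latent vector `V_i ∈ R^k` (k = 4) and the QI output is

```
y_QI = Σ_{(i,j) selected} ⟨V_i, V_j⟩ x_i x_j
     = ½ Σ_l [ (Σ_i v_il x_i)² − Σ_i v_il² x_i² ]     (all-pairs form, O(nk))
```

The 4 pre-activation outputs of the deep component are concatenated with
the scalar `y_QI` and a final linear layer maps the 5-vector to 4 class
logits; softmax is applied only inside the loss. Which pairs enter the QI
layer is decided by Shapley screening (below) — restricting to a handful of
pairs keeps the parameter count compatible with a small dataset.

**MMOE.** Two experts (an 11-neuron single-hidden-layer network and a
QIDeep body), one softmax gate per objective producing convex weights
`g^k(x)` with `Σ_i g^k_i(x) = 1`, mixed representations
`f^k(x) = Σ_i g^k_i(x) f_i(x)`, and two linear heads: a single sigmoid
logit for stroke *occurrence* (the auxiliary objective, = attack
indicator) and 4 softmax logits for the risk state. The joint loss is the
unweighted sum `Σ BCE(y, h₁(x)) + Σ CE(z, h₂(x))`. The auxiliary binary
objective pulls capacity toward the rare attack state.

**Shapley explanations.** Attributions are computed on logits with one
explainer per state: `y_i = y_base + Σ_j φ_ij`, where `y_base` is the mean
model output over a background sample. An exact coalition enumerator
(≤ 12 features) is the canonical oracle; a permutation-sampling estimator
handles the full 34-feature table. Mean |φ| ranks feature importance;
pairwise Shapley interaction indices over a small candidate pool select the
order-2 pairs; force and dependence records export per-patient
explanations.

All training uses Adam (lr 0.01) with early stopping (patience 20) on a
stratified validation slice, restoring the best-validation parameters.

## Worked example

```python
from qideep import ExperimentConfig, run_pipeline

cfg = ExperimentConfig(n_samples=5000, n_repeats=3, rf_repeats=3, seed=1)
res = run_pipeline(cfg)
print(res.summary_table().round(2))
print("pool", res.candidate_pool)
print("pairs", res.selected_pairs)
```

prints (one CPU, ~30 s):

```
          accuracy  macro_recall  macro_precision  macro_f1  attack_recall
base_dnn     75.82         75.63            76.50     76.00          77.78
qideep       80.09         80.02            81.65     80.71          81.48
mmoe         80.18         80.30            80.48     80.32          82.87
rf           61.02         56.96            63.16     58.65          43.06
lr           51.33         53.26            52.32     52.34          69.44
gbdt         66.80         64.79            67.97     66.11          59.72
pool ['Exs', 'Sm', 'LDBP', 'LSBP', 'HS', 'Wt', 'TC']
pairs [('LDBP', 'Sm'), ('LDBP', 'LSBP'), ('Exs', 'LSBP')]
```

Each row is a model evaluated on the held-out 15% split (metrics in %,
mean over repeated training seeds). The generator planted the pair effects
(LSBP, Exs) and (Sm, LDBP); both appear in the selected top-3 pairs. Adding
those quadratic features lifts accuracy over the base DNN, and the
two-objective MMOE attains the best attack-state recall — tree and linear
baselines fall behind on the rare class. The same workflow is available
from the shell as `qideep simulate|pipeline|explain|metrics`.

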