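"""The three risk-prediction architectures.

* **Base DNN** — a multilayer perceptron on all features: input -> hidden
  (17 neurons, ReLU) -> dropout(0.2) -> 4 output neurons, one per risk
  state (low/medium/high/attack).
* **QIDeep** — the base DNN body plus a quadratic-interaction (QI)
  component.  Selected feature pairs get learned latent vectors V_i of
  length k; the QI output is the factorization-machine sum
  ``y_QI = sum_{(i,j) selected} <V_i, V_j> x_i x_j``.  The deep component's
  4 pre-activation outputs are concatenated with the y_QI scalar and a
  final linear layer maps the 5-vector to 4 logits (probabilities via
  softmax only inside the loss).
* **MMOE** — a two-objective multi-gate mixture of experts.  Expert 1 is a
  single 11-neuron hidden layer; expert 2 is a QIDeep body.  One softmax
  gate per objective mixes the experts' last-hidden representations; linear
  heads emit 1 logit (stroke occurrence, sigmoid) and 4 logits (risk state,
  softmax).  The joint loss is the unweighted sum of binary and multiclass
  cross entropy.

Training uses Adam with early stopping on a stratified validation subset;
the best-validation parameters are restored.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import (Adam, Dense, Tensor, add, bce_with_logits, concat,
                        constant, cross_entropy_with_logits, dropout,
                        gather_rows, matmul, mul, relu, scale, softmax, tsum)

__all__ = ["DeepConfig", "QIConfig", "TrainConfig", "MMOEConfig",
           "BaseDNN", "QIDeep", "MMOE", "build_base_dnn", "build_qideep",
           "build_mmoe", "qi_forward", "mmoe_loss", "train", "TrainHistory"]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class DeepConfig:
    input_dim: int
    hidden_dims: tuple[int, ...] = (17,)
    dropout: float = 0.2
    output_dim: int = 4
    activation: str = "relu"

    def __post_init__(self):
        if self.output_dim not in (1, 4):
            raise ValueError("output_dim must be 1 or 4")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only ReLU activation is supported")


@dataclass(frozen=True)
class QIConfig:
    """Order-2 feature configuration.

    ``pairs`` are index pairs into the model input columns; ``latent_dim``
    is the embedding length k (default 4).  When ``all_pairs`` is true the
    QI sum runs over every pair of the distinct QI features instead of only
    the selected pairs.
    """

    pairs: tuple[tuple[int, int], ...]
    latent_dim: int = 4
    all_pairs: bool = False

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        seen = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError("self-pairs are not allowed")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError("duplicate pair")
            seen.add(key)

    @property
    def qi_feature_indices(self) -> tuple[int, ...]:
        return tuple(sorted({i for p in self.pairs for i in p}))


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    optimizer: str = "adam"
    patience: int = 20
    max_epochs: int = 200
    batch_size: int = 256
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only Adam is supported")
        if self.patience < 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass(frozen=True)
class MMOEConfig:
    input_dim: int = 20
    expert1_hidden: int = 11
    expert2_deep: DeepConfig | None = None     # defaults to (input_dim,[17],0.2,4)
    qi: QIConfig = QIConfig(pairs=())
    n_experts: int = 2
    n_objectives: int = 2
    expert_width: int = 11                     # common mixing width
    use_towers: bool = False

    def __post_init__(self):
        if self.n_experts != 2 or self.n_objectives != 2:
            raise ValueError("this MMOE is fixed at 2 experts / 2 objectives")
        if self.use_towers:
            raise NotImplementedError(
                "tower networks are not implemented; linear heads read the "
                "mixed representation directly")


# --------------------------------------------------------------------------
# QI component

def qi_forward(x_qi: np.ndarray, V: np.ndarray) -> float:
    """Quadratic-interaction output for one sample over all feature pairs.

    Computes ``sum_{i<j} <V_i, V_j> x_i x_j`` via the O(n*k) reformulation
    ``1/2 * sum_l [ (sum_i v_il x_i)^2 - sum_i v_il^2 x_i^2 ]``.
    """
    x = np.asarray(x_qi, dtype=float).ravel()
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != x.size:
        raise ValueError("V must be (n, k) with n == len(x_qi)")
    s = V.T @ x                       # (k,) per-latent-position sums
    sq = (V ** 2).T @ (x ** 2)        # (k,)
    return float(0.5 * (s ** 2 - sq).sum())


def _qi_output(X: Tensor, V: Tensor, qi: QIConfig,
               feat_index: dict[int, int]) -> Tensor:
    """Batched y_QI column (m, 1) as an autodiff graph over embeddings V."""
    if not qi.pairs:
        return constant(np.zeros((X.shape[0], 1)))
    feats = qi.qi_feature_indices
    Xq = X.data[:, list(feats)]                     # input is constant wrt params
    if qi.all_pairs:
        # full FM reformulation over the QI feature pool
        S = matmul(constant(Xq), V)                 # (m, k)
        S2 = tsum(mul(S, S), axis=1, keepdims=True)
        Q = matmul(constant(Xq ** 2), mul(V, V))
        Qs = tsum(Q, axis=1, keepdims=True)
        return scale(ad.sub(S2, Qs), 0.5)
    # restricted sum over the selected pairs only
    i_idx = [feat_index[i] for i, _ in qi.pairs]
    j_idx = [feat_index[j] for _, j in qi.pairs]
    inner = tsum(mul(gather_rows(V, i_idx), gather_rows(V, j_idx)), axis=1)
    P = Xq[:, [feats.index(i) for i, _ in qi.pairs]] * \
        Xq[:, [feats.index(j) for _, j in qi.pairs]]      # (m, n_pairs) x_i*x_j
    return matmul(constant(P), ad.Tensor(inner.data.reshape(-1, 1),
                                         parents=(inner,),
                                         bwd=lambda g: (g.ravel(),)))


# --------------------------------------------------------------------------
# predictors

class _Predictor:
    """Shared prediction surface: logits, probabilities, argmax classes."""

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(X, float)).data

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.predict_logits(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_logits(X).argmax(axis=1)

    def loss(self, X: np.ndarray, y, train: bool = False,
             rng: np.random.Generator | None = None) -> Tensor:
        return cross_entropy_with_logits(self.forward(X, train, rng), y)

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


class BaseDNN(_Predictor):
    """Plain MLP risk classifier (or binary DNN-B when output_dim == 1)."""

    def __init__(self, config: DeepConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dims = [config.input_dim, *config.hidden_dims, config.output_dim]
        self.layers = [Dense(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, X, train=False, rng=None):
        h = constant(np.asarray(X, float))
        for layer in self.layers[:-1]:
            h = relu(layer(h))
            h = dropout(h, self.config.dropout, rng, train)
        return self.layers[-1](h)

    def hidden(self, X, train=False, rng=None) -> Tensor:
        """Last hidden representation (before the output layer)."""
        h = constant(np.asarray(X, float))
        for layer in self.layers[:-1]:
            h = relu(layer(h))
            h = dropout(h, self.config.dropout, rng, train)
        return h

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def loss(self, X, y, train=False, rng=None):
        logits = self.forward(X, train, rng)
        if self.config.output_dim == 1:
            return bce_with_logits(logits, np.asarray(y).reshape(-1, 1))
        return cross_entropy_with_logits(logits, y)


class QIDeep(_Predictor):
    """Deep component + quadratic-interaction component.

    The deep component is structurally a base DNN; the QI component embeds
    the distinct features of the selected pairs into latent vectors (one
    row of V per feature) and emits the scalar y_QI.  The concatenated
    5-vector feeds a final linear layer producing the 4 class logits.
    """

    def __init__(self, deep: DeepConfig, qi: QIConfig, seed: int = 0):
        self.deep_config = deep
        self.qi_config = qi
        rng = np.random.default_rng(seed)
        dims = [deep.input_dim, *deep.hidden_dims, deep.output_dim]
        self.deep_layers = [Dense(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        feats = qi.qi_feature_indices
        self._feat_index = {f: r for r, f in enumerate(feats)}
        n = max(len(feats), 1)
        self.V = ad.parameter(rng.normal(0.0, 0.1, size=(n, qi.latent_dim)))
        self.head = Dense(deep.output_dim + 1, deep.output_dim, rng)
        if not qi.pairs:
            logger.info("QIDeep built with no pairs: QI output is constant 0")

    def _deep_out(self, X, train, rng):
        h = constant(np.asarray(X, float))
        for layer in self.deep_layers[:-1]:
            h = relu(layer(h))
            h = dropout(h, self.deep_config.dropout, rng, train)
        return h, self.deep_layers[-1](h)

    def body(self, X, train=False, rng=None) -> Tensor:
        """Last-hidden-layer representation ⊕ y_QI (used by MMOE mixing)."""
        hidden, _ = self._deep_out(X, train, rng)
        X = np.asarray(X, float)
        yqi = _qi_output(constant(X), self.V, self.qi_config, self._feat_index)
        return concat([hidden, yqi], axis=1)

    def forward(self, X, train=False, rng=None):
        X = np.asarray(X, float)
        _, deep_out = self._deep_out(X, train, rng)
        yqi = _qi_output(constant(X), self.V, self.qi_config, self._feat_index)
        return self.head(concat([deep_out, yqi], axis=1))

    def parameters(self):
        ps = [p for layer in self.deep_layers for p in layer.params]
        if self.qi_config.pairs:
            ps.append(self.V)
        return ps + self.head.params

    @property
    def n_qi_params(self) -> int:
        """Embedding entries: one length-k latent vector per distinct QI feature."""
        return len(self.qi_config.qi_feature_indices) * self.qi_config.latent_dim


class MMOE(_Predictor):
    """Two-objective multi-gate mixture of experts.

    Objective 1: stroke occurrence (binary, sigmoid head).  Objective 2:
    four-state risk (softmax head).  Per objective a softmax gate over the
    two experts mixes their representations; towers are omitted by default
    and linear heads read the mixed representation directly.
    """

    def __init__(self, config: MMOEConfig, seed: int = 0):
        self.config = config
        d = config.input_dim
        rng = np.random.default_rng(seed)
        e1_seed, e2_seed = rng.integers(0, 2 ** 31 - 1, size=2)
        # expert 1: single hidden layer, 11 neurons
        self.expert1 = BaseDNN(DeepConfig(d, (config.expert1_hidden,), 0.2, 4),
                               seed=int(e1_seed))
        deep = config.expert2_deep or DeepConfig(d, (17,), 0.2, 4)
        self.expert2 = QIDeep(deep, config.qi, seed=int(e2_seed))
        w = config.expert_width
        e2_width = deep.hidden_dims[-1] + 1      # hidden ⊕ y_QI
        self.proj2 = Dense(e2_width, w, rng)     # project expert2 to mixing width
        self.gates = [Dense(d, config.n_experts, rng) for _ in range(2)]
        self.head_occ = Dense(w, 1, rng)
        self.head_risk = Dense(w, 4, rng)
        self._forced_gate: np.ndarray | None = None   # test hook

    def _expert_reps(self, X, train, rng):
        f1 = self.expert1.hidden(X, train, rng)                  # (m, 11)
        f2 = self.proj2(self.expert2.body(X, train, rng))        # (m, 11)
        return f1, f2

    def gate_weights(self, X) -> list[np.ndarray]:
        """Per-objective gate weights over experts, rows summing to 1."""
        Xc = constant(np.asarray(X, float))
        return [softmax(g(Xc), axis=1).data for g in self.gates]

    def _mix(self, g: Tensor, f1: Tensor, f2: Tensor) -> Tensor:
        g1 = Tensor(g.data[:, :1], parents=(g,),
                    bwd=lambda gr: (np.concatenate([gr, np.zeros_like(gr)], axis=1),))
        g2 = Tensor(g.data[:, 1:], parents=(g,),
                    bwd=lambda gr: (np.concatenate([np.zeros_like(gr), gr], axis=1),))
        return add(mul(g1, f1), mul(g2, f2))

    def forward_both(self, X, train=False, rng=None) -> tuple[Tensor, Tensor]:
        Xc = constant(np.asarray(X, float))
        f1, f2 = self._expert_reps(X, train, rng)
        outs = []
        for k, (gate, head) in enumerate(
                [(self.gates[0], self.head_occ), (self.gates[1], self.head_risk)]):
            if self._forced_gate is not None:
                g = constant(np.broadcast_to(self._forced_gate,
                                             (f1.shape[0], 2)).copy())
            else:
                g = softmax(gate(Xc), axis=1)
            outs.append(head(self._mix(g, f1, f2)))
        return outs[0], outs[1]

    def forward(self, X, train=False, rng=None):
        # risk-objective logits (the 4-class surface of the predictor API)
        return self.forward_both(X, train, rng)[1]

    def predict_occurrence_proba(self, X) -> np.ndarray:
        z = self.forward_both(X)[0].data.ravel()
        return 1.0 / (1.0 + np.exp(-z))

    def parameters(self):
        ps = self.expert1.parameters() + self.expert2.parameters()
        ps += self.proj2.params
        for g in self.gates:
            ps += g.params
        return ps + self.head_occ.params + self.head_risk.params

    def loss(self, X, y, train=False, rng=None):
        """y is the pair (occurrence, risk); joint loss scaled by 1/batch."""
        occ, risk = y
        lo, lr_ = self.forward_both(X, train, rng)
        total = mmoe_loss(lo, lr_, occ, risk)
        return scale(total, 1.0 / len(np.asarray(risk)))


def mmoe_loss(logits_occ: Tensor, logits_risk: Tensor, y, z) -> Tensor:
    """Joint two-objective loss: sum of binary cross entropy on the
    occurrence logits and multiclass cross entropy on the risk logits
    (unweighted sums over the batch)."""
    l1 = bce_with_logits(logits_occ, np.asarray(y, float).reshape(-1, 1),
                         reduction="sum")
    l2 = cross_entropy_with_logits(logits_risk, z, reduction="sum")
    return add(l1, l2)


def build_base_dnn(config: DeepConfig, seed: int = 0) -> BaseDNN:
    return BaseDNN(config, seed)


def build_qideep(deep: DeepConfig, qi: QIConfig, seed: int = 0) -> QIDeep:
    return QIDeep(deep, qi, seed)


def build_mmoe(config: MMOEConfig, seed: int = 0) -> MMOE:
    return MMOE(config, seed)


# --------------------------------------------------------------------------
# training

@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": range(self.n_epochs),
                             "train_loss": self.train_loss,
                             "val_loss": self.val_loss})


def _stratified_val_split(labels: np.ndarray, val_fraction: float,
                          rng: np.random.Generator):
    """Per-class held-out validation indices (at least 1 per class)."""
    labels = np.asarray(labels)
    val_idx = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        n_val = min(n_val, len(idx) - 1) if len(idx) > 1 else n_val
        val_idx.append(idx[:n_val])
    val_idx = np.sort(np.concatenate(val_idx))
    train_idx = np.setdiff1d(np.arange(len(labels)), val_idx)
    return train_idx, val_idx


def train(model: _Predictor, X: np.ndarray, y, config: TrainConfig,
          strat_labels: np.ndarray | None = None):
    """Train a predictor with Adam and patience-based early stopping.

    ``y`` is a label vector, or a (occurrence, risk) pair for MMOE.  A
    stratified ``val_fraction`` slice of the rows is held out; training
    stops once the validation loss has not improved for ``patience``
    consecutive epochs and the best-validation parameters are restored.
    Returns ``(model, TrainHistory)``.
    """
    X = np.asarray(X, float)
    multi = isinstance(y, tuple)
    strat = strat_labels if strat_labels is not None else (y[1] if multi else y)
    rng = np.random.default_rng(config.seed)
    tr_idx, va_idx = _stratified_val_split(np.asarray(strat), config.val_fraction, rng)

    def take(idx):
        if multi:
            return X[idx], (np.asarray(y[0])[idx], np.asarray(y[1])[idx])
        return X[idx], np.asarray(y)[idx]

    Xtr, ytr = take(tr_idx)
    Xva, yva = take(va_idx)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    hist = TrainHistory()
    best_val, best_state, bad = np.inf, model.get_state(), 0
    n = len(Xtr)
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        ep_losses = []
        for start in range(0, n, config.batch_size):
            bidx = perm[start:start + config.batch_size]
            Xb, yb = take(tr_idx[bidx])
            loss = model.loss(Xb, yb, train=True, rng=rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}")
            ad.backward(loss)
            opt.step()
            ep_losses.append(float(loss.data))
        val = float(model.loss(Xva, yva, train=False).data)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        hist.train_loss.append(float(np.mean(ep_losses)))
        hist.val_loss.append(val)
        if val < best_val:
            best_val, best_state, bad = val, model.get_state(), 0
            hist.best_epoch = epoch
        else:
            bad += 1
            if bad > config.patience:
                break
    hist.stopped_epoch = len(hist.train_loss) - 1
    model.set_state(best_state)
    return model, hist
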