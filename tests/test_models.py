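"""Architectures, the quadratic-interaction identity, and training."""

import numpy as np
import pytest

from qideep.models import (MMOE, BaseDNN, DeepConfig, MMOEConfig, QIConfig,
                           QIDeep, TrainConfig, build_base_dnn, build_mmoe,
                           build_qideep, mmoe_loss, qi_forward, train)
from qideep._autodiff import Tensor, backward, constant


def brute_force_qi(x, V):
    n = len(x)
    return sum(float(V[i] @ V[j]) * x[i] * x[j]
               for i in range(n) for j in range(i + 1, n))


class TestQIForward:
    def test_degenerate_cases(self):
        assert qi_forward([1.0], np.zeros((1, 4))) == 0.0
        assert qi_forward([1.0, 2.0], np.zeros((2, 3))) == 0.0

    def test_hand_case(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        x = np.array([1.0, 2.0, 3.0])
        assert qi_forward(x, V) == pytest.approx(brute_force_qi(x, V))

    def test_reformulation_matches_pairwise_double_sum(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            k = int(rng.integers(1, 7))
            V = rng.normal(size=(n, k))
            x = rng.normal(size=n)
            brute = brute_force_qi(x, V)
            assert qi_forward(x, V) == pytest.approx(brute, rel=1e-6, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qi_forward([1.0, 2.0], np.zeros((3, 2)))


class TestBaseDNN:
    def test_parameter_count_34_17_4(self):
        m = build_base_dnn(DeepConfig(34, (17,), 0.2, 4), seed=0)
        assert m.n_params == 34 * 17 + 17 + 17 * 4 + 4 == 667

    def test_inference_is_deterministic_despite_dropout(self):
        m = build_base_dnn(DeepConfig(5, (17,), 0.5, 4), seed=0)
        X = np.random.default_rng(0).normal(size=(6, 5))
        assert np.array_equal(m.predict_logits(X), m.predict_logits(X))

    def test_probabilities_normalized(self):
        m = build_base_dnn(DeepConfig(5, (17,), 0.2, 4), seed=1)
        X = np.random.default_rng(1).normal(size=(8, 5))
        p = m.predict_proba(X)
        assert (p >= 0).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestQIDeep:
    def test_embedding_parameter_count(self):
        # 3 pairs spanning 7 distinct features, k=4 -> 28 embedding entries
        qi = QIConfig(pairs=((0, 1), (2, 3), (4, 6)), latent_dim=4)
        qi2 = QIConfig(pairs=((0, 1), (2, 3), (4, 5), (5, 6)), latent_dim=4)
        m = build_qideep(DeepConfig(7, (17,), 0.2, 4), qi2, seed=0)
        assert m.n_qi_params == 7 * 4 == 28
        assert len(qi.qi_feature_indices) == 6

    def test_empty_pairs_degenerates_to_zero_qi_output(self):
        m = build_qideep(DeepConfig(6, (17,), 0.2, 4), QIConfig(pairs=()), seed=0)
        X = np.random.default_rng(2).normal(size=(5, 6))
        body = m.body(X)
        assert (body.data[:, -1] == 0).all()
        assert m.predict_logits(X).shape == (5, 4)

    def test_logits_exposed_unnormalized(self):
        qi = QIConfig(pairs=((0, 1),), latent_dim=2)
        m = build_qideep(DeepConfig(4, (17,), 0.2, 4), qi, seed=3)
        X = np.random.default_rng(3).normal(size=(5, 4))
        z = m.predict_logits(X)
        assert not np.allclose(z.sum(axis=1), 1.0)
        assert np.allclose(m.predict_proba(X).sum(axis=1), 1.0, atol=1e-6)

    def test_qi_gradient_matches_finite_difference(self):
        qi = QIConfig(pairs=((0, 1), (1, 2)), latent_dim=3)
        m = build_qideep(DeepConfig(4, (5,), 0.0, 4), qi, seed=4)
        X = np.random.default_rng(4).normal(size=(7, 4))
        y = np.random.default_rng(5).integers(0, 4, size=7)
        loss = m.loss(X, y)
        backward(loss)
        g = m.V.grad.copy()
        eps = 1e-6
        for (i, l) in [(0, 0), (1, 2), (2, 1)]:
            m.V.data[i, l] += eps
            up = float(m.loss(X, y).data)
            m.V.data[i, l] -= 2 * eps
            dn = float(m.loss(X, y).data)
            m.V.data[i, l] += eps
            assert (up - dn) / (2 * eps) == pytest.approx(g[i, l], rel=1e-4, abs=1e-7)

    def test_rejects_self_and_duplicate_pairs(self):
        with pytest.raises(ValueError):
            QIConfig(pairs=((1, 1),))
        with pytest.raises(ValueError):
            QIConfig(pairs=((0, 1), (1, 0)))


class TestMMOE:
    def _model(self, seed=0):
        qi = QIConfig(pairs=((0, 1), (2, 3)), latent_dim=4)
        return build_mmoe(MMOEConfig(input_dim=8, qi=qi), seed=seed)

    def test_two_gates_normalized(self):
        m = self._model()
        X = np.random.default_rng(6).normal(size=(10, 8))
        gates = m.gate_weights(X)
        assert len(gates) == 2
        for g in gates:
            assert (g >= 0).all()
            assert np.allclose(g.sum(axis=1), 1.0, atol=1e-6)

    def test_forced_gate_selects_single_expert(self):
        m = self._model()
        X = np.random.default_rng(7).normal(size=(4, 8))
        m._forced_gate = np.array([1.0, 0.0])
        occ1, risk1 = m.forward_both(X)
        # reproduce expert-1-only path by hand
        f1 = m.expert1.hidden(X)
        occ_hand = f1.data @ m.head_occ.W.data + m.head_occ.b.data
        risk_hand = f1.data @ m.head_risk.W.data + m.head_risk.b.data
        assert np.allclose(occ1.data, occ_hand)
        assert np.allclose(risk1.data, risk_hand)
        m._forced_gate = None

    def test_occurrence_head_is_single_logit(self):
        m = self._model()
        X = np.random.default_rng(8).normal(size=(3, 8))
        occ, risk = m.forward_both(X)
        assert occ.data.shape == (3, 1) and risk.data.shape == (3, 4)
        p = m.predict_occurrence_proba(X)
        assert ((p > 0) & (p < 1)).all()


class TestMMOELoss:
    def test_zero_logit_bce_is_ln2_per_sample(self):
        lo = constant(np.zeros((3, 1)))
        lr = constant(np.log(np.eye(4)[[0, 1, 2]] * 1e9 + 1e-12))
        y = np.ones(3)
        z = np.array([0, 1, 2])
        total = mmoe_loss(lo, lr, y, z)
        assert float(total.data) == pytest.approx(3 * np.log(2), abs=1e-6)

    def test_hand_computed_batch(self):
        lo = constant(np.array([[0.5], [-1.0]]))
        lr = constant(np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 2.0, 0.0, 0.0]]))
        y, z = np.array([1, 0]), np.array([0, 1])
        bce = (np.log1p(np.exp(-0.5))) + (np.log1p(np.exp(-1.0)))
        ce = -np.log(np.exp(1) / (np.exp(1) + 3)) - np.log(np.exp(2) / (np.exp(2) + 3))
        assert float(mmoe_loss(lo, lr, y, z).data) == pytest.approx(bce + ce, abs=1e-9)

    def test_confident_correct_predictions_vanish(self):
        lo = constant(np.full((2, 1), 50.0))
        lr = constant(np.array([[50.0, 0, 0, 0], [0, 50.0, 0, 0]]))
        total = mmoe_loss(lo, lr, np.array([1, 1]), np.array([0, 1]))
        assert float(total.data) < 1e-8

    def test_labels_out_of_range_rejected(self):
        lo = constant(np.zeros((1, 1)))
        lr = constant(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            mmoe_loss(lo, lr, np.array([2]), np.array([0]))
        with pytest.raises(ValueError):
            mmoe_loss(lo, lr, np.array([1]), np.array([7]))


class TestTraining:
    def _toy(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, 2))
        y = (X[:, 0] > 0).astype(int) * 2 + (X[:, 1] > 0).astype(int)
        return X, y

    def test_quadrant_toy_is_learnable(self):
        X, y = self._toy()
        m = build_base_dnn(DeepConfig(2, (17,), 0.2, 4), seed=0)
        m, _ = train(m, X, y, TrainConfig(max_epochs=200, patience=20,
                                          batch_size=128, seed=0))
        assert (m.predict(X) == y).mean() > 0.95

    def test_training_is_deterministic(self):
        X, y = self._toy(n=150, seed=1)
        runs = []
        for _ in range(2):
            m = build_base_dnn(DeepConfig(2, (8,), 0.2, 4), seed=5)
            m, _ = train(m, X, y, TrainConfig(max_epochs=15, patience=5, seed=5))
            runs.append(m.get_state())
        for a, b in zip(*runs):
            assert np.array_equal(a, b)

    def test_early_stop_restores_best_validation_loss(self):
        X, y = self._toy(n=300, seed=2)
        m = build_base_dnn(DeepConfig(2, (8,), 0.2, 4), seed=2)
        m, hist = train(m, X, y, TrainConfig(max_epochs=60, patience=5, seed=2))
        assert hist.best_epoch == int(np.argmin(hist.val_loss))
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_zero_patience_stops_at_first_non_improvement(self):
        X, y = self._toy(n=200, seed=3)
        m = build_base_dnn(DeepConfig(2, (8,), 0.2, 4), seed=3)
        m, hist = train(m, X, y, TrainConfig(max_epochs=100, patience=0, seed=3))
        vl = hist.val_loss
        first_bad = next((i for i in range(1, len(vl))
                          if vl[i] >= min(vl[:i])), None)
        if first_bad is not None:
            assert hist.stopped_epoch == first_bad
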