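"""Shapley axioms, estimator convergence, interaction screening and the
plot-data exports."""

import numpy as np
import pytest

from qideep.explain import (AttributionSet, attribute_rows, dependence_data,
                            dependency_values, exact_shapley, force_data,
                            importance, interactions, sampled_shapley,
                            select_order2)


def product_plus_linear(X):
    return (X[:, 0] * X[:, 1] + X[:, 2]).reshape(-1, 1)


class TestExactShapley:
    def test_linear_model_closed_form(self):
        w = np.array([2.0, -1.0, 0.5])
        f = lambda X: (X @ w).reshape(-1, 1)
        x = np.array([1.0, 2.0, 3.0])
        b = np.array([[0.5, 0.5, 0.5]])
        phi, base = exact_shapley(f, x, b)
        assert np.allclose(phi.ravel(), w * (x - 0.5))
        assert base[0] == pytest.approx(float((b @ w)[0]))

    def test_hand_enumerated_product_case(self):
        phi, base = exact_shapley(product_plus_linear, [1, 1, 1], [[0, 0, 0]])
        assert np.allclose(phi.ravel(), [0.5, 0.5, 1.0])
        assert base[0] == 0.0

    def test_dummy_feature_gets_zero(self):
        f = lambda X: (3 * X[:, 0]).reshape(-1, 1)
        phi, _ = exact_shapley(f, [1.0, 7.0], np.random.default_rng(0).normal(size=(5, 2)))
        assert phi[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_of_interchangeable_features(self):
        f = lambda X: (X[:, 0] + X[:, 1] + X[:, 0] * X[:, 1]).reshape(-1, 1)
        phi, _ = exact_shapley(f, [2.0, 2.0], [[0.0, 0.0]])
        assert phi[0, 0] == pytest.approx(phi[1, 0])

    def test_efficiency_exact_on_random_model(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(4, 3))
        f = lambda X: np.tanh(X @ W)
        x = rng.normal(size=4)
        B = rng.normal(size=(6, 4))
        phi, base = exact_shapley(f, x, B)
        assert np.allclose(base + phi.sum(axis=0), f(x[None, :])[0], atol=1e-12)

    def test_too_many_features_refused(self):
        f = lambda X: X.sum(axis=1, keepdims=True)
        with pytest.raises(ValueError):
            exact_shapley(f, np.zeros(13), np.zeros((2, 13)))


class TestSampledShapley:
    # fixed 5-feature toy: one interaction plus linear terms
    @staticmethod
    def toy(X):
        return (X[:, 0] * X[:, 1] + X[:, 2] - 2 * X[:, 3] + 0.5 * X[:, 4]).reshape(-1, 1)

    @pytest.fixture(scope="class")
    @staticmethod
    def setting():
        rng = np.random.default_rng(42)
        return rng.normal(size=5), rng.normal(size=(10, 5))

    def test_converges_to_exact_oracle(self, setting):
        x, B = setting
        pe, _ = exact_shapley(self.toy, x, B)
        ps, _ = sampled_shapley(self.toy, x, B, n_permutations=2000, seed=0)
        assert np.abs(pe - ps).mean() < 0.01

    def test_error_decreases_with_permutations(self, setting):
        x, B = setting
        pe, _ = exact_shapley(self.toy, x, B)
        errs = []
        for nperm in (10, 50, 200):
            e = [np.abs(pe - sampled_shapley(self.toy, x, B, nperm, seed=s)[0]).mean()
                 for s in range(20)]
            errs.append(np.mean(e))
        assert errs[0] > errs[1] > errs[2]

    def test_efficiency_enforced_and_deterministic(self, setting):
        x, B = setting
        p1, base = sampled_shapley(self.toy, x, B, n_permutations=7, seed=3)
        p2, _ = sampled_shapley(self.toy, x, B, n_permutations=7, seed=3)
        assert np.array_equal(p1, p2)
        fx = self.toy(x[None, :])[0]
        assert np.abs(base + p1.sum(axis=0) - fx).max() < 1e-9


class TestInteractions:
    def test_additive_model_has_zero_interactions(self):
        f = lambda X: (2 * X[:, 0] + 3 * X[:, 1] - X[:, 2]).reshape(-1, 1)
        I = interactions(f, np.array([[1.0, 2.0, 3.0]]), [0, 1, 2],
                         np.zeros((2, 3)))
        off = I.copy()
        for j in range(3):
            off[j, j] = 0
        assert np.abs(off).max() < 1e-6

    def test_product_pair_dominates(self):
        f = lambda X: (X[:, 0] * X[:, 1] + 0.1 * X[:, 2]).reshape(-1, 1)
        I = interactions(f, np.array([[1.0, 1.0, 1.0]]), [0, 1, 2],
                         np.zeros((1, 3)))
        s = np.abs(I).sum(axis=2)
        assert s[0, 1] > 0
        assert s[0, 1] == max(s[0, 1], s[0, 2], s[1, 2])

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(4, 2))
        f = lambda X: np.tanh(X @ W) + (X[:, 0] * X[:, 3]).reshape(-1, 1)
        I = interactions(f, rng.normal(size=(3, 4)), [0, 1, 2, 3],
                         rng.normal(size=(5, 4)))
        assert np.allclose(I, np.transpose(I, (1, 0, 2)))
        for j in range(4):
            assert np.allclose(I[j, j], 0)


def _linear_attrs(n=6, d=3, C=2, seed=0):
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(d, C))
    f = lambda X: X @ W
    X = rng.normal(size=(n, d))
    B = rng.normal(size=(8, d))
    return attribute_rows(f, X, B, [f"f{j}" for j in range(d)],
                          n_permutations=30, seed=1)


class TestImportanceAndSelection:
    def test_all_zero_attributions(self):
        attrs = AttributionSet(y_base=np.zeros(2), phi=np.zeros((3, 2, 2)),
                               model_output=np.zeros((3, 2)),
                               feature_names=["b", "a"], X=np.zeros((3, 2)))
        imp = importance(attrs)
        assert (imp.overall == 0).all()
        assert imp.order == ["a", "b"]   # lexicographic under ties

    def test_single_sample_absolute_values(self):
        phi = np.zeros((1, 2, 1))
        phi[0, :, 0] = [-2.0, 1.0]
        attrs = AttributionSet(y_base=np.zeros(1), phi=phi,
                               model_output=np.zeros((1, 1)),
                               feature_names=["x", "y"], X=np.zeros((1, 2)))
        imp = importance(attrs)
        assert imp.per_class.loc["x", 0] == 2.0
        assert imp.per_class.loc["y", 0] == 1.0
        assert imp.order == ["x", "y"]

    def test_dominant_main_effect_ranks_first_across_seeds(self, schema):
        """On data with one overwhelming main effect the attribution
        ranking should put that feature first in at least 9/10 seeds."""
        from sklearn.linear_model import LogisticRegression
        from qideep.synthetic import GeneratorSpec, generate
        from qideep import tabular as tab
        wins = 0
        for seed in range(10):
            spec = GeneratorSpec(n_samples=300, seed=seed, noise_scale=0.2,
                                 main_effects={"LSBP": 3.0, "Exs": 0.3,
                                               "TC": 0.2})
            ds = tab.encode(tab.clean(generate(spec, schema), schema), schema)
            clf = LogisticRegression(max_iter=300).fit(ds.Xnum, ds.risk)
            rng = np.random.default_rng(seed)
            rows = ds.Xnum[rng.choice(len(ds.Xnum), 15, replace=False)]
            bg = ds.Xnum[rng.choice(len(ds.Xnum), 25, replace=False)]
            attrs = attribute_rows(clf.decision_function, rows, bg,
                                   ds.feature_names, n_permutations=10,
                                   seed=seed)
            wins += importance(attrs).order[0] == "LSBP"
        assert wins >= 9

    def test_select_all_pairs_ranked(self):
        I = np.zeros((3, 3, 1))
        I[0, 1] = I[1, 0] = 0.5
        I[0, 2] = I[2, 0] = 2.0
        I[1, 2] = I[2, 1] = 1.0
        sel = select_order2(None, I, ["a", "b", "c"], 3)
        assert sel == [("a", "c"), ("b", "c"), ("a", "b")]

    def test_tie_break_lexicographic(self):
        I = np.full((3, 3, 1), 1.0)
        sel = select_order2(None, I, ["c", "a", "b"], 3)
        assert sel == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError):
            select_order2(None, np.zeros((2, 2, 1)), ["a", "b"], 2)

    def test_dependency_values_in_unit_interval(self):
        attrs = _linear_attrs()
        dep = dependency_values(attrs, 0, ["f0", "f1", "f2"])
        assert ((dep.values >= 0) & (dep.values <= 1)).all()


class TestPlotData:
    def test_force_record_sums_to_output(self):
        attrs = _linear_attrs()
        for i in range(attrs.phi.shape[0]):
            for c in range(attrs.phi.shape[2]):
                rec = force_data(attrs, i, c)
                assert rec.check_sum(1e-6)
                mags = [abs(p) for _, _, p in rec.contributions]
                assert mags == sorted(mags, reverse=True)

    def test_dependence_table_one_row_per_sample(self):
        attrs = _linear_attrs(n=9)
        dep = dependence_data(attrs, "f0", "f2", class_id=1)
        assert len(dep) == 9
        assert list(dep.columns) == ["value", "phi", "color_value"]

    def test_unknown_feature_rejected(self):
        attrs = _linear_attrs()
        with pytest.raises(KeyError):
            dependence_data(attrs, "nope", "f0", 0)

    def test_planted_positive_effect_has_positive_attribution(self):
        # model with an explicitly positive smoking coefficient: a smoker row
        # must receive a positive contribution for the elevated-risk output
        w = np.array([1.5, 0.2])
        f = lambda X: (X @ w).reshape(-1, 1)
        X = np.array([[2.0, 0.0]])           # Sm = 2 (current smoker)
        B = np.zeros((4, 2))
        attrs = attribute_rows(f, X, B, ["Sm", "other"], n_permutations=20,
                               seed=0)
        rec = force_data(attrs, 0, 0)
        sm = dict((n, p) for n, _, p in rec.contributions)
        assert sm["Sm"] > 0
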