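"""Shapley additive attributions, interaction screening and plot data.

A prediction ``y_i`` is decomposed as ``y_i = y_base + sum_j phi_ij`` where
``y_base`` is the mean model output over a background sample and ``phi_ij``
is feature j's Shapley value — its average marginal contribution over all
coalitions (efficiency, symmetry, dummy and additivity hold).  Attributions
are computed on logits (pre-softmax), one explainer per risk state.

Two estimators are provided: an exact coalition enumerator (the canonical
oracle, feasible for at most 12 features) and a permutation-sampling
estimator for the full 34-feature table.  Pairwise Shapley interaction
indices over a small candidate pool drive the selection of order-2
features for the QI layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["AttributionSet", "ImportanceRanking", "ForceRecord",
           "exact_shapley", "sampled_shapley", "attribute_rows",
           "importance", "interactions", "dependency_values",
           "select_order2", "force_data", "dependence_data"]

MAX_EXACT_FEATURES = 12


# --------------------------------------------------------------------------
# containers

@dataclass
class AttributionSet:
    """Per-sample, per-feature, per-class attributions.

    ``phi`` has shape (n_samples, n_features, n_classes); ``y_base`` is the
    per-class baseline (mean model output over the background) and
    ``model_output`` the per-sample outputs, so that for every sample and
    class ``y_base[c] + phi[i, :, c].sum() == model_output[i, c]`` up to
    the estimator's tolerance.
    """

    y_base: np.ndarray
    phi: np.ndarray
    model_output: np.ndarray
    feature_names: list[str]
    X: np.ndarray = None     # raw encoded rows the attributions refer to

    def efficiency_gap(self) -> np.ndarray:
        return self.model_output - (self.y_base[None, :] + self.phi.sum(axis=1))

    def to_long_frame(self) -> pd.DataFrame:
        n, d, C = self.phi.shape
        rows = []
        for i in range(n):
            for j in range(d):
                for c in range(C):
                    rows.append((i, self.feature_names[j], c, self.phi[i, j, c]))
        return pd.DataFrame(rows, columns=["sample", "feature", "class", "value"])


@dataclass
class ImportanceRanking:
    """Mean |phi| per feature: one column per class plus the overall mean
    (average of the per-class importances); ``order`` sorts descending with
    lexicographic tie-break."""

    per_class: pd.DataFrame      # index features, columns class ids
    overall: pd.Series
    order: list[str]

    def top(self, k: int) -> list[str]:
        return self.order[:k]


@dataclass
class ForceRecord:
    """Single-prediction explanation: signed contributions pushing the
    output away from the base value, sorted by |contribution| descending."""

    sample: int
    class_id: int
    y_base: float
    model_output: float
    contributions: list[tuple[str, float, float]]   # (feature, raw value, phi)

    def check_sum(self, tol: float = 1e-6) -> bool:
        s = sum(c for _, _, c in self.contributions)
        return abs(self.y_base + s - self.model_output) <= tol

    def to_json(self) -> str:
        return json.dumps({
            "sample": self.sample, "class": self.class_id,
            "y_base": self.y_base, "model_output": self.model_output,
            "contributions": [
                {"feature": f, "value": v, "phi": p}
                for f, v, p in self.contributions],
        })


# --------------------------------------------------------------------------
# exact enumeration

def _coalition_values(model_fn, x, background, features):
    """v(S) for every coalition S of `features`: model output with features
    in S taken from x and the rest averaged over the background.  Features
    outside `features` are held at x's values."""
    x = np.asarray(x, float).ravel()
    B = np.atleast_2d(np.asarray(background, float))
    m = len(features)
    base = np.tile(x, (B.shape[0], 1))
    base[:, features] = B[:, features]        # coalition members overwritten below
    values = {}
    for mask in range(1 << m):
        rows = base.copy()
        for b, j in enumerate(features):
            if mask >> b & 1:
                rows[:, j] = x[j]
        out = np.atleast_2d(model_fn(rows))
        values[mask] = out.mean(axis=0)
    return values


def exact_shapley(model_fn, x, background, features=None):
    """Exact Shapley values by coalition enumeration.

    Parameters
    ----------
    model_fn : callable
        Maps an (m, d) array to (m, C) outputs (logits).
    x : (d,) array — the row to explain.
    background : (b, d) array — reference sample defining "absent" features.
    features : sequence of int, optional
        Subset of columns to attribute over (default: all; at most 12).

    Returns
    -------
    phi : (len(features), C) array, y_base : (C,) array
        ``y_base`` is v(empty set); efficiency holds exactly:
        ``y_base + phi.sum(0) == model_fn(x)``.
    """
    x = np.asarray(x, float).ravel()
    if features is None:
        features = list(range(x.size))
    features = list(features)
    m = len(features)
    if m > MAX_EXACT_FEATURES:
        raise ValueError(f"exact enumeration limited to {MAX_EXACT_FEATURES} features")
    v = _coalition_values(model_fn, x, background, features)
    C = v[0].size
    phi = np.zeros((m, C))
    fact = [factorial(i) for i in range(m + 1)]
    for b in range(m):
        for mask in range(1 << m):
            if mask >> b & 1:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[m - s - 1] / fact[m]
            phi[b] += w * (v[mask | (1 << b)] - v[mask])
    return phi, v[0]


def interactions(model_fn, rows, candidates, background, feature_names=None):
    """Pairwise Shapley interaction indices over a candidate pool.

    For each pair (j, k) the interaction index is the coalition-weighted
    average of the second difference
    ``v(S+jk) - v(S+j) - v(S+k) + v(S)``, averaged over ``rows``.  Returns
    a (p, p, C) array, symmetric in the first two axes with zero diagonal.
    """
    candidates = list(candidates)
    p = len(candidates)
    if p > MAX_EXACT_FEATURES:
        raise ValueError(f"interaction screening limited to {MAX_EXACT_FEATURES} candidates")
    rows = np.atleast_2d(np.asarray(rows, float))
    fact = [factorial(i) for i in range(p + 1)]
    total = None
    for x in rows:
        v = _coalition_values(model_fn, x, background, candidates)
        C = v[0].size
        I = np.zeros((p, p, C))
        for a, b in combinations(range(p), 2):
            bit_a, bit_b = 1 << a, 1 << b
            acc = np.zeros(C)
            for mask in range(1 << p):
                if mask & (bit_a | bit_b):
                    continue
                s = bin(mask).count("1")
                # Shapley interaction weight over coalitions excluding {a, b}
                w = fact[s] * fact[p - s - 2] / (2 * fact[p - 1])
                acc += w * (v[mask | bit_a | bit_b] - v[mask | bit_a]
                            - v[mask | bit_b] + v[mask])
            I[a, b] = I[b, a] = acc
        total = I if total is None else total + I
    return total / len(rows)


# --------------------------------------------------------------------------
# permutation sampling

def sampled_shapley(model_fn, x, background, n_permutations=100, seed=0):
    """Permutation-sampling Shapley estimate for all features of ``x``.

    Each sampled permutation contributes the telescoping marginal gains of
    adding features one at a time, an unbiased estimate of the exact value.
    Any residual between the additive reconstruction and the model output
    is redistributed proportionally to |phi| so efficiency holds to 1e-9.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, float).ravel()
    B = np.atleast_2d(np.asarray(background, float))
    d = x.size
    rng = np.random.default_rng(seed)
    fx = np.atleast_2d(model_fn(x[None, :])).mean(axis=0)
    y_base = np.atleast_2d(model_fn(B)).mean(axis=0)
    C = fx.size
    phi = np.zeros((d, C))
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        rows = B.copy()
        prev = y_base
        for j in perm:
            rows[:, j] = x[j]
            cur = np.atleast_2d(model_fn(rows)).mean(axis=0)
            phi[j] += cur - prev
            prev = cur
    phi /= n_permutations
    # enforce the additive identity exactly
    residual = fx - y_base - phi.sum(axis=0)
    absphi = np.abs(phi)
    col = absphi.sum(axis=0)
    for c in range(C):
        if col[c] > 0:
            phi[:, c] += residual[c] * absphi[:, c] / col[c]
        else:
            phi[:, c] += residual[c] / d
    return phi, y_base


def attribute_rows(model_fn, X, background, feature_names,
                   n_permutations=100, seed=0) -> AttributionSet:
    """Sampled Shapley attributions for every row of ``X``."""
    X = np.atleast_2d(np.asarray(X, float))
    outs = np.atleast_2d(model_fn(X))
    phis = []
    for i, x in enumerate(X):
        phi, y_base = sampled_shapley(model_fn, x, background,
                                      n_permutations, seed + i)
        phis.append(phi)
    return AttributionSet(y_base=y_base, phi=np.stack(phis),
                          model_output=outs, feature_names=list(feature_names),
                          X=X)


# --------------------------------------------------------------------------
# rankings and selection

def importance(attrs: AttributionSet) -> ImportanceRanking:
    """Mean absolute attribution per feature, per class and overall."""
    if attrs.phi.size == 0:
        raise ValueError("empty attribution set")
    per_class = np.abs(attrs.phi).mean(axis=0)          # (d, C)
    df = pd.DataFrame(per_class, index=attrs.feature_names,
                      columns=list(range(per_class.shape[1])))
    overall = df.mean(axis=1)
    order = sorted(attrs.feature_names,
                   key=lambda n: (-overall[n], n))
    return ImportanceRanking(per_class=df, overall=overall, order=order)


def dependency_values(attrs: AttributionSet, class_id: int,
                      candidates: list[str]) -> pd.DataFrame:
    """Dependence-plot spread: fraction of variance of phi_j (for the given
    class) explained by a linear fit on a partner feature's raw value."""
    idx = {n: attrs.feature_names.index(n) for n in candidates}
    out = pd.DataFrame(0.0, index=candidates, columns=candidates)
    for a in candidates:
        pa = attrs.phi[:, idx[a], class_id]
        va = np.var(pa)
        for b in candidates:
            if a == b or va == 0:
                continue
            xb = attrs.X[:, idx[b]]
            if np.var(xb) == 0:
                continue
            r = np.corrcoef(pa, xb)[0, 1]
            out.loc[a, b] = float(r ** 2) if np.isfinite(r) else 0.0
    return out


def select_order2(imp: ImportanceRanking, inter: np.ndarray,
                  candidates: list[str], n_pairs: int) -> list[tuple[str, str]]:
    """Pick the top order-2 feature pairs for the QI layer.

    Pairs of the candidate pool are ranked by interaction strength — the
    absolute Shapley interaction index summed over the four states — with a
    lexicographic tie-break on the pair name.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    p = len(candidates)
    n_avail = p * (p - 1) // 2
    if n_pairs > n_avail:
        raise ValueError(f"n_pairs={n_pairs} exceeds available pairs ({n_avail})")
    strength = np.abs(inter).sum(axis=2) if inter.ndim == 3 else np.abs(inter)
    scored = []
    for a, b in combinations(range(p), 2):
        pair = tuple(sorted((candidates[a], candidates[b])))
        scored.append((pair, float(strength[a, b])))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [pair for pair, _ in scored[:n_pairs]]


# --------------------------------------------------------------------------
# plot data

def force_data(attrs: AttributionSet, sample: int, class_id: int) -> ForceRecord:
    """Force-plot data for one sample and one risk state."""
    if not 0 <= sample < attrs.phi.shape[0]:
        raise IndexError("sample out of range")
    if not 0 <= class_id < attrs.phi.shape[2]:
        raise IndexError("class out of range")
    phi = attrs.phi[sample, :, class_id]
    vals = attrs.X[sample] if attrs.X is not None else np.full(phi.size, np.nan)
    order = sorted(range(phi.size),
                   key=lambda j: (-abs(phi[j]), attrs.feature_names[j]))
    contribs = [(attrs.feature_names[j], float(vals[j]), float(phi[j]))
                for j in order]
    return ForceRecord(sample=sample, class_id=class_id,
                       y_base=float(attrs.y_base[class_id]),
                       model_output=float(attrs.model_output[sample, class_id]),
                       contributions=contribs)


def dependence_data(attrs: AttributionSet, feature: str, color_feature: str,
                    class_id: int) -> pd.DataFrame:
    """Dependence-plot data: per sample the feature's raw value, its
    attribution for the chosen state, and the colouring feature's value."""
    for f in (feature, color_feature):
        if f not in attrs.feature_names:
            raise KeyError(f"unknown feature {f!r}")
    j = attrs.feature_names.index(feature)
    k = attrs.feature_names.index(color_feature)
    return pd.DataFrame({
        "value": attrs.X[:, j],
        "phi": attrs.phi[:, j, class_id],
        "color_value": attrs.X[:, k],
    })
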