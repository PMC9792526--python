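"""Synthetic stroke-screening tables with known ground truth.

The real registry behind the four-state risk labels is not public, so this
module generates structurally faithful stand-ins: 34 features drawn
according to the schema codings, a latent risk score with configurable main
effects and planted pairwise (order-2) effects, four risk labels assigned
by the score's empirical quantiles (so class imbalance is controlled
exactly), and a binary stroke-occurrence label that is the indicator of the
attack state.

The default class proportions mirror the study's cleaned counts
7221:5868:5475:1967 (attack:non-attack roughly 1:10).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .schema import FeatureSchema, default_schema, schema_by_name

__all__ = ["GeneratorSpec", "LabeledTable", "generate", "planted_pairs",
           "DEFAULT_CLASS_COUNTS"]

#: cleaned per-state sample counts of the source registry (low:medium:high:attack)
DEFAULT_CLASS_COUNTS = (7221, 5868, 5475, 1967)
_TOTAL = sum(DEFAULT_CLASS_COUNTS)


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic table.

    ``main_effects`` maps feature name -> coefficient and ``pair_effects``
    maps (name, name) -> coefficient; both act on per-column standardized
    values so coefficients are comparable across features.  ``noise_scale``
    is the standard deviation of the additive Gaussian noise on the latent
    score.
    """

    n_samples: int = _TOTAL
    class_proportions: tuple[float, float, float, float] = tuple(
        c / _TOTAL for c in DEFAULT_CLASS_COUNTS)
    main_effects: dict = field(default_factory=dict)
    pair_effects: dict = field(default_factory=dict)
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self, schema: list[FeatureSchema]) -> None:
        names = {f.name for f in schema}
        if self.n_samples < 20:
            raise ValueError("n_samples < 20: quantile label assignment degenerate")
        if len(self.class_proportions) != 4 or any(p < 0 for p in self.class_proportions):
            raise ValueError("class_proportions must be 4 nonnegative reals")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        unknown = set(self.main_effects) - names
        if unknown:
            raise ValueError(f"main_effects on unknown features: {sorted(unknown)}")
        for a, b in self.pair_effects:
            if a == b:
                raise ValueError(f"pair effect on identical feature {a!r}")
            if a not in names or b not in names:
                raise ValueError(f"pair effect on unknown feature in ({a}, {b})")


@dataclass
class LabeledTable:
    """A feature table with the four-level risk label and the binary
    occurrence label (occurrence == 1 iff risk == 3, the attack state)."""

    X: pd.DataFrame
    risk: np.ndarray
    occurrence: np.ndarray

    def __post_init__(self):
        self.risk = np.asarray(self.risk, dtype=int)
        self.occurrence = np.asarray(self.occurrence, dtype=int)
        if not (len(self.X) == len(self.risk) == len(self.occurrence)):
            raise ValueError("X, risk and occurrence must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out["risk"] = self.risk
        out["occurrence"] = self.occurrence
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledTable":
        df = pd.read_csv(path)
        risk = df.pop("risk").to_numpy()
        occ = df.pop("occurrence").to_numpy()
        return cls(df, risk, occ)


def _exact_class_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder apportionment: integer counts summing to n, each
    within 1 of n * proportion."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _draw_features(schema, n, rng) -> pd.DataFrame:
    cols = {}
    for f in schema:
        if f.kind == "continuous":
            lo, hi = f.range
            mu, sd = (lo + hi) / 2.0, (hi - lo) / 6.0
            a, b = (lo - mu) / sd, (hi - mu) / sd
            cols[f.name] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n,
                                         random_state=rng)
        else:
            cols[f.name] = rng.choice(f.codes, size=n).astype(float)
    df = pd.DataFrame(cols, columns=[f.name for f in schema])
    # years of smoking is defined only for (ex-)smokers
    if "Ys" in df.columns and "Sm" in df.columns:
        ys_lo, ys_hi = schema_by_name(schema)["Ys"].range
        smoker = df["Sm"].to_numpy() > 0
        ys = np.zeros(n)
        ys[smoker] = rng.uniform(ys_lo, ys_hi, size=int(smoker.sum()))
        df["Ys"] = ys
    return df


def _standardized(df: pd.DataFrame) -> pd.DataFrame:
    z = df - df.mean(axis=0)
    sd = df.std(axis=0, ddof=0).replace(0.0, 1.0)
    return z / sd


def latent_score(df: pd.DataFrame, spec: GeneratorSpec, rng=None) -> np.ndarray:
    """Latent risk score: main effects + planted order-2 effects (+ noise)."""
    z = _standardized(df)
    score = np.zeros(len(df))
    for name, beta in spec.main_effects.items():
        score += beta * z[name].to_numpy()
    for (a, b), gamma in spec.pair_effects.items():
        score += gamma * z[a].to_numpy() * z[b].to_numpy()
    if rng is not None and spec.noise_scale > 0:
        score += spec.noise_scale * rng.standard_normal(len(df))
    return score


def generate(spec: GeneratorSpec, schema: list[FeatureSchema] | None = None) -> LabeledTable:
    """Generate a labeled table according to ``spec``.

    Risk labels are assigned by rank on the latent score: the lowest-score
    block becomes state 0 (low) and the top block state 3 (attack), with
    block sizes apportioned exactly from ``class_proportions``.  The
    occurrence label is the attack indicator.  Fully reproducible for a
    fixed ``spec.seed``.
    """
    schema = schema or default_schema()
    spec.validate(schema)
    rng = np.random.default_rng(spec.seed)
    df = _draw_features(schema, spec.n_samples, rng)
    score = latent_score(df, spec, rng)
    counts = _exact_class_counts(spec.n_samples, spec.class_proportions)
    order = np.argsort(score, kind="stable")
    risk = np.empty(spec.n_samples, dtype=int)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    for c in range(4):
        risk[order[bounds[c]:bounds[c + 1]]] = c
    occurrence = (risk == 3).astype(int)
    return LabeledTable(df, risk, occurrence)


def planted_pairs(spec: GeneratorSpec) -> list[tuple[str, str]]:
    """Ground-truth interacting pairs, sorted by |coefficient| descending;
    ties broken lexicographically by pair name."""
    if not spec.pair_effects:
        raise ValueError("spec has no pair_effects")
    items = [(tuple(p), abs(c)) for p, c in spec.pair_effects.items() if c != 0]
    items.sort(key=lambda t: (-t[1], t[0]))
    return [p for p, _ in items]
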