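"""Cleaning, encoding and splitting of labeled clinical tables.

Categorical features keep their integer codes as a single numeric column
(the models take one input neuron per feature); continuous features are
standardized with moments fitted on the training split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .schema import FeatureSchema, schema_by_name
from .synthetic import LabeledTable

__all__ = ["EncodedDataset", "SplitSpec", "clean", "encode", "decode",
           "split", "split_indices"]

logger = logging.getLogger(__name__)


class EmptyDatasetError(ValueError):
    """Raised when cleaning drops every row."""


@dataclass
class EncodedDataset:
    """Model-ready numeric matrix plus labels and the fitted scaler.

    ``scaler`` maps feature name -> (mean, sd) for the standardized
    (continuous) columns; categorical columns are absent from it.
    """

    Xnum: np.ndarray
    feature_names: list[str]
    risk: np.ndarray
    occurrence: np.ndarray
    scaler: dict[str, tuple[float, float]]

    def __len__(self) -> int:
        return self.Xnum.shape[0]

    def subset_rows(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(self.Xnum[idx], list(self.feature_names),
                              self.risk[idx], self.occurrence[idx], dict(self.scaler))

    def subset_features(self, names: list[str]) -> "EncodedDataset":
        cols = [self.feature_names.index(n) for n in names]
        return EncodedDataset(self.Xnum[:, cols], list(names), self.risk,
                              self.occurrence,
                              {n: v for n, v in self.scaler.items() if n in names})


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.15
    stratify: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


def clean(table: LabeledTable, schema: list[FeatureSchema]) -> LabeledTable:
    """Apply the cleaning rules and return a new table.

    - rows with a missing risk label are dropped;
    - missing years-of-smoking (Ys) is set to 0 for nonsmokers (Sm == 0);
    - other missing continuous values are imputed by the column median;
    - rows with a categorical value outside the schema codes are dropped
      (count logged).
    """
    by_name = schema_by_name(schema)
    df = table.X.copy()
    risk = pd.Series(table.risk, index=df.index, dtype="float")
    keep = risk.notna()
    df, risk = df[keep], risk[keep].astype(int)

    if "Ys" in df.columns and "Sm" in df.columns:
        nonsmoker = df["Sm"] == 0
        df.loc[nonsmoker & df["Ys"].isna(), "Ys"] = 0.0

    bad = pd.Series(False, index=df.index)
    for f in schema:
        if f.name not in df.columns:
            raise ValueError(f"table missing schema column {f.name!r}")
        col = df[f.name]
        if f.kind == "continuous":
            if col.isna().any():
                df[f.name] = col.fillna(col.median())
        else:
            bad |= col.notna() & ~col.isin(f.codes)
            bad |= col.isna()
    dropped = int(bad.sum())
    if dropped:
        logger.info("clean: dropping %d rows with out-of-code categorical values", dropped)
    df, risk = df[~bad], risk[~bad]
    if len(df) == 0:
        raise EmptyDatasetError("cleaning removed every row")
    df = df.reset_index(drop=True)[[f.name for f in schema]]
    risk = risk.reset_index(drop=True).to_numpy()
    return LabeledTable(df, risk, (risk == 3).astype(int))


def encode(table: LabeledTable, schema: list[FeatureSchema],
           fit_scaler: bool = True,
           scaler: dict[str, tuple[float, float]] | None = None) -> EncodedDataset:
    """Encode a clean table into a numeric matrix in schema column order.

    Binary/ordinal features pass through as their integer codes; continuous
    features are standardized to (x - mean) / sd.  When ``fit_scaler`` is
    False a previously fitted ``scaler`` must be supplied (test-split use).
    A zero-variance continuous column gets sd clamped to 1 (warned).
    """
    if not fit_scaler and scaler is None:
        raise ValueError("fit_scaler=False requires a fitted scaler")
    names = [f.name for f in schema]
    X = table.X[names].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("encode requires a clean table without missing values")
    fitted = {} if fit_scaler else dict(scaler)
    for j, f in enumerate(schema):
        if f.kind != "continuous":
            continue
        if fit_scaler:
            mu = float(X[:, j].mean())
            sd = float(X[:, j].std(ddof=0))
            if sd == 0.0:
                logger.warning("encode: zero-variance column %s, sd clamped to 1", f.name)
                sd = 1.0
            fitted[f.name] = (mu, sd)
        mu, sd = fitted[f.name]
        X[:, j] = (X[:, j] - mu) / sd
    return EncodedDataset(X, names, np.asarray(table.risk, int),
                          np.asarray(table.occurrence, int), fitted)


def decode(ds: EncodedDataset, schema: list[FeatureSchema]) -> LabeledTable:
    """Invert :func:`encode` given the schema and the stored scaler."""
    X = ds.Xnum.copy()
    for j, f in enumerate(schema):
        if f.kind == "continuous":
            mu, sd = ds.scaler[f.name]
            X[:, j] = X[:, j] * sd + mu
    df = pd.DataFrame(X, columns=ds.feature_names)
    return LabeledTable(df, ds.risk.copy(), ds.occurrence.copy())


def split_indices(ds: EncodedDataset, spec: SplitSpec) -> pd.DataFrame:
    """Row assignment of a split as a two-column frame (row_id, fold)."""
    if spec.stratify:
        counts = np.bincount(ds.risk, minlength=4)
        if (counts[counts > 0] < 2).any():
            raise ValueError("cannot stratify: a class has fewer than 2 members")
    idx = np.arange(len(ds))
    tr, te = train_test_split(
        idx, test_size=spec.test_fraction, random_state=spec.seed,
        stratify=ds.risk if spec.stratify else None, shuffle=True)
    fold = np.full(len(ds), "train", dtype=object)
    fold[np.sort(te)] = "test"
    return pd.DataFrame({"row_id": idx, "fold": fold})


def split(ds: EncodedDataset, spec: SplitSpec) -> tuple[EncodedDataset, EncodedDataset]:
    """Deterministic (optionally risk-stratified) train/test split."""
    folds = split_indices(ds, spec)
    tr = folds.loc[folds["fold"] == "train", "row_id"].to_numpy()
    te = folds.loc[folds["fold"] == "test", "row_id"].to_numpy()
    return ds.subset_rows(tr), ds.subset_rows(te)
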