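"""Typed containers for feature tables and binary clinical references.

A study dataset is two aligned artifacts: a real-valued feature table
(samples x features) and a binary reference vector (1 = clinically
significant outcome).  They are stored and serialized separately and joined
on ``sample_id`` so that noised copies of the reference can be first-class
objects with their own provenance.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import round_half_away


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(items, what: str) -> None:
    seen = set()
    dups = [x for x in items if x in seen or seen.add(x)]
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass(frozen=True)
class FeatureTable:
    """An n x p matrix of real-valued features with sample and feature names."""

    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {vals.shape}")
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValidationError(
                f"shape mismatch: values {vals.shape} vs "
                f"{len(self.sample_ids)} sample ids x {len(self.feature_names)} feature names"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.feature_names, "feature names")
        if not np.all(np.isfinite(vals)):
            rows, cols = np.nonzero(~np.isfinite(vals))
            cells = [
                f"(sample {self.sample_ids[r]}, feature {self.feature_names[c]})"
                for r, c in list(zip(rows, cols))[:5]
            ]
            raise ValidationError(f"non-finite values at {cells}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def p(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        ids = [str(x) for x in df.iloc[:, 0]]
        return cls(tuple(ids), tuple(str(c) for c in df.columns[1:]),
                   df.iloc[:, 1:].to_numpy(dtype=float))

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def subset_rows(self, ids) -> "FeatureTable":
        """Rows for the given sample ids, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in ids]
        return FeatureTable(tuple(ids), self.feature_names, self.values[rows])

    def select_features(self, names) -> "FeatureTable":
        """Columns for the given feature names, in the given order."""
        index = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise ValidationError(f"missing feature column: {missing[:5]}")
        cols = [index[f] for f in names]
        return FeatureTable(self.sample_ids, tuple(names), self.values[:, cols])


@dataclass(frozen=True)
class ReferenceVector:
    """Binary clinical reference labels aligned to a feature table."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray
    positive_meaning: str = "clinically significant"

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        lab = np.asarray(self.labels)
        if not np.isin(lab, [0, 1]).all():
            bad = sorted(set(np.asarray(lab).ravel().tolist()) - {0, 1})
            raise ValidationError(f"labels must be in {{0,1}}, found {bad[:5]}")
        lab = lab.astype(np.int8)
        object.__setattr__(self, "labels", lab)
        if len(lab) != len(self.sample_ids):
            raise ValidationError("labels and sample_ids have different lengths")
        _check_unique(self.sample_ids, "sample ids")
        if len(np.unique(lab)) < 2:
            raise ValidationError("single class: reference must contain both 0 and 1 labels")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.n

    def check_aligned(self, table: FeatureTable) -> None:
        if self.sample_ids != table.sample_ids:
            raise ValidationError("reference sample ids do not match the feature table")

    def subset(self, ids) -> "ReferenceVector":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in ids]
        return ReferenceVector(tuple(ids), self.labels[rows], self.positive_meaning)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": list(self.sample_ids), "label": self.labels})

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class SplitAssignment:
    """A stratified partition of the samples into training and hold-out sets."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    ratio: float
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValidationError("train and test ids overlap")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.train_ids) + list(self.test_ids),
                "partition": ["train"] * len(self.train_ids) + ["test"] * len(self.test_ids),
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_feature_table(path) -> FeatureTable:
    """Read a feature table CSV: first column sample_id, rest numeric features."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("feature CSV needs a sample_id column plus >= 1 feature column")
    ids = [str(x) for x in df.iloc[:, 0]]
    names = [str(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:]

    na = body.isna()
    if na.to_numpy().any():
        rows, cols = np.nonzero(na.to_numpy())
        cells = [f"(sample {ids[r]}, column {names[c]})" for r, c in list(zip(rows, cols))[:5]]
        raise ValidationError(f"missing values at {cells}")
    for j, col in enumerate(body.columns):
        if body[col].dtype == object:
            coerced = pd.to_numeric(body[col], errors="coerce")
            bad = int(np.nonzero(coerced.isna().to_numpy())[0][0])
            raise ValidationError(
                f"non-numeric cell {body[col].iloc[bad]!r} at (sample {ids[bad]}, column {names[j]})"
            )
    return FeatureTable(tuple(ids), tuple(names), body.to_numpy(dtype=float))


def read_reference(path, table: FeatureTable | None = None) -> ReferenceVector:
    """Read a reference CSV with columns (sample_id, label); labels in {0,1}.

    If ``table`` is supplied, the sample ids must match it exactly and in
    order.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ValidationError("reference CSV must have columns sample_id,label")
    ref = ReferenceVector(tuple(str(x) for x in df["sample_id"]), df["label"].to_numpy())
    if table is not None:
        ref.check_aligned(table)
    return ref


def stratified_split(
    table: FeatureTable, ref: ReferenceVector, ratio: float = 0.7, seed: int = 0
) -> SplitAssignment:
    """Stratified train/hold-out split at the given ratio (default 7:3).

    The overall training size is ``round(ratio * n)`` and each class
    contributes ``round(ratio * class_count)`` samples up to rounding, so
    the class prevalences of the two partitions differ from the full data
    by at most one sample's worth.  Deterministic given the seed.
    """
    ref.check_aligned(table)
    if not 0 < ratio < 1:
        raise ValidationError(f"ratio must be in (0,1), got {ratio}")
    ids = np.asarray(table.sample_ids, dtype=object)
    pos = ids[ref.labels == 1]
    neg = ids[ref.labels == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("each class needs >= 2 members to split")

    n = table.n
    n_train = round_half_away(ratio * n)
    n_train_pos = round_half_away(ratio * len(pos))
    n_train_neg = n_train - n_train_pos
    # keep the per-class count inside [1, class-1] so both partitions see both classes
    n_train_neg = min(max(n_train_neg, 1), len(neg) - 1)
    n_train_pos = min(max(n_train_pos, 1), len(pos) - 1)

    rng = np.random.default_rng(seed)
    train = set(rng.choice(pos, size=n_train_pos, replace=False))
    train |= set(rng.choice(neg, size=n_train_neg, replace=False))
    train_ids = tuple(s for s in table.sample_ids if s in train)
    test_ids = tuple(s for s in table.sample_ids if s not in train)
    return SplitAssignment(train_ids, test_ids, ratio, seed)
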