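"""The universal tabular input: a sample-by-feature matrix with binary labels.

A :class:`FeatureTable` is what every operation in the package consumes —
whether it came from the synthetic generator or from a real radiomics CSV
(rows = subjects, columns = numeric features plus one 0/1 label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]


@dataclass(frozen=True)
class FeatureTable:
    """Numeric sample x feature matrix with per-sample binary class labels.

    Invariants enforced at construction: finite values, matching shapes,
    unique names/ids, and both classes present with at least two members.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = field(default=())
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if labels.ndim != 1 or labels.shape[0] != values.shape[0]:
            raise ValueError("labels length must equal the number of rows")
        if not np.isfinite(values).all():
            raise ValueError("values contain missing or non-finite entries")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary in {0, 1}")
        for cls in (0, 1):
            if (labels == cls).sum() < 2:
                raise ValueError(f"class {cls} needs at least 2 members")
        if not self.feature_names:
            names = tuple(f"f{j}" for j in range(values.shape[1]))
            object.__setattr__(self, "feature_names", names)
        else:
            object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if not self.sample_ids:
            ids = tuple(f"s{i}" for i in range(values.shape[0]))
            object.__setattr__(self, "sample_ids", ids)
        else:
            object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(self.feature_names) != values.shape[1]:
            raise ValueError("feature_names length must equal column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if len(self.sample_ids) != values.shape[0]:
            raise ValueError("sample_ids length must equal row count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        """Row subset (keeps feature columns and names untouched)."""
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[idx],
            labels=self.labels[idx],
            feature_names=self.feature_names,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )

    # -- CSV interchange -------------------------------------------------
    # Schema: first column sample_id, last column label (0/1), intervening
    # columns numeric features; UTF-8, '.' decimal separator, header row.
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "sample_id", list(self.sample_ids))
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id" or df.columns[-1] != "label":
            raise ValueError(
                "expected schema: sample_id, <features...>, label"
            )
        features = df.columns[1:-1]
        return cls(
            values=df[features].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            feature_names=tuple(features),
            sample_ids=tuple(str(s) for s in df["sample_id"]),
        )
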