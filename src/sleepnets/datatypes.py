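"""Core data container shared by every stage of the pipeline.

A cohort is an ``n x p`` matrix of binary (0/1) item responses with item
labels — e.g. 414 respondents by 12 sleep-change indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BinaryDataset:
    """An ``n x p`` matrix over {0, 1} with one label per column.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Binary responses; validated to contain only 0 and 1 and no
        missing values.
    labels : tuple of str
        Unique item names, one per column.
    """

    values: np.ndarray
    labels: tuple = field(default=())

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("values must contain only 0 and 1 (no missing)")
        arr = np.ascontiguousarray(arr, dtype=np.int8)
        labels = tuple(self.labels) if self.labels else tuple(
            f"item{i + 1}" for i in range(arr.shape[1])
        )
        if len(labels) != arr.shape[1]:
            raise ValueError(
                f"{len(labels)} labels for {arr.shape[1]} columns"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def marginals(self) -> np.ndarray:
        """Per-item endorsement probability (column means)."""
        return self.values.mean(axis=0)

    def constant_columns(self) -> list:
        """Labels of columns that are all-0 or all-1."""
        m = self.marginals()
        return [lab for lab, v in zip(self.labels, m) if v in (0.0, 1.0)]

    # ---- interchange -------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BinaryDataset":
        return cls(df.to_numpy(), tuple(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), columns=list(self.labels))

    @classmethod
    def from_csv(cls, path) -> "BinaryDataset":
        return cls.from_dataframe(pd.read_csv(path))

    def to_csv(self, path) -> None:
        # header + "0"/"1" cells, comma-delimited, LF endings
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")
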