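"""Cohort file handling and Insomnia Severity Index scoring.

Survey rows carry 12 binary sleep-change indicators (0 = no change /
change in the opposite direction, 1 = change), optionally a 7-item ISI
(each item 0-4) for two recall periods, and an optional chronotype
label.  Column names in the source file are mapped through a small
user-editable configuration, since deposited files rarely share a
schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BinaryDataset
from .simulate import STUDY_LABELS

ISI_BANDS = (
    (0, 7, "none"),
    (8, 14, "subthreshold"),
    (15, 21, "moderate"),
    (22, 28, "severe"),
)

CHRONOTYPES = frozenset({"M", "E", "A", "N", "V", "L", "Other"})

_BINARY_MAP = {"0": 0, "1": 1, "no": 0, "yes": 1, "false": 0, "true": 1}


@dataclass(frozen=True)
class ISIRecord:
    """Seven 0-4 Likert responses for one recall period."""

    items: tuple
    period: str = "post"

    def __post_init__(self):
        items = tuple(int(v) for v in self.items)
        if len(items) != 7:
            raise ValueError("ISI has exactly 7 items")
        for k, v in enumerate(items, start=1):
            if v not in (0, 1, 2, 3, 4):
                raise ValueError(f"ISI item {k} out of range 0-4: {v}")
        object.__setattr__(self, "items", items)


@dataclass(frozen=True)
class SurveyRecord:
    respondent: str
    change_items: dict                      # label -> 0/1, possibly partial
    isi_lockdown: ISIRecord | None = None
    isi_post: ISIRecord | None = None
    chronotype: str | None = None

    def __post_init__(self):
        if self.chronotype is not None and self.chronotype not in CHRONOTYPES:
            raise ValueError(f"unknown chronotype {self.chronotype!r}")

    def complete(self, labels=STUDY_LABELS) -> bool:
        return all(lab in self.change_items for lab in labels)


def score_isi(rec: ISIRecord) -> tuple:
    """Total score (0-28) and clinical category.

    Bands: 0-7 none, 8-14 subthreshold, 15-21 moderate, 22-28 severe;
    scores >= 15 indicate clinically significant insomnia.
    """
    total = sum(rec.items)
    for lo, hi, name in ISI_BANDS:
        if lo <= total <= hi:
            return total, name
    raise AssertionError("unreachable")


def insomnia_prevalence(records, cutoff: int = 15) -> float:
    """Fraction of scored ISI records at or above the clinical cutoff."""
    recs = list(records)
    if not recs:
        raise ValueError("need at least one scored record")
    return sum(1 for r in recs if sum(r.items) >= cutoff) / len(recs)


@dataclass
class CohortConfig:
    """Column mapping for a cohort file: change-item labels to source
    column names, plus optional ISI and chronotype columns."""

    item_columns: dict = field(
        default_factory=lambda: {lab: lab for lab in STUDY_LABELS})
    id_column: str | None = None
    isi_lockdown_columns: tuple = ()
    isi_post_columns: tuple = ()
    chronotype_column: str | None = None

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            item_columns=d.get("item_columns",
                               {lab: lab for lab in STUDY_LABELS}),
            id_column=d.get("id_column"),
            isi_lockdown_columns=tuple(d.get("isi_lockdown_columns", ())),
            isi_post_columns=tuple(d.get("isi_post_columns", ())),
            chronotype_column=d.get("chronotype_column"),
        )


def _decode_binary(value, row: int, column: str):
    if pd.isna(value):
        return None
    key = str(value).strip().lower()
    if key in ("", "nan"):
        return None
    if key.endswith(".0"):
        key = key[:-2]
    if key not in _BINARY_MAP:
        raise ValueError(
            f"row {row}, column {column!r}: cannot decode {value!r} as 0/1")
    return _BINARY_MAP[key]


def read_cohort_csv(path, config: CohortConfig | None = None) -> list:
    """Read survey records from a flat CSV through a column mapping.

    Accepts 0/1 and yes/no encodings.  Missing change items are kept as
    absent entries on the record; ``dichotomize_change_items`` excludes
    such records from network analysis and reports the count.
    """
    config = config or CohortConfig()
    df = pd.read_csv(path, dtype=str)
    for lab, colname in config.item_columns.items():
        if colname not in df.columns:
            raise ValueError(f"mapped column {colname!r} (item {lab!r}) "
                             "missing from file")
    records = []
    for ridx, row in df.iterrows():
        items = {}
        for lab, colname in config.item_columns.items():
            v = _decode_binary(row[colname], ridx, colname)
            if v is not None:
                items[lab] = v
        rid = (str(row[config.id_column]) if config.id_column
               else str(ridx))
        isi_lock = isi_post = None
        if config.isi_lockdown_columns:
            vals = [row[c] for c in config.isi_lockdown_columns]
            if not any(pd.isna(v) for v in vals):
                isi_lock = ISIRecord(tuple(int(float(v)) for v in vals),
                                     "lockdown")
        if config.isi_post_columns:
            vals = [row[c] for c in config.isi_post_columns]
            if not any(pd.isna(v) for v in vals):
                isi_post = ISIRecord(tuple(int(float(v)) for v in vals),
                                     "post")
        chrono = None
        if config.chronotype_column and not pd.isna(
                row[config.chronotype_column]):
            chrono = str(row[config.chronotype_column])
        records.append(SurveyRecord(rid, items, isi_lock, isi_post, chrono))
    return records


def dichotomize_change_items(records, labels=STUDY_LABELS) -> tuple:
    """Assemble the binary n x 12 analysis matrix in canonical item
    order; returns ``(dataset, n_excluded)`` where excluded rows had at
    least one missing change item."""
    recs = list(records)
    if not recs:
        raise ValueError("no survey records supplied")
    rows, excluded = [], 0
    for r in recs:
        if r.complete(labels):
            rows.append([r.change_items[lab] for lab in labels])
        else:
            excluded += 1
    if not rows:
        raise ValueError("no record has complete change items")
    return BinaryDataset(np.asarray(rows, dtype=np.int8),
                         tuple(labels)), excluded


def write_cohort_csv(records, path, labels=STUDY_LABELS) -> None:
    """Write change items back to CSV (complete records only)."""
    ds, _ = dichotomize_change_items(records, labels)
    ds.to_csv(path)
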