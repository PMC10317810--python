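"""Feature tables and the three prediction feature sets.

A :class:`FeatureTable` is a subjects × features matrix tagged with the
feature-set *kind* it represents:

``baseline``
    Raw regional measures at the pre-treatment scan (150 columns).
``week1``
    Raw regional measures one week after treatment initiation (150 columns).
``change``
    Baseline minus week 1 (positive = decrease over the first week);
    any sign allowed (150 columns).
``joint``
    Baseline and week-1 features concatenated into a single 300-column
    vector (``baseline_*`` columns first, then ``week1_*``).

Subject alignment between tables is always by subject id, never by row
order; the row order of derived tables follows the first argument.
Missing values are rejected rather than imputed — the intended analysis
uses complete cases only — and :func:`drop_incomplete_subjects` is the
explicit utility for upstream cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DuplicateSubjectError,
    SchemaMismatchError,
    TableParseError,
)
from .schema import RegionSchema

__all__ = [
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "compute_change_features",
    "concatenate_joint",
    "drop_incomplete_subjects",
    "KINDS",
]

KINDS = ("baseline", "week1", "change", "joint")
RAW_KINDS = ("baseline", "week1")

SUBJECT_ID_COLUMN = "subject_id"


@dataclass
class FeatureTable:
    """Validated subjects × features numeric matrix."""

    subject_ids: list[str]
    values: np.ndarray
    feature_names: list[str]
    kind: str
    schema_size: int = field(init=False)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature-set kind {self.kind!r}")
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match number of subject ids")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match number of feature names")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DuplicateSubjectError("duplicate subject ids in table")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]} ({self.subject_ids[bad[0]]}), "
                f"column {bad[1]} ({self.feature_names[bad[1]]})"
            )
        if self.kind in RAW_KINDS and self.values.size and self.values.min() <= 0:
            bad = np.argwhere(self.values <= 0)[0]
            raise ValueError(
                f"raw {self.kind} features must be strictly positive; "
                f"offending entry at row {bad[0]}, column {self.feature_names[bad[1]]}"
            )
        self.schema_size = len(self.feature_names)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def select(self, row_indices) -> "FeatureTable":
        """Row subset (e.g. a cross-validation fold), preserving validation."""
        row_indices = np.asarray(row_indices)
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in row_indices],
            values=self.values[row_indices],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, SUBJECT_ID_COLUMN, self.subject_ids)
        return df


def _expected_names(schema: RegionSchema, kind: str) -> list[str]:
    base = schema.feature_names
    if kind == "joint":
        return [f"baseline_{n}" for n in base] + [f"week1_{n}" for n in base]
    return base


def read_feature_table(path, schema: RegionSchema, kind: str, delimiter: str = ",") -> FeatureTable:
    """Read a delimited feature table and normalize columns to schema order.

    The file must have a ``subject_id`` column plus exactly one column per
    schema entry (order-free). Missing/extra columns, non-numeric cells and
    duplicate ids raise specific errors.
    """
    expected = _expected_names(schema, kind)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableParseError(f"cannot parse {path}: {exc}") from exc
    if SUBJECT_ID_COLUMN not in df.columns:
        raise TableParseError(f"{path}: missing required column {SUBJECT_ID_COLUMN!r}")
    present = [c for c in df.columns if c != SUBJECT_ID_COLUMN]
    missing = sorted(set(expected) - set(present))
    extra = sorted(set(present) - set(expected))
    if missing or extra:
        raise SchemaMismatchError(
            f"{path}: feature columns do not match schema "
            f"(missing: {missing[:5]}{'...' if len(missing) > 5 else ''}; "
            f"extra: {extra[:5]}{'...' if len(extra) > 5 else ''})",
            missing=missing,
            extra=extra,
        )
    ids = df[SUBJECT_ID_COLUMN].tolist()
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise DuplicateSubjectError(f"{path}: duplicate subject ids {sorted(dupes)}")
    matrix = np.empty((len(df), len(expected)), dtype=np.float64)
    for j, name in enumerate(expected):
        # numpy's string conversion is correctly rounded (bit-exact round trip);
        # pandas' fast to_numeric parser can be off by one ulp
        raw = df[name].to_numpy(dtype=object)
        try:
            col = raw.astype(np.float64)
        except (ValueError, TypeError):
            col = np.full(len(raw), np.nan)
            for i, cell in enumerate(raw):
                try:
                    col[i] = float(cell)
                except (ValueError, TypeError):
                    raise TableParseError(
                        f"{path}: non-numeric value {cell!r} at row {i} "
                        f"(subject {ids[i]}), column {name!r}",
                        row=i,
                        column=name,
                    ) from None
        bad = np.nonzero(~np.isfinite(col))[0]
        if bad.size:
            i = int(bad[0])
            raise TableParseError(
                f"{path}: non-finite value {raw[i]!r} at row {i} "
                f"(subject {ids[i]}), column {name!r}",
                row=i,
                column=name,
            )
        matrix[:, j] = col
    return FeatureTable(ids, matrix, expected, kind)


def write_feature_table(table: FeatureTable, path, delimiter: str = ",") -> None:
    """Write a feature table as delimited text with full float precision.

    Values are written with Python's shortest round-trip repr, so reading
    the file back recovers each float bit-exactly.
    """
    df = table.to_frame()
    df.to_csv(path, sep=delimiter, index=False)


def _check_pair(baseline: FeatureTable, week1: FeatureTable):
    if baseline.kind != "baseline" or week1.kind != "week1":
        raise SchemaMismatchError(
            f"expected kinds (baseline, week1), got ({baseline.kind}, {week1.kind})"
        )
    if baseline.feature_names != week1.feature_names:
        raise SchemaMismatchError("baseline and week1 tables use different schemas")
    only_b = sorted(set(baseline.subject_ids) - set(week1.subject_ids))
    only_w = sorted(set(week1.subject_ids) - set(baseline.subject_ids))
    if only_b or only_w:
        raise AlignmentError(
            f"subject sets differ (only in baseline: {only_b}; only in week1: {only_w})",
            only_first=only_b,
            only_second=only_w,
        )


def _aligned_week1_values(baseline: FeatureTable, week1: FeatureTable) -> np.ndarray:
    order = {s: i for i, s in enumerate(week1.subject_ids)}
    idx = [order[s] for s in baseline.subject_ids]
    return week1.values[idx]


def compute_change_features(baseline: FeatureTable, week1: FeatureTable) -> FeatureTable:
    """Baseline − week 1, aligned by subject id (positive = decrease)."""
    _check_pair(baseline, week1)
    values = baseline.values - _aligned_week1_values(baseline, week1)
    return FeatureTable(list(baseline.subject_ids), values, list(baseline.feature_names), "change")


def concatenate_joint(baseline: FeatureTable, week1: FeatureTable) -> FeatureTable:
    """Concatenate baseline and week-1 features into one longitudinal vector."""
    _check_pair(baseline, week1)
    values = np.hstack([baseline.values, _aligned_week1_values(baseline, week1)])
    names = [f"baseline_{n}" for n in baseline.feature_names] + [
        f"week1_{n}" for n in week1.feature_names
    ]
    # raw values are positive but 'joint' places no sign constraint; keep kind joint
    return FeatureTable(list(baseline.subject_ids), values, names, "joint")


def drop_incomplete_subjects(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows containing any missing value (explicit complete-case cleaning)."""
    return df.dropna(axis=0, how="any").reset_index(drop=True)
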