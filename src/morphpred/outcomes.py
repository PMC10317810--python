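"""Trial outcome definitions: responder rule and cohort flow.

Treatment response is assessed on the Young Mania Rating Scale (YMRS):
a *responder* shows a reduction of at least 50% from the baseline score to
the week-6 score. The boundary is inclusive — a subject going from 30 to
exactly 15 is a responder. Reductions are computed in exact floating
arithmetic with no rounding before the 0.5 comparison.

Cohort flow mirrors a two-arm randomized trial: subjects recruited, some
excluded before randomization (failed baseline MRI), arms assigned, some
lost to follow-up, and the remainder analyzed. Analyzed subjects must have
a week-6 score and satisfy the inclusion criterion of baseline YMRS ≥ 20;
violations raise a validation error rather than being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import CohortValidationError, LabelingError

__all__ = [
    "ARMS",
    "FLOW_STATUSES",
    "SubjectRecord",
    "ResponderLabel",
    "label_responders",
    "apply_cohort_flow",
    "read_subject_records",
    "write_subject_records",
    "format_flow_table",
    "YMRS_INCLUSION_MIN",
]

ARMS = ("quetiapine", "lithium")
FLOW_STATUSES = ("analyzed", "excluded_baseline_mri", "lost_followup")
YMRS_INCLUSION_MIN = 20

RECORD_COLUMNS = [
    "subject_id",
    "arm",
    "ymrs_baseline",
    "ymrs_week1",
    "ymrs_week6",
    "age_years",
    "sex",
    "flow_status",
]


@dataclass
class SubjectRecord:
    """Trial bookkeeping for one subject."""

    subject_id: str
    arm: Optional[str]  # None only for subjects excluded before randomization
    ymrs_baseline: Optional[float]
    ymrs_week1: Optional[float]
    ymrs_week6: Optional[float]
    age_years: Optional[float] = None
    sex: Optional[str] = None
    flow_status: str = "analyzed"

    def __post_init__(self):
        if self.flow_status not in FLOW_STATUSES:
            raise CohortValidationError(
                f"{self.subject_id}: unknown flow status {self.flow_status!r}"
            )
        if self.arm is not None and self.arm not in ARMS:
            raise CohortValidationError(f"{self.subject_id}: unknown arm {self.arm!r}")


@dataclass(frozen=True)
class ResponderLabel:
    subject_id: str
    responder: bool
    reduction_fraction: float


def label_responders(records: Iterable[SubjectRecord]) -> list[ResponderLabel]:
    """Apply the ≥50%-YMRS-reduction responder rule to each record."""
    labels = []
    for rec in records:
        if rec.ymrs_week6 is None:
            raise LabelingError(f"{rec.subject_id}: week-6 YMRS score absent")
        if rec.ymrs_baseline is None or rec.ymrs_baseline == 0:
            raise LabelingError(
                f"{rec.subject_id}: baseline YMRS missing or zero; "
                "reduction fraction undefined"
            )
        reduction = (rec.ymrs_baseline - rec.ymrs_week6) / rec.ymrs_baseline
        labels.append(ResponderLabel(rec.subject_id, reduction >= 0.5, reduction))
    return labels


def _validate_analyzed(rec: SubjectRecord) -> None:
    if rec.ymrs_week6 is None:
        raise CohortValidationError(
            f"{rec.subject_id}: flow status 'analyzed' but week-6 YMRS absent"
        )
    if rec.ymrs_baseline is None:
        raise CohortValidationError(
            f"{rec.subject_id}: flow status 'analyzed' but baseline YMRS absent"
        )
    if rec.ymrs_baseline < YMRS_INCLUSION_MIN:
        raise CohortValidationError(
            f"{rec.subject_id}: baseline YMRS {rec.ymrs_baseline} below the "
            f"inclusion threshold of {YMRS_INCLUSION_MIN}"
        )
    if rec.arm is None:
        raise CohortValidationError(
            f"{rec.subject_id}: flow status 'analyzed' but no treatment arm"
        )


def apply_cohort_flow(
    records: Iterable[SubjectRecord],
) -> tuple[list[SubjectRecord], dict[str, int]]:
    """Filter to analyzed subjects and tally the CONSORT-style flow counts.

    Returns the analyzed records (input order preserved) and a count map
    satisfying, overall and per arm:

    * recruited == excluded_baseline_mri + randomized
    * randomized_<arm> == lost_<arm> + analyzed_<arm>
    """
    records = list(records)
    counts = {
        "recruited": len(records),
        "excluded_baseline_mri": 0,
        "randomized": 0,
        "analyzed": 0,
    }
    for arm in ARMS:
        counts[f"randomized_{arm}"] = 0
        counts[f"lost_{arm}"] = 0
        counts[f"analyzed_{arm}"] = 0

    analyzed = []
    for rec in records:
        if rec.flow_status == "excluded_baseline_mri":
            counts["excluded_baseline_mri"] += 1
            continue
        if rec.arm is None:
            raise CohortValidationError(
                f"{rec.subject_id}: randomized subject without a treatment arm"
            )
        counts["randomized"] += 1
        counts[f"randomized_{rec.arm}"] += 1
        if rec.flow_status == "lost_followup":
            counts[f"lost_{rec.arm}"] += 1
        else:
            _validate_analyzed(rec)
            counts[f"analyzed_{rec.arm}"] += 1
            counts["analyzed"] += 1
            analyzed.append(rec)
    return analyzed, counts


def format_flow_table(counts: dict[str, int]) -> str:
    """Render flow counts as a plain-text CONSORT-style table."""
    lines = [
        "Cohort flow",
        "-----------",
        f"Recruited:                 {counts['recruited']}",
        f"Excluded (baseline MRI):   {counts['excluded_baseline_mri']}",
        f"Randomized:                {counts['randomized']}",
    ]
    for arm in ARMS:
        lines += [
            f"  {arm}:",
            f"    randomized:          {counts[f'randomized_{arm}']}",
            f"    lost to follow-up:   {counts[f'lost_{arm}']}",
            f"    analyzed:            {counts[f'analyzed_{arm}']}",
        ]
    lines.append(f"Analyzed (total):          {counts['analyzed']}")
    return "\n".join(lines)


def _opt_float(value):
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def read_subject_records(path, delimiter: str = ",") -> list[SubjectRecord]:
    """Read subject records from CSV with the fixed record header."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        arm = row["arm"] if isinstance(row["arm"], str) and row["arm"] else None
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                arm=arm,
                ymrs_baseline=_opt_float(row["ymrs_baseline"]),
                ymrs_week1=_opt_float(row["ymrs_week1"]),
                ymrs_week6=_opt_float(row["ymrs_week6"]),
                age_years=_opt_float(row["age_years"]),
                sex=row["sex"] if isinstance(row["sex"], str) and row["sex"] else None,
                flow_status=row["flow_status"],
            )
        )
    return records


def write_subject_records(records: Iterable[SubjectRecord], path, delimiter: str = ",") -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "arm": rec.arm or "",
                "ymrs_baseline": "" if rec.ymrs_baseline is None else rec.ymrs_baseline,
                "ymrs_week1": "" if rec.ymrs_week1 is None else rec.ymrs_week1,
                "ymrs_week6": "" if rec.ymrs_week6 is None else rec.ymrs_week6,
                "age_years": "" if rec.age_years is None else rec.age_years,
                "sex": rec.sex or "",
                "flow_status": rec.flow_status,
            }
        )
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, sep=delimiter, index=False)
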