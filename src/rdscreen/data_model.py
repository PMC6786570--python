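"""Questionnaire schema, respondent records, completeness filtering and encoding.

The screening questionnaire has 53 ordinal items answered on a 1..4 scale
(1 = "completely false", 4 = "completely true"; plain no/yes answers are
coded 1 and 4).  Together with the respondent's gender and age each completed
form becomes a 55-element numeric feature vector consumed by the binary
classifiers downstream.

Canonical on-disk format is a UTF-8 delimited file (CSV) with columns
``record_id, q01..q53, age, gender, diagnosis, group, rd_subgroup``;
spreadsheets (.xlsx) with the identical column contract are accepted as a
convenience.  Missing answers are empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 53
FEATURE_LENGTH = 55
ANSWER_LEVELS = (1, 2, 3, 4)
GROUPS = ("RD", "NRO", "CD", "PSY", "HEALTHY", "UNKNOWN")
GENDERS = ("F", "M")

#: Default numeric coding of gender in the feature vector.  Any fixed binary
#: coding is equivalent for the classifier families used here; this one is
#: documented and overridable in :func:`encode`.
GENDER_CODES = {"F": 0.0, "M": 1.0}


class SchemaError(ValueError):
    """Input table does not match the questionnaire column contract."""


class ValidationError(ValueError):
    """A record violates the questionnaire value constraints."""


def item_ids(n_items: int = N_ITEMS) -> list[str]:
    """Ordered item identifiers ``q01 .. q53``."""
    return [f"q{i:02d}" for i in range(1, n_items + 1)]


@dataclass(frozen=True)
class QuestionnaireSchema:
    """The 53-item, 4-level ordinal questionnaire layout.

    Items are identified ``q01..q53`` in fixed order; the answer scale is
    exactly ``{1, 2, 3, 4}`` with anchors from "completely false" to
    "completely true".  Age (years) and gender are the two demographic
    fields appended to the encoding.
    """

    items: tuple[str, ...] = tuple(item_ids())
    answer_levels: tuple[int, ...] = ANSWER_LEVELS

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise SchemaError(f"schema must have exactly {N_ITEMS} items, got {len(self.items)}")
        if len(set(self.items)) != len(self.items):
            raise SchemaError("item ids must be unique")
        if tuple(self.answer_levels) != ANSWER_LEVELS:
            raise SchemaError(f"answer scale must be exactly {ANSWER_LEVELS}")


@dataclass
class RespondentRecord:
    """One answered questionnaire.

    ``answers`` holds 53 entries, each an int in {1,2,3,4} or ``None`` when
    the respondent left the item blank.  ``group`` is the diagnostic group
    label (RD = rare disease, NRO = other non-rare, CD = chronic disease,
    PSY = psychosomatic/somatoform); ``diagnosis`` is the free-text
    diagnosis used for subset membership.
    """

    record_id: str
    answers: list[Optional[int]]
    age: Optional[int]
    gender: Optional[str]
    diagnosis: str = ""
    group: str = "UNKNOWN"
    rd_subgroup: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.answers) != N_ITEMS:
            raise ValidationError(
                f"record {self.record_id!r}: expected {N_ITEMS} answers, got {len(self.answers)}"
            )
        for qid, a in zip(item_ids(), self.answers):
            if a is not None and a not in ANSWER_LEVELS:
                raise ValidationError(
                    f"record {self.record_id!r}: answer {a!r} for {qid} outside {{1,2,3,4}}"
                )
        if self.age is not None and not (0 <= self.age <= 120):
            raise ValidationError(f"record {self.record_id!r}: age {self.age} outside 0-120")
        if self.gender is not None and self.gender not in GENDERS:
            raise ValidationError(
                f"record {self.record_id!r}: gender {self.gender!r} not in {GENDERS}"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"record {self.record_id!r}: group {self.group!r} not in {GROUPS}")

    @property
    def is_complete(self) -> bool:
        """True when all 53 answers, age and gender are present."""
        return (
            all(a is not None for a in self.answers)
            and self.age is not None
            and self.gender is not None
        )


# ---------------------------------------------------------------------------
# tabular I/O

REQUIRED_COLUMNS = ["record_id"] + item_ids() + ["age", "gender", "diagnosis", "group"]
ALL_COLUMNS = REQUIRED_COLUMNS + ["rd_subgroup"]


def _parse_cell(value, qid: str, record_id: str) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"record {record_id!r}: non-numeric answer {value!r} for {qid}")
    if float(value) != out:
        raise ValidationError(f"record {record_id!r}: non-integer answer {value!r} for {qid}")
    return out


def records_from_frame(df: pd.DataFrame, schema: QuestionnaireSchema | None = None) -> list[RespondentRecord]:
    """Validate a dataframe row-by-row into :class:`RespondentRecord` objects."""
    schema = schema or QuestionnaireSchema()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        rid = str(row["record_id"])
        answers = [_parse_cell(row[q], q, rid) for q in schema.items]
        age = row["age"]
        age = None if pd.isna(age) else int(age)
        gender = row["gender"]
        gender = None if pd.isna(gender) or gender == "" else str(gender).upper()
        sub = row.get("rd_subgroup")
        sub = None if sub is None or pd.isna(sub) or sub == "" else str(sub)
        records.append(
            RespondentRecord(
                record_id=rid,
                answers=answers,
                age=age,
                gender=gender,
                diagnosis="" if pd.isna(row["diagnosis"]) else str(row["diagnosis"]),
                group=str(row["group"]),
                rd_subgroup=sub,
            )
        )
    return records


def load_records(source: str | Path, schema: QuestionnaireSchema | None = None) -> list[RespondentRecord]:
    """Load respondent records from a CSV or .xlsx answer collection.

    Every row is validated; out-of-range answer codes raise
    :class:`ValidationError` naming the offending row and item rather than
    being silently coerced.
    """
    source = Path(source)
    if source.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(source)
    else:
        df = pd.read_csv(source)
    return records_from_frame(df, schema)


def records_to_frame(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {"record_id": r.record_id}
        for qid, a in zip(item_ids(), r.answers):
            row[qid] = "" if a is None else a
        row["age"] = "" if r.age is None else r.age
        row["gender"] = "" if r.gender is None else r.gender
        row["diagnosis"] = r.diagnosis
        row["group"] = r.group
        row["rd_subgroup"] = "" if r.rd_subgroup is None else r.rd_subgroup
        rows.append(row)
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


def write_records(records: Sequence[RespondentRecord], dest: str | Path) -> None:
    """Write records in the canonical CSV layout (or .xlsx by extension)."""
    dest = Path(dest)
    df = records_to_frame(records)
    if dest.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(dest, index=False)
    else:
        df.to_csv(dest, index=False)


# ---------------------------------------------------------------------------
# completeness and encoding

def completeness_filter(
    records: Sequence[RespondentRecord],
) -> tuple[list[RespondentRecord], list[RespondentRecord]]:
    """Partition records into (kept, excluded) by completeness.

    A record is kept only when all 53 answers plus age and gender are
    present; incomplete forms are excluded from training rather than
    imputed, mirroring the exclusion of incomplete questionnaires from the
    study pool.
    """
    kept = [r for r in records if r.is_complete]
    excluded = [r for r in records if not r.is_complete]
    return kept, excluded


def encode(
    record: RespondentRecord,
    gender_codes: dict[str, float] = GENDER_CODES,
) -> np.ndarray:
    """Encode a complete record as the 55-element feature vector.

    Layout: the 53 answers verbatim on their 1..4 scale, then the gender
    code (female 0, male 1 by default), then age in years.
    """
    if not record.is_complete:
        raise ValidationError(f"record {record.record_id!r} is incomplete; filter before encoding")
    vec = np.empty(FEATURE_LENGTH, dtype=float)
    vec[:N_ITEMS] = record.answers
    vec[N_ITEMS] = gender_codes[record.gender]
    vec[N_ITEMS + 1] = float(record.age)
    return vec


def decode(
    vector: np.ndarray,
    record_id: str = "decoded",
    gender_codes: dict[str, float] = GENDER_CODES,
) -> RespondentRecord:
    """Invert :func:`encode` (answers, gender, age recovered exactly)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (FEATURE_LENGTH,):
        raise ValidationError(f"feature vector must have length {FEATURE_LENGTH}")
    code_to_gender = {v: k for k, v in gender_codes.items()}
    return RespondentRecord(
        record_id=record_id,
        answers=[int(a) for a in vector[:N_ITEMS]],
        age=int(vector[N_ITEMS + 1]),
        gender=code_to_gender[vector[N_ITEMS]],
    )


def encode_records(records: Sequence[RespondentRecord]) -> np.ndarray:
    """Stack encodings of complete records into an (n, 55) design matrix."""
    return np.vstack([encode(r) for r in records])
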