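"""Assessment records: schema, CSV I/O, calendar quarters, longitudinal pairing.

Records move through the pipeline in two equivalent shapes: a pandas
DataFrame with one row per assessment (the shape every bulk operation
uses) and a list of :class:`AssessmentRecord` objects (the convenient
shape for unit-level work).  The CSV layout is one column per identity
field followed by one column per item code; the missing token is the
empty string, dates are ISO-8601.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dictionary import (
    ASSESSMENT_TYPES,
    IDENTITY_COLUMNS,
    ItemDictionary,
    SECTORS,
)

DATE_COLUMNS = ("reference_date", "signoff_date", "birthdate")


class SchemaError(ValueError):
    """Raised for header mismatches or out-of-domain item values."""


@dataclass
class AssessmentRecord:
    person_id: str
    facility_id: str
    sector: str
    assessment_type: str
    reference_date: dt.date
    signoff_date: dt.date | None
    birthdate: dt.date | None
    items: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.sector not in SECTORS:
            raise SchemaError(f"unknown sector {self.sector!r}")
        if self.assessment_type not in ASSESSMENT_TYPES:
            raise SchemaError(f"unknown assessment type {self.assessment_type!r}")

    def get(self, code: str):
        v = self.items.get(code)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v


@dataclass
class AssessmentPair:
    """Two chronologically consecutive assessments of one person in one sector."""

    person_id: str
    sector: str
    t1: AssessmentRecord
    t2: AssessmentRecord

    def __post_init__(self):
        if self.t1.person_id != self.t2.person_id or self.t1.sector != self.t2.sector:
            raise ValueError("pair members must share person and sector")
        if not self.t2.reference_date > self.t1.reference_date:
            raise ValueError("t2 must postdate t1")


@dataclass(frozen=True)
class Quarter:
    label: str  # "YYYY_Q"
    sector_index: int  # 0 at the sector's first observed quarter


# ---------------------------------------------------------------------------
# calendar quarters


def quarter_label(date: dt.date | pd.Timestamp) -> str:
    q = (date.month - 1) // 3 + 1
    return f"{date.year}_{q}"


def quarter_ordinal(label: str) -> int:
    """Number of calendar quarters since year 0 for a ``YYYY_Q`` label."""
    year, q = label.split("_")
    return int(year) * 4 + int(q) - 1


def assign_quarter(record: AssessmentRecord, sector_origin: Mapping[str, str]) -> Quarter:
    """Assign a record to its calendar quarter.

    ``sector_origin`` maps sector to the label of that sector's first
    observed quarter; ``sector_index`` counts quarters from it.
    """
    label = quarter_label(record.reference_date)
    origin = sector_origin[record.sector]
    return Quarter(label=label, sector_index=quarter_ordinal(label) - quarter_ordinal(origin))


def add_quarter_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Add ``quarter`` and per-sector ``quarter_index`` columns."""
    out = frame.copy()
    dates = pd.to_datetime(out["reference_date"])
    out["quarter"] = dates.dt.year.astype(str) + "_" + dates.dt.quarter.astype(str)
    ords = dates.dt.year * 4 + (dates.dt.quarter - 1)
    out["quarter_index"] = ords - ords.groupby(out["sector"]).transform("min")
    return out


# ---------------------------------------------------------------------------
# frame <-> record conversion


def _to_date(value) -> dt.date | None:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return pd.Timestamp(value).date()


def frame_to_records(frame: pd.DataFrame, dictionary: ItemDictionary) -> list[AssessmentRecord]:
    codes = dictionary.codes
    records = []
    for row in frame.to_dict("records"):
        items = {}
        for c in codes:
            v = row.get(c)
            items[c] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        records.append(
            AssessmentRecord(
                person_id=str(row["person_id"]),
                facility_id=str(row["facility_id"]),
                sector=row["sector"],
                assessment_type=row["assessment_type"],
                reference_date=_to_date(row["reference_date"]),
                signoff_date=_to_date(row.get("signoff_date")),
                birthdate=_to_date(row.get("birthdate")),
                items=items,
            )
        )
    return records


def records_to_frame(records: Sequence[AssessmentRecord], dictionary: ItemDictionary) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "person_id": r.person_id,
            "facility_id": r.facility_id,
            "sector": r.sector,
            "assessment_type": r.assessment_type,
            "reference_date": r.reference_date,
            "signoff_date": r.signoff_date,
            "birthdate": r.birthdate,
        }
        for c in dictionary.codes:
            row[c] = r.items.get(c)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(IDENTITY_COLUMNS) + list(dictionary.codes))


# ---------------------------------------------------------------------------
# CSV I/O


def validate_frame(frame: pd.DataFrame, dictionary: ItemDictionary) -> None:
    """Check header and item domains; raise SchemaError naming the offender."""
    expected = list(IDENTITY_COLUMNS) + list(dictionary.codes)
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise SchemaError(f"header mismatch: missing={missing[:5]} unexpected={extra[:5]}")
    for code, idef in dictionary.items.items():
        col = pd.to_numeric(frame[code], errors="coerce")
        present = frame[code].notna() & (frame[code] != "")
        bad_numeric = present & col.isna()
        if bad_numeric.any():
            row = int(np.flatnonzero(bad_numeric)[0])
            raise SchemaError(f"non-numeric value in column {code!r} row {row}")
        if idef.domain is not None:
            ok = col.isin(list(idef.domain)) | ~present
        else:
            ok = (~present) | ((col >= (idef.lo if idef.lo is not None else -np.inf))
                               & (col <= (idef.hi if idef.hi is not None else np.inf)))
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise SchemaError(
                f"out-of-domain value {frame[code].iloc[row]!r} in column {code!r} row {row}"
            )


def read_frame(path, dictionary: ItemDictionary) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"person_id": str, "facility_id": str},
                        keep_default_na=False, na_values=[""])
    validate_frame(frame, dictionary)
    for c in DATE_COLUMNS:
        frame[c] = pd.to_datetime(frame[c], format="%Y-%m-%d", errors="raise")
    for code in dictionary.codes:
        frame[code] = pd.to_numeric(frame[code], errors="coerce")
    return frame


def write_frame(frame: pd.DataFrame, path, dictionary: ItemDictionary) -> None:
    out = frame[list(IDENTITY_COLUMNS) + list(dictionary.codes)].copy()
    for c in DATE_COLUMNS:
        dates = pd.to_datetime(out[c], errors="coerce")
        out[c] = dates.dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def read_assessments(path, dictionary: ItemDictionary) -> list[AssessmentRecord]:
    return frame_to_records(read_frame(path, dictionary), dictionary)


def write_assessments(records: Sequence[AssessmentRecord], path, dictionary: ItemDictionary) -> None:
    write_frame(records_to_frame(records, dictionary), path, dictionary)


# ---------------------------------------------------------------------------
# filtering and pairing


def exclude_comatose(records):
    """Drop records assessed as comatose (idempotent).

    Accepts a DataFrame or a record list and returns the same shape.
    """
    if isinstance(records, pd.DataFrame):
        keep = ~(pd.to_numeric(records["comatose"], errors="coerce") == 1)
        return records.loc[keep].reset_index(drop=True)
    return [r for r in records if r.get("comatose") != 1]


def make_pairs(records: Sequence[AssessmentRecord]) -> list[AssessmentPair]:
    """Consecutive within-person, within-sector assessment pairs."""
    keyed = sorted(records, key=lambda r: (r.person_id, r.sector, r.reference_date))
    pairs = []
    for prev, cur in zip(keyed, keyed[1:]):
        if prev.person_id == cur.person_id and prev.sector == cur.sector:
            if prev.reference_date == cur.reference_date:
                raise ValueError(
                    f"duplicate assessment date {cur.reference_date} for person "
                    f"{cur.person_id} in {cur.sector}"
                )
            pairs.append(AssessmentPair(cur.person_id, cur.sector, prev, cur))
    return pairs


def pair_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Frame of (t1 index, t2 index) row positions for consecutive pairs.

    Returns a DataFrame with columns ``i1``/``i2`` holding integer row
    positions into ``frame`` (which is re-sorted internally; positions
    refer to the original frame).
    """
    order = frame.sort_values(["person_id", "sector", "reference_date"], kind="mergesort")
    idx = order.index.to_numpy()
    same = (
        (order["person_id"].to_numpy()[1:] == order["person_id"].to_numpy()[:-1])
        & (order["sector"].to_numpy()[1:] == order["sector"].to_numpy()[:-1])
    )
    dates = pd.to_datetime(order["reference_date"]).to_numpy()
    dup = same & (dates[1:] == dates[:-1])
    if dup.any():
        j = int(np.flatnonzero(dup)[0]) + 1
        raise ValueError(
            f"duplicate assessment date for person {order['person_id'].iloc[j]}"
        )
    return pd.DataFrame({"i1": idx[:-1][same], "i2": idx[1:][same]})
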