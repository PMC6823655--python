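"""Multi-source client record model and bundle input/output.

A *bundle* is the on-disk exchange format: one table per source record
type (encounters, HoNOS assessments, problem-list entries, vitals, ED
visits, acute admissions, administrative flags, PHQ-9 results), stored
either as a single JSON document or as a directory of CSV files.
Records from all tables are linked on an opaque ``client_id`` into a
:class:`VirtualPatientRecord` (VPR) — the unified per-client view the
scoring rules operate on.

Dates are ISO-8601 calendar dates throughout.  Linkage is exact-ID:
clients carrying different identifiers in different source systems are
treated as distinct people.
"""

from __future__ import annotations

import datetime as dt
import json
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from dateutil.relativedelta import relativedelta
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

__all__ = [
    "AnalysisWindow",
    "Encounter",
    "HonosAssessment",
    "ProblemEntry",
    "VitalsObservation",
    "EDVisit",
    "AcuteAdmission",
    "FlagKind",
    "FlagRecord",
    "Phq9Result",
    "VirtualPatientRecord",
    "Bundle",
    "BundleValidationError",
    "load_bundle",
    "write_bundle",
    "link_records",
    "window_filter",
    "latest_honos",
    "latest_phq9",
    "latest_vitals",
]

SCHEMA_VERSION = "1"


class AnalysisWindow(BaseModel):
    """Lookback window ``(as_of_date - lookback_months, as_of_date]``.

    The lookback is counted in calendar months (not a fixed day count):
    half-open at the start, inclusive of the as-of date.
    """

    model_config = ConfigDict(frozen=True)

    as_of_date: dt.date
    lookback_months: int = Field(default=18, gt=0)

    @property
    def start(self) -> dt.date:
        return self.as_of_date - relativedelta(months=self.lookback_months)

    def contains(self, date: dt.date) -> bool:
        return self.start < date <= self.as_of_date


class _Record(BaseModel):
    model_config = ConfigDict(extra="forbid")

    client_id: str = Field(min_length=1)


class Encounter(_Record):
    """A service contact.  ``booked and not attended`` is an NSBA
    (no-show with booked appointment)."""

    date: dt.date
    source_system: str = ""
    program: str = ""
    booked: bool = False
    attended: bool = True

    @property
    def is_nsba(self) -> bool:
        return self.booked and not self.attended


class HonosAssessment(_Record):
    """One HoNOS administration: twelve clinician-rated items, each 0-4."""

    date: dt.date
    items: list[int] = Field(min_length=12, max_length=12)

    @field_validator("items")
    @classmethod
    def _items_in_range(cls, v: list[int]) -> list[int]:
        for i, x in enumerate(v, start=1):
            if not 0 <= x <= 4:
                raise ValueError(f"HoNOS item {i} must be in 0..4, got {x}")
        return v

    def item(self, number: int) -> int:
        """Item score by its conventional 1-based number."""
        if not 1 <= number <= 12:
            raise IndexError(f"HoNOS item number must be 1..12, got {number}")
        return self.items[number - 1]

    @property
    def total(self) -> int:
        return sum(self.items)


class ProblemEntry(_Record):
    """A problem-list diagnosis (current-state; not window-filtered).

    The category booleans may be preset by the producer; the scoring
    layer additionally resolves them against configured code lists.
    """

    code: str = Field(min_length=1)
    label: str = ""
    is_sumh: bool = False
    is_complex_care: bool = False
    is_neurodegenerative: bool = False


class VitalsObservation(_Record):
    date: dt.date
    systolic_bp: Optional[float] = Field(default=None, gt=0)
    diastolic_bp: Optional[float] = Field(default=None, gt=0)
    bmi: Optional[float] = Field(default=None, gt=0)


class EDVisit(_Record):
    """Emergency-department visit with CTAS triage level (1 = most acute)."""

    date: dt.date
    ctas_level: int = Field(ge=1, le=5)


class AcuteAdmission(_Record):
    admit_date: dt.date
    discharge_date: Optional[dt.date] = None

    @model_validator(mode="after")
    def _discharge_after_admit(self) -> "AcuteAdmission":
        if self.discharge_date is not None and self.discharge_date < self.admit_date:
            raise ValueError("discharge_date precedes admit_date")
        return self

    def los_days(self, as_of: dt.date) -> int:
        """Length of stay in days; an open admission accrues up to ``as_of``."""
        end = self.discharge_date if self.discharge_date is not None else as_of
        return max(0, (end - self.admit_date).days)


class FlagKind(str, Enum):
    PWD_FORM = "PWD_FORM"
    SHX_CODE = "SHX_CODE"
    INTERRAI_MDS = "INTERRAI_MDS"
    MOBILITY_ASSESSMENT = "MOBILITY_ASSESSMENT"
    VIOLENCE_ALERT = "VIOLENCE_ALERT"
    EXTENDED_LEAVE = "EXTENDED_LEAVE"


class FlagRecord(_Record):
    """Administrative/status flag (disability forms, social-history codes,
    standardized ADL assessments, violence alerts, Extended Leave).

    Flags describe current state and are never window-filtered."""

    flag_kind: FlagKind
    date: Optional[dt.date] = None


class Phq9Result(_Record):
    date: dt.date
    total: int = Field(ge=0, le=27)


class VirtualPatientRecord(BaseModel):
    """Unified per-client view across all source systems."""

    model_config = ConfigDict(extra="forbid")

    client_id: str
    encounters: list[Encounter] = Field(default_factory=list)
    honos: list[HonosAssessment] = Field(default_factory=list)
    problems: list[ProblemEntry] = Field(default_factory=list)
    vitals: list[VitalsObservation] = Field(default_factory=list)
    ed_visits: list[EDVisit] = Field(default_factory=list)
    admissions: list[AcuteAdmission] = Field(default_factory=list)
    flags: list[FlagRecord] = Field(default_factory=list)
    phq9: list[Phq9Result] = Field(default_factory=list)

    def has_flag(self, kind: FlagKind) -> bool:
        return any(f.flag_kind == kind for f in self.flags)

    def record_count(self) -> int:
        return (
            len(self.encounters) + len(self.honos) + len(self.problems)
            + len(self.vitals) + len(self.ed_visits) + len(self.admissions)
            + len(self.flags) + len(self.phq9)
        )


# table name -> record model; order fixes serialization order everywhere
TABLES: dict[str, type[_Record]] = {
    "encounters": Encounter,
    "honos": HonosAssessment,
    "problems": ProblemEntry,
    "vitals": VitalsObservation,
    "ed_visits": EDVisit,
    "admissions": AcuteAdmission,
    "flags": FlagRecord,
    "phq9": Phq9Result,
}


class Bundle(BaseModel):
    """All source records, grouped by table, before linkage."""

    model_config = ConfigDict(extra="forbid")

    encounters: list[Encounter] = Field(default_factory=list)
    honos: list[HonosAssessment] = Field(default_factory=list)
    problems: list[ProblemEntry] = Field(default_factory=list)
    vitals: list[VitalsObservation] = Field(default_factory=list)
    ed_visits: list[EDVisit] = Field(default_factory=list)
    admissions: list[AcuteAdmission] = Field(default_factory=list)
    flags: list[FlagRecord] = Field(default_factory=list)
    phq9: list[Phq9Result] = Field(default_factory=list)

    def table(self, name: str) -> list:
        if name not in TABLES:
            raise KeyError(f"unknown table {name!r}")
        return getattr(self, name)

    def counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLES}

    def total_records(self) -> int:
        return sum(self.counts().values())

    def client_ids(self) -> list[str]:
        ids = {r.client_id for name in TABLES for r in self.table(name)}
        return sorted(ids)


class BundleValidationError(ValueError):
    """A bundle row failed validation; names the table, row and field."""

    def __init__(self, table: str, row: int, field: str, message: str):
        self.table = table
        self.row = row
        self.field = field
        super().__init__(f"{table}[{row}].{field}: {message}")


def _validate_row(table: str, row_index: int, model: type[_Record], raw: dict) -> _Record:
    try:
        return model.model_validate(raw)
    except ValidationError as exc:
        err = exc.errors()[0]
        field = ".".join(str(part) for part in err["loc"]) or "<row>"
        raise BundleValidationError(table, row_index, field, err["msg"]) from exc


# ---------------------------------------------------------------------------
# JSON bundle I/O

def _bundle_from_obj(obj: dict) -> Bundle:
    if not isinstance(obj, dict):
        raise BundleValidationError("<bundle>", 0, "<root>", "bundle must be a JSON object")
    tables: dict[str, list] = {}
    for name, model in TABLES.items():
        rows = obj.get(name, [])
        if not isinstance(rows, list):
            raise BundleValidationError(name, 0, "<table>", "table must be an array")
        tables[name] = [_validate_row(name, i, model, row) for i, row in enumerate(rows)]
    unknown = set(obj) - set(TABLES) - {"schema_version"}
    if unknown:
        raise BundleValidationError(sorted(unknown)[0], 0, "<table>", "unknown table")
    return Bundle(**tables)


def _bundle_to_obj(bundle: Bundle) -> dict:
    obj: dict = {"schema_version": SCHEMA_VERSION}
    for name in TABLES:
        obj[name] = [r.model_dump(mode="json") for r in bundle.table(name)]
    return obj


# ---------------------------------------------------------------------------
# CSV-directory bundle I/O

_CSV_BOOL = {"true": True, "1": True, "false": False, "0": False}


def _row_from_csv(table: str, row_index: int, model: type[_Record], raw: dict) -> _Record:
    """Convert a string-valued CSV row into the model's JSON shape."""
    out: dict = {}
    if table == "honos":
        items = []
        for i in range(1, 13):
            key = f"item{i}"
            val = raw.pop(key, "")
            if val == "":
                raise BundleValidationError(table, row_index, key, "missing HoNOS item")
            try:
                items.append(int(val))
            except ValueError:
                raise BundleValidationError(table, row_index, key, f"not an integer: {val!r}")
        out["items"] = items
    for key, val in raw.items():
        if val == "":
            continue  # absent optional value
        field = model.model_fields.get(key)
        if field is not None and field.annotation is bool:
            parsed = _CSV_BOOL.get(val.strip().lower())
            if parsed is None:
                raise BundleValidationError(table, row_index, key, f"not a boolean: {val!r}")
            out[key] = parsed
        else:
            out[key] = val
    return _validate_row(table, row_index, model, out)


def _csv_columns(table: str, model: type[_Record]) -> list[str]:
    cols = []
    for name in model.model_fields:
        if table == "honos" and name == "items":
            cols.extend(f"item{i}" for i in range(1, 13))
        else:
            cols.append(name)
    return cols


def _row_to_csv(table: str, record: _Record) -> dict:
    dumped = record.model_dump(mode="json")
    if table == "honos":
        items = dumped.pop("items")
        for i, val in enumerate(items, start=1):
            dumped[f"item{i}"] = val
    out = {}
    for key, val in dumped.items():
        if val is None:
            out[key] = ""
        elif isinstance(val, bool):
            out[key] = "true" if val else "false"
        else:
            out[key] = val
    return out


def _load_csv_dir(path: Path) -> Bundle:
    tables: dict[str, list] = {}
    for name, model in TABLES.items():
        file = path / f"{name}.csv"
        if not file.exists():
            tables[name] = []
            continue
        frame = pd.read_csv(file, dtype=str, keep_default_na=False)
        rows = frame.to_dict(orient="records")
        tables[name] = [_row_from_csv(name, i, model, dict(row)) for i, row in enumerate(rows)]
    return Bundle(**tables)


def _write_csv_dir(bundle: Bundle, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for name, model in TABLES.items():
        cols = _csv_columns(name, model)
        rows = [_row_to_csv(name, r) for r in bundle.table(name)]
        frame = pd.DataFrame(rows, columns=cols)
        frame.to_csv(path / f"{name}.csv", index=False)


# ---------------------------------------------------------------------------
# Public I/O surface

def load_bundle(path: str | Path, format: Optional[str] = None) -> Bundle:
    """Load a record bundle from a JSON file or a CSV directory.

    ``format`` is ``"json"`` or ``"csv-dir"``; by default it is inferred
    (directory -> CSV, file -> JSON).  Malformed rows raise
    :class:`BundleValidationError` naming table, row and field.
    """
    path = Path(path)
    if format is None:
        format = "csv-dir" if path.is_dir() else "json"
    if format == "csv-dir":
        if not path.is_dir():
            raise FileNotFoundError(f"bundle directory not found: {path}")
        return _load_csv_dir(path)
    if format == "json":
        if not path.is_file():
            raise FileNotFoundError(f"bundle file not found: {path}")
        with open(path, "r", encoding="utf-8") as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise BundleValidationError("<bundle>", 0, "<root>", f"invalid JSON: {exc}") from exc
        return _bundle_from_obj(obj)
    raise ValueError(f"unknown bundle format {format!r}")


def write_bundle(bundle: Bundle, path: str | Path, format: Optional[str] = None) -> None:
    """Write a bundle as JSON (single file) or as a CSV directory."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv-dir"
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_bundle_to_obj(bundle), fh, indent=1)
            fh.write("\n")
    elif format == "csv-dir":
        _write_csv_dir(bundle, path)
    else:
        raise ValueError(f"unknown bundle format {format!r}")


# ---------------------------------------------------------------------------
# Linkage and windowing

def link_records(bundle: Bundle) -> list[VirtualPatientRecord]:
    """Group all source records into one VPR per distinct client_id.

    Exact-ID linkage: every input record lands in exactly one VPR, and a
    client present in any table gets a VPR.  Output is sorted by id.
    """
    grouped: dict[str, dict[str, list]] = {}
    for name in TABLES:
        for record in bundle.table(name):
            grouped.setdefault(record.client_id, {t: [] for t in TABLES})[name].append(record)
    return [
        VirtualPatientRecord(client_id=cid, **tables)
        for cid, tables in sorted(grouped.items())
    ]


def window_filter(vpr: VirtualPatientRecord, window: AnalysisWindow) -> VirtualPatientRecord:
    """Restrict a VPR to the analysis window.

    Utilization and assessment records (encounters, HoNOS, vitals, ED
    visits, admissions, PHQ-9) are kept only when dated inside the
    window.  The problem list and status flags describe current state
    and pass through unfiltered.  An admission is retained when its stay
    intersects the window (an open admission extends to the as-of date).
    """
    def dated(records: Iterable) -> list:
        return [r for r in records if window.contains(r.date)]

    admissions = []
    for adm in vpr.admissions:
        end = adm.discharge_date if adm.discharge_date is not None else window.as_of_date
        if adm.admit_date <= window.as_of_date and end > window.start:
            admissions.append(adm)

    return vpr.model_copy(
        update=dict(
            encounters=dated(vpr.encounters),
            honos=dated(vpr.honos),
            vitals=dated(vpr.vitals),
            ed_visits=dated(vpr.ed_visits),
            phq9=dated(vpr.phq9),
            admissions=admissions,
        )
    )


def latest_honos(vpr: VirtualPatientRecord, window: AnalysisWindow) -> Optional[HonosAssessment]:
    """Most recent in-window HoNOS assessment, or None.

    Date ties are broken by the higher total item score (the
    complexity-preserving choice), which makes the pick deterministic.
    """
    candidates = [a for a in vpr.honos if window.contains(a.date)]
    if not candidates:
        return None
    return max(candidates, key=lambda a: (a.date, a.total))


def latest_phq9(vpr: VirtualPatientRecord, window: AnalysisWindow) -> Optional[Phq9Result]:
    """Most recent in-window PHQ-9 result; ties broken by higher total."""
    candidates = [r for r in vpr.phq9 if window.contains(r.date)]
    if not candidates:
        return None
    return max(candidates, key=lambda r: (r.date, r.total))


def latest_vitals(vpr: VirtualPatientRecord, window: AnalysisWindow) -> Optional[VitalsObservation]:
    """Most recent in-window vitals observation (stable on date ties)."""
    candidates = [v for v in vpr.vitals if window.contains(v.date)]
    if not candidates:
        return None
    best = candidates[0]
    for v in candidates[1:]:
        if v.date >= best.date:
            best = v
    return best
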