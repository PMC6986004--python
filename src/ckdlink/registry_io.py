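"""Data model and tabular I/O for the six administrative health registries.

The pipeline links person-level records across five routinely collected
sources — demographics/residence history, hospital discharge abstracts
(HDR), ticket (co-pay) exemptions (TER), outpatient specialist services
(OSSIS), drug dispensings (PHARM) — plus a dialysis registry (LDR) used
as a validation gold standard.  Every record carries an opaque person
identifier that is the exact linkage key across all registries.

All files are UTF-8, comma-separated with a header row; dates are
ISO 8601 (``YYYY-MM-DD``).  Multi-valued cells (hospital diagnoses,
procedures, service codes) are semicolon-delimited within one cell.
Residence history is a semicolon-delimited list of half-open intervals
``start/end`` where an empty ``end`` means the interval is still open.
The full column schemas are documented in ``docs/schemas.md`` and
enforced on read.
"""

from __future__ import annotations

import csv
import datetime
import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

log = logging.getLogger(__name__)

Date = datetime.date

#: ATC codes follow a letter / 2-digit / letter / letter / 2-digit level
#: structure; any prefix that ends on a level boundary is accepted.
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

_SEXES = ("male", "female")


class RegistryKind(str, enum.Enum):
    """The six registry file kinds handled by :func:`read_registry`."""

    DEMOGRAPHICS = "demographics"
    HDR = "hdr"
    TER = "ter"
    OSSIS = "ossis"
    PHARM = "pharm"
    LDR = "ldr"


class SchemaError(ValueError):
    """Header row does not match the documented column schema."""


class RowError(ValueError):
    """One or more data rows violated a type invariant.

    Carries ``(row_number, message)`` pairs in :attr:`row_errors`
    (row numbers are 1-based and count the header as row 1).
    """

    def __init__(self, path: Union[str, Path], row_errors: Sequence[tuple[int, str]]):
        self.row_errors = list(row_errors)
        detail = "; ".join(f"row {n}: {msg}" for n, msg in self.row_errors)
        super().__init__(f"{path}: {detail}")


def _parse_date(text: str, what: str) -> Date:
    try:
        return datetime.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValueError(f"unparseable {what} {text!r}") from exc


def _parse_opt_date(text: str, what: str) -> Optional[Date]:
    text = text.strip()
    return _parse_date(text, what) if text else None


@dataclass(frozen=True, order=True)
class PersonID:
    """Opaque pseudonymized identifier, identical across registries."""

    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("PersonID must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True)
class Demographics:
    """Sex, vital status and regional-residence history of one person.

    ``residence_intervals`` are half-open ``[start, end)`` periods of
    regional residence, sorted and non-overlapping; ``end is None``
    means the registration is still open.
    """

    person: PersonID
    sex: str
    birth_date: Date
    death_date: Optional[Date] = None
    residence_intervals: tuple[tuple[Date, Optional[Date]], ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.death_date is not None and self.birth_date > self.death_date:
            raise ValueError("birth_date after death_date")
        object.__setattr__(
            self, "residence_intervals", tuple(tuple(iv) for iv in self.residence_intervals)
        )
        prev_end: Optional[Date] = None
        for start, end in self.residence_intervals:
            if end is not None and start > end:
                raise ValueError(f"residence interval start {start} after end {end}")
            if prev_end is not None and start < prev_end:
                raise ValueError("residence intervals overlap or are unsorted")
            prev_end = datetime.date.max if end is None else end


@dataclass(frozen=True)
class HospitalRecord:
    """One hospital discharge abstract (HDR row).

    Up to six ICD-9-CM discharge diagnoses (first = primary), up to six
    ICD-9-CM procedures, and zero or more regional complex-outpatient
    package codes.  Out-of-region hospitalizations of residents are
    ordinary rows; the algorithm treats them identically.
    """

    person: PersonID
    admission_date: Date
    discharge_date: Date
    diagnoses: tuple[str, ...]
    procedures: tuple[str, ...] = ()
    service_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "diagnoses", tuple(self.diagnoses))
        object.__setattr__(self, "procedures", tuple(self.procedures))
        object.__setattr__(self, "service_codes", tuple(self.service_codes))
        if self.admission_date > self.discharge_date:
            raise ValueError("admission_date after discharge_date")
        if not 1 <= len(self.diagnoses) <= 6:
            raise ValueError("hospital record needs 1-6 diagnoses")
        if len(self.procedures) > 6:
            raise ValueError("hospital record allows at most 6 procedures")


@dataclass(frozen=True)
class ExemptionRecord:
    """Co-pay fee exemption (TER row); ``end_date is None`` = still active."""

    person: PersonID
    code: str
    start_date: Date
    end_date: Optional[Date] = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("exemption code must be non-empty")
        if self.end_date is not None and self.start_date > self.end_date:
            raise ValueError("start_date after end_date")


@dataclass(frozen=True)
class OutpatientRecord:
    """One outpatient specialist service (OSSIS row).

    ``branch`` is the specialty-branch qualifier of the dispensing
    clinic; nephrology is branch ``"29"``.  Records without a branch
    value never count as nephrology visits.
    """

    person: PersonID
    service_date: Date
    service_code: str
    branch: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.service_code:
            raise ValueError("service_code must be non-empty")


@dataclass(frozen=True)
class DrugRecord:
    """One drug dispensing (PHARM row), coded in the ATC system."""

    person: PersonID
    dispensing_date: Date
    atc: str

    def __post_init__(self) -> None:
        if not _ATC_RE.match(self.atc):
            raise ValueError(f"invalid ATC code {self.atc!r}")


class DialysisModality(str, enum.Enum):
    HEMODIALYSIS = "hemodialysis"
    PERITONEAL = "peritoneal"


@dataclass(frozen=True)
class DialysisRegistryRecord:
    """Chronic-dialysis registry entry (LDR row).

    Chronicity (at least 90 days of treatment) is the registry's own
    inclusion rule and is not re-checked here.
    """

    person: PersonID
    start_date: Date
    modality: DialysisModality

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality", DialysisModality(self.modality))


RegistryRecord = Union[
    Demographics,
    HospitalRecord,
    ExemptionRecord,
    OutpatientRecord,
    DrugRecord,
    DialysisRegistryRecord,
]


@dataclass
class RecordBundle:
    """All registries for one analysis run, already parsed."""

    demographics: list[Demographics] = field(default_factory=list)
    hdr: list[HospitalRecord] = field(default_factory=list)
    ter: list[ExemptionRecord] = field(default_factory=list)
    ossis: list[OutpatientRecord] = field(default_factory=list)
    pharm: list[DrugRecord] = field(default_factory=list)
    ldr: list[DialysisRegistryRecord] = field(default_factory=list)


# --------------------------------------------------------------------------
# residence

def resident_at(demographics: Demographics, date: Date) -> bool:
    """True iff some residence interval covers ``date``.

    Intervals are half-open: the start date is covered, the end date is
    not.  Vital status is handled separately by the cohort resolution.
    """
    for start, end in demographics.residence_intervals:
        if start <= date and (end is None or date < end):
            return True
    return False


# --------------------------------------------------------------------------
# CSV schemas

_SCHEMAS: dict[RegistryKind, list[str]] = {
    RegistryKind.DEMOGRAPHICS: [
        "person_id", "sex", "birth_date", "death_date", "residence_intervals",
    ],
    RegistryKind.HDR: [
        "person_id", "admission_date", "discharge_date",
        "diagnoses", "procedures", "service_codes",
    ],
    RegistryKind.TER: ["person_id", "code", "start_date", "end_date"],
    RegistryKind.OSSIS: ["person_id", "service_date", "service_code", "branch"],
    RegistryKind.PHARM: ["person_id", "dispensing_date", "atc"],
    RegistryKind.LDR: ["person_id", "start_date", "modality"],
}

#: Default file name for each registry kind.
DEFAULT_FILENAMES: dict[RegistryKind, str] = {
    RegistryKind.DEMOGRAPHICS: "demographics.csv",
    RegistryKind.HDR: "hdr.csv",
    RegistryKind.TER: "ter.csv",
    RegistryKind.OSSIS: "ossis.csv",
    RegistryKind.PHARM: "pharm.csv",
    RegistryKind.LDR: "ldr.csv",
}


def _split_multi(cell: str) -> tuple[str, ...]:
    return tuple(part for part in cell.split(";") if part.strip()) if cell.strip() else ()


def _join_multi(values: Sequence[str]) -> str:
    return ";".join(values)


def _intervals_to_cell(intervals) -> str:
    return ";".join(
        f"{start.isoformat()}/{end.isoformat() if end is not None else ''}"
        for start, end in intervals
    )


def _intervals_from_cell(cell: str):
    out = []
    for part in _split_multi(cell):
        start_s, _, end_s = part.partition("/")
        out.append((_parse_date(start_s, "residence start"),
                    _parse_opt_date(end_s, "residence end")))
    return tuple(out)


def _row_to_record(row: dict[str, str], kind: RegistryKind) -> RegistryRecord:
    pid = PersonID(row["person_id"].strip())
    if kind is RegistryKind.DEMOGRAPHICS:
        return Demographics(
            person=pid,
            sex=row["sex"].strip(),
            birth_date=_parse_date(row["birth_date"], "birth_date"),
            death_date=_parse_opt_date(row["death_date"], "death_date"),
            residence_intervals=_intervals_from_cell(row["residence_intervals"]),
        )
    if kind is RegistryKind.HDR:
        return HospitalRecord(
            person=pid,
            admission_date=_parse_date(row["admission_date"], "admission_date"),
            discharge_date=_parse_date(row["discharge_date"], "discharge_date"),
            diagnoses=_split_multi(row["diagnoses"]),
            procedures=_split_multi(row["procedures"]),
            service_codes=_split_multi(row["service_codes"]),
        )
    if kind is RegistryKind.TER:
        return ExemptionRecord(
            person=pid,
            code=row["code"].strip(),
            start_date=_parse_date(row["start_date"], "start_date"),
            end_date=_parse_opt_date(row["end_date"], "end_date"),
        )
    if kind is RegistryKind.OSSIS:
        branch = row["branch"].strip() or None
        return OutpatientRecord(
            person=pid,
            service_date=_parse_date(row["service_date"], "service_date"),
            service_code=row["service_code"].strip(),
            branch=branch,
        )
    if kind is RegistryKind.PHARM:
        return DrugRecord(
            person=pid,
            dispensing_date=_parse_date(row["dispensing_date"], "dispensing_date"),
            atc=row["atc"].strip().upper(),
        )
    if kind is RegistryKind.LDR:
        return DialysisRegistryRecord(
            person=pid,
            start_date=_parse_date(row["start_date"], "start_date"),
            modality=DialysisModality(row["modality"].strip()),
        )
    raise ValueError(f"unknown registry kind {kind}")  # pragma: no cover


def _record_to_row(record: RegistryRecord) -> list[str]:
    if isinstance(record, Demographics):
        return [
            record.person.value,
            record.sex,
            record.birth_date.isoformat(),
            record.death_date.isoformat() if record.death_date else "",
            _intervals_to_cell(record.residence_intervals),
        ]
    if isinstance(record, HospitalRecord):
        return [
            record.person.value,
            record.admission_date.isoformat(),
            record.discharge_date.isoformat(),
            _join_multi(record.diagnoses),
            _join_multi(record.procedures),
            _join_multi(record.service_codes),
        ]
    if isinstance(record, ExemptionRecord):
        return [
            record.person.value,
            record.code,
            record.start_date.isoformat(),
            record.end_date.isoformat() if record.end_date else "",
        ]
    if isinstance(record, OutpatientRecord):
        return [
            record.person.value,
            record.service_date.isoformat(),
            record.service_code,
            record.branch or "",
        ]
    if isinstance(record, DrugRecord):
        return [record.person.value, record.dispensing_date.isoformat(), record.atc]
    if isinstance(record, DialysisRegistryRecord):
        return [record.person.value, record.start_date.isoformat(), record.modality.value]
    raise TypeError(f"unknown record type {type(record)!r}")  # pragma: no cover


_RECORD_KIND: dict[type, RegistryKind] = {
    Demographics: RegistryKind.DEMOGRAPHICS,
    HospitalRecord: RegistryKind.HDR,
    ExemptionRecord: RegistryKind.TER,
    OutpatientRecord: RegistryKind.OSSIS,
    DrugRecord: RegistryKind.PHARM,
    DialysisRegistryRecord: RegistryKind.LDR,
}


def read_registry(
    path: Union[str, Path],
    registry_kind: Union[RegistryKind, str],
    lenient: bool = False,
) -> list[RegistryRecord]:
    """Parse one registry CSV into typed records.

    Raises :class:`SchemaError` if the header does not match the
    documented schema, and :class:`RowError` listing every offending row
    (1-based, header counted) if any data row violates a type invariant.
    With ``lenient=True`` bad rows are skipped with a logged warning
    instead.
    """
    kind = RegistryKind(registry_kind)
    expected = _SCHEMAS[kind]
    records: list[RegistryRecord] = []
    errors: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header {expected}")
        if [h.strip() for h in header] != expected:
            raise SchemaError(
                f"{path}: header {header} does not match expected columns {expected}"
            )
        for row_number, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(expected):
                errors.append((row_number, f"expected {len(expected)} columns, got {len(row)}"))
                continue
            try:
                records.append(_row_to_record(dict(zip(expected, row)), kind))
            except (ValueError, KeyError) as exc:
                errors.append((row_number, str(exc)))
    if errors:
        if not lenient:
            raise RowError(path, errors)
        for row_number, msg in errors:
            log.warning("%s row %d skipped: %s", path, row_number, msg)
    return records


def write_registry(records: Sequence[RegistryRecord], path: Union[str, Path]) -> None:
    """Write a homogeneous record list as a registry CSV.

    An empty list still gets a header (the kind must then be inferable
    from the file name, e.g. ``hdr.csv``).  ``read_registry`` on the
    output returns structurally equal records.
    """
    if records:
        kinds = {_RECORD_KIND[type(r)] for r in records}
        if len(kinds) != 1:
            raise ValueError(f"mixed record kinds {sorted(k.value for k in kinds)}")
        kind = kinds.pop()
    else:
        stem = Path(path).stem
        try:
            kind = RegistryKind(stem)
        except ValueError:
            raise ValueError(
                f"cannot infer registry kind for empty record list from {path!r}"
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCHEMAS[kind])
        for record in records:
            writer.writerow(_record_to_row(record))


def read_bundle(directory: Union[str, Path]) -> RecordBundle:
    """Read all registry files found under ``directory``.

    Missing files yield empty lists (e.g. a run without a dialysis
    registry simply skips validation).
    """
    directory = Path(directory)
    bundle = RecordBundle()
    for kind, filename in DEFAULT_FILENAMES.items():
        path = directory / filename
        if path.exists():
            setattr(bundle, kind.value, read_registry(path, kind))
    return bundle


def write_bundle(bundle: RecordBundle, directory: Union[str, Path]) -> None:
    """Write every registry in the bundle under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, filename in DEFAULT_FILENAMES.items():
        write_registry(getattr(bundle, kind.value), directory / filename)
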