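"""Two-tier severity classification of identified CKD cases.

A case is *higher severity* when, during the selection window, it shows
any of: (i) dialysis evidence — a dialysis or dialysis-access hospital
procedure on a non-excluded discharge, or a dialysis-related outpatient
service; (ii) transplant evidence — kidney-transplant procedure 55.6x,
transplant-status diagnosis V42.0, the transplant exemption, or a
transplant assessment/follow-up package; (iii) a hospital diagnosis of
CKD stage IV or greater (585.4x-585.6x); or (iv) at least one
dispensing of a qualifying drug.  All remaining cases are *lower
severity*.  Kidney biopsy (55.23) qualifies a case but is never
severity evidence.
"""

from __future__ import annotations

import datetime
import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .casefinder import (
    CaseRecord,
    ContributionTable,
    DEFAULT_WINDOW,
    StudyWindow,
    attribute_sources,
    exemption_active_at,
    hdr_record_excluded,
)
from .codelists import CodeCatalog, CodeSystem, any_match, normalize_code
from .registry_io import Demographics, PersonID, RecordBundle
from .utils import round_half_away

Date = datetime.date

HIGHER = "higher"
LOWER = "lower"


class EvidenceKind(str, enum.Enum):
    DIALYSIS = "dialysis"
    TRANSPLANT = "transplant"
    ADVANCED_STAGE_DX = "advanced_stage_dx"
    SEVERITY_DRUG = "severity_drug"


@dataclass(frozen=True)
class SeverityEvidence:
    kind: EvidenceKind
    source: str
    record: object
    date: Date


class SeverityIndex:
    """Per-person severity evidence, built once from the full bundle."""

    def __init__(
        self,
        bundle: RecordBundle,
        catalog: CodeCatalog,
        window: StudyWindow = DEFAULT_WINDOW,
    ):
        self._evidence: dict[PersonID, list[SeverityEvidence]] = defaultdict(list)
        add = self._add

        for record in bundle.hdr:
            if not window.contains(record.discharge_date):
                continue
            if hdr_record_excluded(record, catalog):
                continue  # the record no longer exists for the algorithm
            date = record.discharge_date
            for raw in record.procedures:
                code = normalize_code(raw, CodeSystem.ICD9_PROC)
                if any_match(code, catalog.dialysis_procedure_codes):
                    add(record.person, EvidenceKind.DIALYSIS, "HDR", record, date)
                if any_match(code, catalog.transplant_procedure_codes):
                    add(record.person, EvidenceKind.TRANSPLANT, "HDR", record, date)
            for raw in record.diagnoses:
                code = normalize_code(raw, CodeSystem.ICD9_DX)
                if any_match(code, catalog.severity_dx_codes):
                    add(record.person, EvidenceKind.ADVANCED_STAGE_DX, "HDR", record, date)
                if any_match(code, catalog.transplant_dx_codes):
                    add(record.person, EvidenceKind.TRANSPLANT, "HDR", record, date)
            for raw in record.service_codes:
                code = normalize_code(raw, CodeSystem.REGIONAL_SERVICE)
                if any_match(code, catalog.transplant_service_codes):
                    add(record.person, EvidenceKind.TRANSPLANT, "HDR", record, date)

        for record in bundle.ossis:
            if not window.contains(record.service_date):
                continue
            code = normalize_code(record.service_code, CodeSystem.REGIONAL_SERVICE)
            if any_match(code, catalog.ossis_dialysis_service_codes):
                add(record.person, EvidenceKind.DIALYSIS, "OSSIS", record,
                    record.service_date)

        for record in bundle.ter:
            code = normalize_code(record.code, CodeSystem.EXEMPTION)
            if any_match(code, catalog.transplant_ter_codes) and exemption_active_at(
                record, window.prevalence_date
            ):
                add(record.person, EvidenceKind.TRANSPLANT, "TER", record,
                    record.start_date)

        for record in bundle.pharm:
            if not window.contains(record.dispensing_date):
                continue
            code = normalize_code(record.atc, CodeSystem.ATC)
            if any_match(code, catalog.pharm_atc):
                add(record.person, EvidenceKind.SEVERITY_DRUG, "PHARM", record,
                    record.dispensing_date)

    def _add(self, person, kind, source, record, date) -> None:
        self._evidence[person].append(SeverityEvidence(kind, source, record, date))

    def evidence_for(self, person: PersonID) -> list[SeverityEvidence]:
        return sorted(
            self._evidence.get(person, []), key=lambda e: (e.date, e.kind.value)
        )


def classify_severity(
    case: CaseRecord,
    bundle: RecordBundle,
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
    index: Optional[SeverityIndex] = None,
) -> tuple[str, list[SeverityEvidence]]:
    """Severity tier and supporting evidence for one identified case.

    Pass a prebuilt :class:`SeverityIndex` when classifying many cases;
    it is rebuilt from the bundle otherwise.
    """
    if index is None:
        index = SeverityIndex(bundle, catalog, window)
    evidence = index.evidence_for(case.person)
    return (HIGHER if evidence else LOWER), evidence


def classify_all(
    cases: Sequence[CaseRecord],
    bundle: RecordBundle,
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
) -> dict[PersonID, list[SeverityEvidence]]:
    """Classify every case in place and return the evidence audit map."""
    index = SeverityIndex(bundle, catalog, window)
    audit: dict[PersonID, list[SeverityEvidence]] = {}
    for case in cases:
        tier, evidence = classify_severity(case, bundle, catalog, window, index)
        case.severity = tier
        audit[case.person] = evidence
    return audit


@dataclass
class SeveritySummary:
    """Counts and percentage shares of higher/lower severity cases."""

    total: int
    higher: int
    lower: int
    higher_share: float
    lower_share: float
    by_sex: Optional[dict[str, dict[str, int]]] = None

    @classmethod
    def from_counts(cls, higher: int, total: int,
                    by_sex: Optional[dict] = None) -> "SeveritySummary":
        if not 0 <= higher <= total:
            raise ValueError("need 0 <= higher <= total")
        if total == 0:
            return cls(0, 0, 0, 0.0, 0.0, by_sex)
        higher_share = round_half_away(100.0 * higher / total, 1)
        lower_share = round_half_away(100.0 * (total - higher) / total, 1)
        return cls(total, higher, total - higher, higher_share, lower_share, by_sex)

    def to_dict(self) -> dict:
        out = {
            "total": self.total,
            "higher": self.higher,
            "lower": self.lower,
            "higher_share": self.higher_share,
            "lower_share": self.lower_share,
        }
        if self.by_sex is not None:
            out["by_sex"] = self.by_sex
        return out


def severity_summary(
    cases: Sequence[CaseRecord],
    demographics: Optional[Sequence[Demographics]] = None,
) -> SeveritySummary:
    """Tally classified cases by severity, and by sex when demographics
    are supplied."""
    unclassified = [c.person.value for c in cases if c.severity not in (HIGHER, LOWER)]
    if unclassified:
        raise ValueError(f"unclassified cases: {unclassified[:10]}")
    higher = sum(1 for c in cases if c.severity == HIGHER)
    by_sex = None
    if demographics is not None:
        sex_of = {d.person: d.sex for d in demographics}
        by_sex = {
            sex: {"higher": 0, "lower": 0} for sex in ("male", "female")
        }
        for case in cases:
            by_sex[sex_of[case.person]][case.severity] += 1
    return SeveritySummary.from_counts(higher, len(cases), by_sex)


def higher_severity_contributions(
    cases: Sequence[CaseRecord],
) -> ContributionTable:
    """Source-attribution table restricted to higher-severity cases."""
    return attribute_sources([c for c in cases if c.severity == HIGHER])
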