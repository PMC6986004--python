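"""Rule-based identification of prevalent CKD cases.

A person enters the prevalent cohort when, during the selection window,
at least one source registry satisfies its inclusion rule:

* **HDR** — any hospital discharge carrying a qualifying diagnosis
  (primary or secondary), a qualifying procedure, or a complex
  outpatient package code.  To avoid capturing acute renal failure,
  a discharge whose *only* qualifying evidence is hemodialysis (39.95)
  and/or venous catheterization for dialysis (38.95) is discarded when
  any of its diagnoses is acute renal failure (584.x).
* **TER** — a CKD or kidney-transplant co-pay exemption active at the
  prevalence date.
* **OSSIS** — at least two nephrology visits on distinct dates, or one
  nephrology visit confirmed by a urine-albumin measurement or by a
  qualifying drug dispensing, or any dialysis-related outpatient
  service.
* **PHARM** — at least one dispensing of a drug reserved for advanced
  CKD (erythropoiesis-stimulating agents, phosphate binders, potassium
  binders).

Qualified persons who died on or before the prevalence date, or who
were not regional residents at the prevalence date, are excluded.  The
remaining persons form the prevalent cohort; each carries the full set
of triggers that qualified it, from which per-source exclusive
contributions are tabulated.
"""

from __future__ import annotations

import datetime
import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .codelists import CodeCatalog, CodeSystem, any_match, normalize_code
from .registry_io import (
    Demographics,
    DrugRecord,
    ExemptionRecord,
    HospitalRecord,
    OutpatientRecord,
    PersonID,
    RecordBundle,
    resident_at,
)
from .utils import round_half_away

Date = datetime.date


class Source(str, enum.Enum):
    HDR = "HDR"
    TER = "TER"
    OSSIS = "OSSIS"
    PHARM = "PHARM"


class Rule(str, enum.Enum):
    """Inclusion pathway satisfied by a trigger."""

    HDR_DIAGNOSIS = "hdr_diagnosis"
    HDR_PROCEDURE = "hdr_procedure"
    HDR_COMPLEX_SERVICE = "hdr_complex_service"
    TER_EXEMPTION = "ter_exemption"
    OSSIS_TWO_VISITS = "ossis_two_visits"
    OSSIS_VISIT_ALBUMIN = "ossis_visit_albumin"
    OSSIS_VISIT_DRUG = "ossis_visit_drug"
    OSSIS_DIALYSIS_SERVICE = "ossis_dialysis_service"
    PHARM_DISPENSING = "pharm_dispensing"


@dataclass(frozen=True)
class StudyWindow:
    """Selection window; the prevalence date is its last day."""

    start: Date
    end: Date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window start after end")

    @property
    def prevalence_date(self) -> Date:
        return self.end

    def contains(self, date: Date) -> bool:
        return self.start <= date <= self.end


#: Selection window of the published study.
DEFAULT_WINDOW = StudyWindow(datetime.date(2012, 1, 1), datetime.date(2017, 12, 31))


@dataclass(frozen=True)
class Trigger:
    """One record (or record pair) that satisfied an inclusion rule."""

    source: Source
    rule: Rule
    records: tuple = ()
    date: Optional[Date] = None


@dataclass
class CaseRecord:
    """An identified prevalent case with its qualifying evidence."""

    person: PersonID
    triggers: tuple[Trigger, ...]
    severity: Optional[str] = None  # filled by the severity classifier

    def __post_init__(self) -> None:
        self.triggers = tuple(self.triggers)
        if not self.triggers:
            raise ValueError("a case needs at least one trigger")

    @property
    def sources(self) -> frozenset[Source]:
        return frozenset(t.source for t in self.triggers)


@dataclass(frozen=True)
class RuleFlags:
    """Configurable readings of genuinely ambiguous inclusion rules.

    ``ossis_rule`` — ``"drug_standalone"`` (default) lets a qualifying
    dispensing alone qualify a person through PHARM, in addition to
    confirming a single nephrology visit; ``"drug_confirms_only"``
    restricts dispensings to the visit-confirmation role.

    ``ossis_dialysis_standalone`` — whether a dialysis-related
    outpatient service qualifies directly without visit confirmation.
    """

    ossis_rule: str = "drug_standalone"
    ossis_dialysis_standalone: bool = True

    def __post_init__(self) -> None:
        if self.ossis_rule not in ("drug_standalone", "drug_confirms_only"):
            raise ValueError(f"unknown ossis_rule {self.ossis_rule!r}")


# --------------------------------------------------------------------------
# per-record HDR evidence

def hdr_evidence(
    record: HospitalRecord, catalog: CodeCatalog
) -> tuple[list[str], list[str], list[str]]:
    """Normalized qualifying (diagnoses, procedures, services) of a record."""
    dx = [
        c for c in (normalize_code(d, CodeSystem.ICD9_DX) for d in record.diagnoses)
        if any_match(c, catalog.hdr_diagnoses)
    ]
    procs = [
        c for c in (normalize_code(p, CodeSystem.ICD9_PROC) for p in record.procedures)
        if any_match(c, catalog.hdr_procedures)
    ]
    svcs = [
        c for c in (normalize_code(s, CodeSystem.REGIONAL_SERVICE) for s in record.service_codes)
        if any_match(c, catalog.hdr_complex_services)
    ]
    return dx, procs, svcs


def hdr_record_excluded(record: HospitalRecord, catalog: CodeCatalog) -> bool:
    """Acute-renal-failure exclusion, applied per record.

    True when the record's only qualifying evidence is the procedure
    39.95 and/or 38.95 and one of its diagnoses is 584.x.  Such a
    record no longer exists for the algorithm: it neither qualifies a
    case nor contributes severity evidence.
    """
    dx, procs, svcs = hdr_evidence(record, catalog)
    if dx or svcs or not procs:
        return False
    if not all(any_match(p, catalog.acute_exclusion_procedures) for p in procs):
        return False
    return any(
        any_match(normalize_code(d, CodeSystem.ICD9_DX), catalog.acute_renal_failure_dx)
        for d in record.diagnoses
    )


def qualify_hdr(
    records: Sequence[HospitalRecord],
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
) -> dict[PersonID, list[Trigger]]:
    """Hospital-discharge inclusion rule; window membership by discharge date."""
    out: dict[PersonID, list[Trigger]] = defaultdict(list)
    for record in records:
        if not window.contains(record.discharge_date):
            continue
        if hdr_record_excluded(record, catalog):
            continue
        dx, procs, svcs = hdr_evidence(record, catalog)
        if dx:
            out[record.person].append(
                Trigger(Source.HDR, Rule.HDR_DIAGNOSIS, (record,), record.discharge_date)
            )
        if procs:
            out[record.person].append(
                Trigger(Source.HDR, Rule.HDR_PROCEDURE, (record,), record.discharge_date)
            )
        if svcs:
            out[record.person].append(
                Trigger(Source.HDR, Rule.HDR_COMPLEX_SERVICE, (record,), record.discharge_date)
            )
    return dict(out)


def exemption_active_at(record: ExemptionRecord, date: Date) -> bool:
    return record.start_date <= date and (record.end_date is None or record.end_date > date)


def qualify_ter(
    records: Sequence[ExemptionRecord],
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
) -> dict[PersonID, list[Trigger]]:
    """Exemption rule: a qualifying code registered and active at the
    prevalence date."""
    out: dict[PersonID, list[Trigger]] = defaultdict(list)
    for record in records:
        code = normalize_code(record.code, CodeSystem.EXEMPTION)
        if not any_match(code, catalog.ter_codes):
            continue
        if not exemption_active_at(record, window.prevalence_date):
            continue
        out[record.person].append(
            Trigger(Source.TER, Rule.TER_EXEMPTION, (record,), record.start_date)
        )
    return dict(out)


def _is_nephrology_visit(record: OutpatientRecord, catalog: CodeCatalog) -> bool:
    if record.branch != catalog.nephrology_branch:
        return False
    code = normalize_code(record.service_code, CodeSystem.REGIONAL_SERVICE)
    return any_match(code, catalog.ossis_visit_codes)


def qualify_ossis(
    ossis: Sequence[OutpatientRecord],
    pharm: Sequence[DrugRecord],
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
    flags: RuleFlags = RuleFlags(),
) -> dict[PersonID, list[Trigger]]:
    """Outpatient rule with visit-confirmation logic.

    Pathways: (a) two nephrology visits on distinct dates; (b) one
    visit plus a urine-albumin measurement; (c) one visit plus a
    qualifying dispensing — which also contributes a PHARM trigger for
    the supporting dispensing; (d) any dialysis-related service, when
    ``flags.ossis_dialysis_standalone`` is set.
    """
    visits: dict[PersonID, list[OutpatientRecord]] = defaultdict(list)
    albumin: dict[PersonID, list[OutpatientRecord]] = defaultdict(list)
    dialysis: dict[PersonID, list[OutpatientRecord]] = defaultdict(list)
    for record in ossis:
        if not window.contains(record.service_date):
            continue
        code = normalize_code(record.service_code, CodeSystem.REGIONAL_SERVICE)
        if _is_nephrology_visit(record, catalog):
            visits[record.person].append(record)
        if any_match(code, catalog.ossis_albumin_code):
            albumin[record.person].append(record)
        if any_match(code, catalog.ossis_dialysis_service_codes):
            dialysis[record.person].append(record)

    drugs: dict[PersonID, list[DrugRecord]] = defaultdict(list)
    for record in pharm:
        if not window.contains(record.dispensing_date):
            continue
        if any_match(normalize_code(record.atc, CodeSystem.ATC), catalog.pharm_atc):
            drugs[record.person].append(record)

    out: dict[PersonID, list[Trigger]] = defaultdict(list)
    for person, vs in visits.items():
        distinct_dates = sorted({v.service_date for v in vs})
        if len(distinct_dates) >= 2:
            out[person].append(
                Trigger(Source.OSSIS, Rule.OSSIS_TWO_VISITS, tuple(vs), distinct_dates[1])
            )
        if albumin.get(person):
            first = albumin[person][0]
            out[person].append(
                Trigger(
                    Source.OSSIS, Rule.OSSIS_VISIT_ALBUMIN,
                    (vs[0], first), first.service_date,
                )
            )
        if drugs.get(person):
            supporting = drugs[person][0]
            out[person].append(
                Trigger(
                    Source.OSSIS, Rule.OSSIS_VISIT_DRUG,
                    (vs[0], supporting), supporting.dispensing_date,
                )
            )
            out[person].append(
                Trigger(
                    Source.PHARM, Rule.PHARM_DISPENSING,
                    (supporting,), supporting.dispensing_date,
                )
            )
    if flags.ossis_dialysis_standalone:
        for person, ds in dialysis.items():
            out[person].append(
                Trigger(
                    Source.OSSIS, Rule.OSSIS_DIALYSIS_SERVICE,
                    tuple(ds), ds[0].service_date,
                )
            )
    return dict(out)


def qualify_pharm(
    pharm: Sequence[DrugRecord],
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
) -> dict[PersonID, list[Trigger]]:
    """Standalone dispensing rule: one qualifying dispensing suffices."""
    out: dict[PersonID, list[Trigger]] = defaultdict(list)
    for record in pharm:
        if not window.contains(record.dispensing_date):
            continue
        if any_match(normalize_code(record.atc, CodeSystem.ATC), catalog.pharm_atc):
            out[record.person].append(
                Trigger(
                    Source.PHARM, Rule.PHARM_DISPENSING,
                    (record,), record.dispensing_date,
                )
            )
    return dict(out)


def qualify_all(
    bundle: RecordBundle,
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
    flags: RuleFlags = RuleFlags(),
) -> list[Mapping[PersonID, list[Trigger]]]:
    """Run every source rule and return the per-source trigger maps."""
    maps = [
        qualify_hdr(bundle.hdr, catalog, window),
        qualify_ter(bundle.ter, catalog, window),
        qualify_ossis(bundle.ossis, bundle.pharm, catalog, window, flags),
    ]
    if flags.ossis_rule == "drug_standalone":
        maps.append(qualify_pharm(bundle.pharm, catalog, window))
    return maps


def resolve_cohort(
    qualified: Iterable[Mapping[PersonID, list[Trigger]]],
    demographics: Sequence[Demographics],
    window: StudyWindow = DEFAULT_WINDOW,
) -> list[CaseRecord]:
    """Merge per-source trigger maps into the prevalent cohort.

    Excludes persons dead on or before the prevalence date and persons
    not resident at the prevalence date.  Raises ``KeyError`` listing
    qualified persons missing from demographics.  Output is sorted by
    person identifier for reproducibility.
    """
    merged: dict[PersonID, list[Trigger]] = defaultdict(list)
    for source_map in qualified:
        for person, triggers in source_map.items():
            merged[person].extend(triggers)

    demo_index = {d.person: d for d in demographics}
    orphans = sorted(p.value for p in merged if p not in demo_index)
    if orphans:
        raise KeyError(
            f"{len(orphans)} qualified person(s) missing from demographics: "
            + ", ".join(orphans[:20])
        )

    prevalence_date = window.prevalence_date
    cases = []
    for person in sorted(merged):
        demo = demo_index[person]
        if demo.death_date is not None and demo.death_date <= prevalence_date:
            continue
        if not resident_at(demo, prevalence_date):
            continue
        cases.append(CaseRecord(person=person, triggers=tuple(merged[person])))
    return cases


@dataclass
class ContributionTable:
    """Exclusive per-source contributions to case identification.

    A case contributes exclusively to source S when S is its only
    qualifying source; the ``all_sources`` line counts cases found in
    every one of the four databases.  Shares are percentages of the
    total, rounded half-away-from-zero to one decimal.
    """

    total: int
    exclusive_counts: dict[Source, int]
    all_sources_count: int
    exclusive_shares: dict[Source, float] = field(init=False)
    all_sources_share: float = field(init=False)

    def __post_init__(self) -> None:
        self.exclusive_shares = {
            s: self._share(n) for s, n in self.exclusive_counts.items()
        }
        self.all_sources_share = self._share(self.all_sources_count)

    def _share(self, count: int) -> float:
        if self.total == 0:
            return 0.0
        return round_half_away(100.0 * count / self.total, 1)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "exclusive_counts": {s.value: n for s, n in self.exclusive_counts.items()},
            "exclusive_shares": {s.value: v for s, v in self.exclusive_shares.items()},
            "all_sources_count": self.all_sources_count,
            "all_sources_share": self.all_sources_share,
        }


def attribute_sources(cases: Sequence[CaseRecord]) -> ContributionTable:
    """Tabulate exclusive and all-database contributions of the sources."""
    exclusive = {s: 0 for s in Source}
    all_sources = 0
    for case in cases:
        sources = case.sources
        if len(sources) == 1:
            exclusive[next(iter(sources))] += 1
        if sources >= frozenset(Source):
            all_sources += 1
    return ContributionTable(
        total=len(cases),
        exclusive_counts=exclusive,
        all_sources_count=all_sources,
    )


def identify(
    bundle: RecordBundle,
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
    flags: RuleFlags = RuleFlags(),
) -> list[CaseRecord]:
    """Full case identification: source rules then cohort resolution."""
    return resolve_cohort(qualify_all(bundle, catalog, window, flags),
                          bundle.demographics, window)
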