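"""Independent per-person re-evaluation of the inclusion rules.

This oracle deliberately shares no code with the package: it spells
the code lists as literal regular expressions and walks every record
of every person one by one.  It is used to cross-check the pipeline on
randomized instances.
"""

import datetime
import re

import numpy as np

from ckdlink.registry_io import (
    Demographics,
    DrugRecord,
    ExemptionRecord,
    HospitalRecord,
    OutpatientRecord,
    PersonID,
    RecordBundle,
)

D = datetime.date

_HDR_DX = re.compile(
    r"^(2504.*|403.*|404.*|582.*|583.*|585.*|586.*|587.*|588.*|7531.*|5900.*|V56.*|V420)$"
)
_HDR_PROC = re.compile(r"^(3995|5498|556.*|3927|5493|3942|3943|3895|5523)$")
_HDR_SVC = re.compile(r"^(P583|P585A|P585B|PV420)$")
_TER = re.compile(r"^(025585|025V420)$")
_VISIT = re.compile(r"^(897|8901|8903)$")
_ALBUMIN = re.compile(r"^90334$")
_OSSIS_DIALYSIS = re.compile(r"^(3995.*|5498.*|3895|5493|39991|9782|97291)$")
_ATC = re.compile(r"^(B03XA01|B03XA02|B03XA03|V03AE01|V03AE02|V03AE03|V03AE05)$")
_ARF = re.compile(r"^584.*$")
_SEV_DX = re.compile(r"^(5854.*|5855.*|5856.*)$")
_DIALYSIS_PROC = re.compile(r"^(3995|5498|3927|5493|3942|3943|3895)$")
_TRANSPLANT_PROC = re.compile(r"^556.*$")


def _norm(code: str) -> str:
    return code.replace(".", "").replace(" ", "").upper()


def _in_window(date, start, end) -> bool:
    return start <= date <= end


def _hdr_record_kept(rec: HospitalRecord) -> bool:
    """Acute-failure trap, re-derived from scratch."""
    dx_hits = [c for c in map(_norm, rec.diagnoses) if _HDR_DX.match(c)]
    proc_hits = [c for c in map(_norm, rec.procedures) if _HDR_PROC.match(c)]
    svc_hits = [c for c in map(_norm, rec.service_codes) if _HDR_SVC.match(c)]
    if not (dx_hits or proc_hits or svc_hits):
        return False  # nothing qualifying at all
    if dx_hits or svc_hits:
        return True
    if all(c in ("3995", "3895") for c in proc_hits) and any(
        _ARF.match(c) for c in map(_norm, rec.diagnoses)
    ):
        return False
    return True


def naive_person_eval(
    person: PersonID,
    bundle: RecordBundle,
    start: D,
    end: D,
) -> set[str]:
    """Source set qualifying this person, by brute record-by-record scan."""
    sources: set[str] = set()

    for rec in bundle.hdr:
        if rec.person != person or not _in_window(rec.discharge_date, start, end):
            continue
        if _hdr_record_kept(rec):
            sources.add("HDR")

    for rec in bundle.ter:
        if rec.person != person:
            continue
        if _TER.match(_norm(rec.code)) and rec.start_date <= end and (
            rec.end_date is None or rec.end_date > end
        ):
            sources.add("TER")

    visit_dates = set()
    albumin = False
    dialysis_service = False
    for rec in bundle.ossis:
        if rec.person != person or not _in_window(rec.service_date, start, end):
            continue
        code = _norm(rec.service_code)
        if rec.branch == "29" and _VISIT.match(code):
            visit_dates.add(rec.service_date)
        if _ALBUMIN.match(code):
            albumin = True
        if _OSSIS_DIALYSIS.match(code):
            dialysis_service = True

    has_drug = any(
        rec.person == person
        and _in_window(rec.dispensing_date, start, end)
        and _ATC.match(_norm(rec.atc))
        for rec in bundle.pharm
    )

    if (
        len(visit_dates) >= 2
        or (len(visit_dates) >= 1 and (albumin or has_drug))
        or dialysis_service
    ):
        sources.add("OSSIS")
    if has_drug:
        sources.add("PHARM")
    return sources


def naive_cohort(bundle: RecordBundle, start: D, end: D) -> dict[PersonID, set[str]]:
    """Person -> qualifying source set for the surviving cohort."""
    out = {}
    for demo in bundle.demographics:
        if demo.death_date is not None and demo.death_date <= end:
            continue
        covered = any(
            s <= end and (e is None or end < e) for s, e in demo.residence_intervals
        )
        if not covered:
            continue
        sources = naive_person_eval(demo.person, bundle, start, end)
        if sources:
            out[demo.person] = sources
    return out


# --------------------------------------------------------------------------
# randomized instances for oracle trials

_DX_POOL = ["585.3", "585.4", "584.9", "401.9", "V42.0", "250.40", "590.0",
            "590.1", "753.1", "763.1", "586", "428.0"]
_PROC_POOL = ["39.95", "38.95", "55.69", "55.23", "99.99", "54.98", "39.27"]
_SVC_POOL = ["P583", "PV420", "P999"]
_OSSIS_POOL = ["89.7", "89.01", "89.03", "90.33.4", "39.95.1", "97.82", "88.7",
               "90.44.1"]
_BRANCH_POOL = ["29", "29", "08", None]
_ATC_POOL = ["B03XA01", "V03AE02", "C09AA05", "A10BA02"]
_TER_POOL = ["025.585", "025.V42.0", "025.999"]


def _rand_date(rng, lo=D(2011, 1, 1), hi=D(2018, 6, 30)) -> D:
    return lo + datetime.timedelta(days=int(rng.integers((hi - lo).days + 1)))


def random_instance(seed: int, n_persons: int = 200) -> RecordBundle:
    """A messy random registry set: codes in and out of the catalogue,
    dates in and out of the window, deaths and closed residences."""
    rng = np.random.default_rng(seed)
    bundle = RecordBundle()
    for i in range(n_persons):
        person = PersonID(f"R{i:04d}")
        death = _rand_date(rng) if rng.random() < 0.08 else None
        if rng.random() < 0.08:
            residence = ((D(2000, 1, 1), _rand_date(rng)),)
        else:
            residence = ((D(2000, 1, 1), None),)
        bundle.demographics.append(
            Demographics(
                person=person,
                sex="male" if rng.random() < 0.5 else "female",
                birth_date=D(1960, 1, 1),
                death_date=death,
                residence_intervals=residence,
            )
        )
        for _ in range(rng.integers(0, 3)):
            discharge = _rand_date(rng)
            n_dx = int(rng.integers(1, 4))
            n_proc = int(rng.integers(0, 3))
            bundle.hdr.append(
                HospitalRecord(
                    person=person,
                    admission_date=discharge - datetime.timedelta(days=2),
                    discharge_date=discharge,
                    diagnoses=tuple(rng.choice(_DX_POOL, n_dx)),
                    procedures=tuple(rng.choice(_PROC_POOL, n_proc)),
                    service_codes=tuple(rng.choice(_SVC_POOL, int(rng.integers(0, 2)))),
                )
            )
        if rng.random() < 0.25:
            end = _rand_date(rng) if rng.random() < 0.3 else None
            start = _rand_date(rng)
            if end is not None and end < start:
                start, end = end, start
            bundle.ter.append(
                ExemptionRecord(
                    person=person,
                    code=str(rng.choice(_TER_POOL)),
                    start_date=start,
                    end_date=end,
                )
            )
        for _ in range(rng.integers(0, 4)):
            bundle.ossis.append(
                OutpatientRecord(
                    person=person,
                    service_date=_rand_date(rng),
                    service_code=str(rng.choice(_OSSIS_POOL)),
                    branch=rng.choice(np.array(_BRANCH_POOL, dtype=object)),
                )
            )
        for _ in range(rng.integers(0, 2)):
            bundle.pharm.append(
                DrugRecord(
                    person=person,
                    dispensing_date=_rand_date(rng),
                    atc=str(rng.choice(_ATC_POOL)),
                )
            )
    return bundle
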