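"""Code catalogue, normalization and wildcard matching.

Case ascertainment is driven entirely by published code lists: ICD-9-CM
diagnoses and procedures on hospital abstracts, regional outpatient
service codes, ticket-exemption codes and ATC drug codes.  Codes are
compared after normalization (dots and whitespace stripped, uppercased),
so ``585.4`` and ``5854`` are the same code.  A trailing run of ``X``
characters in a catalogue pattern is a wildcard: ``585.XX`` matches any
code extending the stem ``585`` — including the bare three-digit stem,
because ICD-9-CM allows codes with no fourth digit.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Union

import yaml


class CodeSystem(str, enum.Enum):
    ICD9_DX = "icd9_dx"
    ICD9_PROC = "icd9_proc"
    REGIONAL_SERVICE = "regional_service"
    EXEMPTION = "exemption"
    ATC = "atc"


def normalize_code(raw: str, system: Union[CodeSystem, str]) -> str:
    """Canonical spelling of a code: no dots, no whitespace, uppercase.

    Idempotent; raises ``ValueError`` on an empty code.  The ``system``
    argument validates intent (all systems currently normalize the same
    way).
    """
    CodeSystem(system)
    normalized = raw.strip().replace(".", "").replace(" ", "").upper()
    if not normalized:
        raise ValueError("empty code")
    return normalized


@dataclass(frozen=True, order=True)
class CodePattern:
    """A normalized catalogue entry, possibly wildcard-suffixed.

    ``pattern`` ends in zero or more ``X`` characters; the stem before
    the wildcard run is matched as a prefix, an empty run means exact
    equality.
    """

    system: CodeSystem
    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "system", CodeSystem(self.system))
        if not self.pattern:
            raise ValueError("empty pattern")
        if "X" in self.stem and self.system is not CodeSystem.ATC:
            raise ValueError(f"wildcard allowed only as suffix: {self.pattern!r}")

    @property
    def stem(self) -> str:
        return self.pattern.rstrip("X")

    @property
    def is_wildcard(self) -> bool:
        return self.pattern != self.stem


def matches(code: str, pattern: CodePattern) -> bool:
    """True iff a normalized ``code`` matches a catalogue ``pattern``.

    A wildcard pattern matches any (possibly empty) extension of its
    stem; a plain pattern requires exact equality.
    """
    if pattern.is_wildcard:
        return code.startswith(pattern.stem)
    return code == pattern.pattern


def any_match(code: str, patterns: Iterable[CodePattern]) -> bool:
    """True iff ``code`` matches at least one pattern in the set."""
    return any(matches(code, p) for p in patterns)


def _patterns(system: CodeSystem, raw_codes: Iterable[str]) -> frozenset[CodePattern]:
    return frozenset(
        CodePattern(system, normalize_code(raw, system)) for raw in raw_codes
    )


@dataclass(frozen=True)
class CodeCatalog:
    """The full published code catalogue, as named pattern sets.

    ``hdr_*`` sets apply to hospital discharge abstracts, ``ter_codes``
    to exemptions, ``ossis_*`` to outpatient services, ``pharm_atc`` to
    dispensings.  ``severity_dx_codes`` (CKD stage IV or worse),
    ``dialysis_procedure_codes`` and ``transplant_*`` feed the severity
    classifier rather than case finding.
    """

    hdr_diagnoses: frozenset[CodePattern]
    hdr_procedures: frozenset[CodePattern]
    hdr_complex_services: frozenset[CodePattern]
    ter_codes: frozenset[CodePattern]
    ossis_visit_codes: frozenset[CodePattern]
    ossis_albumin_code: frozenset[CodePattern]
    ossis_dialysis_service_codes: frozenset[CodePattern]
    pharm_atc: frozenset[CodePattern]
    severity_dx_codes: frozenset[CodePattern]
    dialysis_procedure_codes: frozenset[CodePattern]
    transplant_procedure_codes: frozenset[CodePattern]
    transplant_dx_codes: frozenset[CodePattern]
    transplant_ter_codes: frozenset[CodePattern]
    transplant_service_codes: frozenset[CodePattern]
    acute_renal_failure_dx: frozenset[CodePattern]
    acute_exclusion_procedures: frozenset[CodePattern]
    nephrology_branch: str = "29"

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "nephrology_branch":
                continue
            if not value:
                raise ValueError(f"code set {f.name} must be non-empty")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "nephrology_branch":
                out[f.name] = value
            else:
                out[f.name] = {
                    "system": next(iter(value)).system.value,
                    "codes": sorted(p.pattern for p in value),
                }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "CodeCatalog":
        kwargs = {}
        for key, value in data.items():
            if key == "nephrology_branch":
                kwargs[key] = str(value)
            else:
                kwargs[key] = _patterns(CodeSystem(value["system"]), value["codes"])
        return cls(**kwargs)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CodeCatalog":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def checksum(self) -> str:
        """SHA-256 of the canonical serialization; freezes the content."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def default_catalog() -> CodeCatalog:
    """The shipped catalogue used by the published ascertainment rules."""
    dx = CodeSystem.ICD9_DX
    proc = CodeSystem.ICD9_PROC
    svc = CodeSystem.REGIONAL_SERVICE
    return CodeCatalog(
        # hospital discharge diagnoses (primary or secondary)
        hdr_diagnoses=_patterns(dx, [
            "250.4X",   # diabetes with renal manifestations
            "403.XX",   # hypertensive chronic kidney disease
            "404.XX",   # hypertensive heart and chronic kidney disease
            "582.XX",   # chronic glomerulonephritis
            "583.XX",   # nephritis/nephropathy, not specified acute or chronic
            "585.XX",   # chronic kidney disease
            "586.XX",   # renal failure, unspecified
            "587.XX",   # renal sclerosis, unspecified
            "588.XX",   # disorders from impaired renal function
            "753.1X",   # cystic kidney disease
            "590.0X",   # chronic pyelonephritis
            "V56.X",    # encounter for dialysis and dialysis catheter care
            "V42.0",    # kidney replaced by transplant
        ]),
        # hospital procedures
        hdr_procedures=_patterns(proc, [
            "39.95",    # hemodialysis
            "54.98",    # peritoneal dialysis
            "55.6X",    # transplant of kidney
            "39.27",    # arteriovenostomy for renal dialysis
            "54.93",    # creation of cutaneoperitoneal fistula
            "39.42",    # revision of arteriovenous shunt for renal dialysis
            "39.43",    # removal of arteriovenous shunt for renal dialysis
            "38.95",    # venous catheterization for renal dialysis
            "55.23",    # closed percutaneous biopsy of kidney
        ]),
        # complex outpatient packages recorded alongside hospital data
        hdr_complex_services=_patterns(svc, [
            "P583",     # assess diagnosis of nephropathies
            "P585A",    # assess chronic kidney disease
            "P585B",    # assess kidney transplant
            "PV420",    # follow-up of kidney transplant patient
        ]),
        # co-pay exemptions
        ter_codes=_patterns(CodeSystem.EXEMPTION, [
            "025.585",    # chronic kidney disease
            "025.V42.0",  # kidney transplantation
        ]),
        # nephrology visits (branch-qualified) and albumin measurement
        ossis_visit_codes=_patterns(svc, [
            "89.7",     # first ambulatory specialist visit (nephrology)
            "89.01",    # ambulatory specialist visit (nephrology)
            "89.03",    # definition of dialysis scheme (nephrology)
        ]),
        ossis_albumin_code=_patterns(svc, ["90.33.4"]),
        # dialysis-related outpatient services
        ossis_dialysis_service_codes=_patterns(svc, [
            "39.95.X",  # hemodialysis or hemodiafiltration
            "54.98.X",  # peritoneal dialysis
            "38.95",    # venous catheterization for renal dialysis
            "54.93",    # creation of cutaneoperitoneal fistula
            "39.99.1",  # debriding of peritoneal catheter
            "97.82",    # removal of peritoneal catheter
            "97.29.1",  # revision of peritoneal catheter
        ]),
        # dispensed drugs reserved for advanced CKD
        pharm_atc=_patterns(CodeSystem.ATC, [
            "B03XA01",  # erythropoietin
            "B03XA02",  # darbepoetin alfa
            "B03XA03",  # methoxy polyethylene glycol-epoetin beta
            "V03AE01",  # polystyrene sulfonate
            "V03AE02",  # sevelamer
            "V03AE03",  # lanthanum carbonate
            "V03AE05",  # sucroferric oxyhydroxide
        ]),
        # CKD stage IV or greater
        severity_dx_codes=_patterns(dx, ["585.4X", "585.5X", "585.6X"]),
        # dialysis and dialysis-access procedures (biopsy 55.23 excluded:
        # it qualifies a case but is not severity evidence)
        dialysis_procedure_codes=_patterns(proc, [
            "39.95", "54.98", "39.27", "54.93", "39.42", "39.43", "38.95",
        ]),
        transplant_procedure_codes=_patterns(proc, ["55.6X"]),
        transplant_dx_codes=_patterns(dx, ["V42.0"]),
        transplant_ter_codes=_patterns(CodeSystem.EXEMPTION, ["025.V42.0"]),
        transplant_service_codes=_patterns(svc, ["P585B", "PV420"]),
        # acute renal failure, used only by the exclusion rule
        acute_renal_failure_dx=_patterns(dx, ["584.XX"]),
        # records whose only qualifying evidence is one of these two
        # procedures are dropped when an acute-failure diagnosis co-occurs
        acute_exclusion_procedures=_patterns(proc, ["39.95", "38.95"]),
    )
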