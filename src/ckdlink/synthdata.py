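"""Synthetic registries with plantable ground truth.

The real regional databases are not public, so every pipeline stage is
exercised on generated data: a resident population with a configurable
age/sex structure, per-stratum CKD prevalence, a higher-severity
fraction among cases, per-source emission probabilities, and explicit
noise channels (acute-renal-failure admissions, unconfirmed single
visits, deaths and emigrations of planted cases, background records,
and planted dialysis false positives/negatives).  The generator
records for every person whether it is a case, its severity tier,
dialysis status and any exclusion reason, so the pipeline's output can
be checked against planted truth exactly.

Generation is deterministic given the seed; every person draws from
its own substream keyed by ``(seed, person_index)``, so enlarging the
population never reshuffles existing persons.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .casefinder import DEFAULT_WINDOW, StudyWindow
from .registry_io import (
    Demographics,
    DialysisModality,
    DialysisRegistryRecord,
    DrugRecord,
    ExemptionRecord,
    HospitalRecord,
    OutpatientRecord,
    PersonID,
    RecordBundle,
    write_bundle,
)

Date = datetime.date

# --------------------------------------------------------------------------
# published stratum grid (cases, population) per (age class, sex), used as
# arithmetic fixture and as the default demographic/prevalence shape

_TABLE2_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("0-18", "male"): (1_604, 490_339),
    ("19-44", "male"): (2_791, 851_677),
    ("45-64", "male"): (10_511, 826_673),
    ("65-74", "male"): (13_302, 281_274),
    ("75-84", "male"): (18_746, 189_776),
    ("85+", "male"): (8_578, 60_502),
    ("0-18", "female"): (1_163, 461_531),
    ("19-44", "female"): (2_487, 866_373),
    ("45-64", "female"): (7_346, 900_610),
    ("65-74", "female"): (8_474, 327_045),
    ("75-84", "female"): (14_381, 257_535),
    ("85+", "female"): (10_074, 123_175),
}

#: Published exclusive-source contribution counts among all identified
#: cases, and among the higher-severity subset.
SOURCE_COUNTS = {
    "total": 99_457,
    "exclusive": {"OSSIS": 35_047, "HDR": 27_778, "TER": 4_143, "PHARM": 463},
}
HIGHER_SEVERITY_COUNTS = {
    "total": 21_159,
    "exclusive": {"OSSIS": 116, "HDR": 2_400, "TER": 219, "PHARM": 463},
}


def table2_fixture() -> pd.DataFrame:
    """The published age x sex stratum grid as a tidy frame.

    Columns ``age_class, sex, cases, population``; one row per stratum.
    Lets the rate arithmetic be exercised without person-level data.
    """
    rows = [
        {"age_class": label, "sex": sex, "cases": c, "population": n}
        for (label, sex), (c, n) in _TABLE2_COUNTS.items()
    ]
    return pd.DataFrame(rows)


def table2_counts() -> dict[tuple[str, str], tuple[int, int]]:
    """The same grid as a ``(age_class, sex) -> (cases, population)`` map."""
    return dict(_TABLE2_COUNTS)


# --------------------------------------------------------------------------
# configuration

_AGE_BOUNDS = {
    "0-18": (0, 18),
    "19-44": (19, 44),
    "45-64": (45, 64),
    "65-74": (65, 74),
    "75-84": (75, 84),
    "85+": (85, 99),
}


def _default_structure() -> dict[tuple[str, str], float]:
    total = sum(n for _, n in _TABLE2_COUNTS.values())
    return {k: n / total for k, (_, n) in _TABLE2_COUNTS.items()}


def _default_prevalence() -> dict[tuple[str, str], float]:
    return {k: c / n for k, (c, n) in _TABLE2_COUNTS.items()}


@dataclass(frozen=True)
class NoiseConfig:
    """Rates of the perturbation channels; all off by default.

    * ``arf_admission_rate`` — non-cases get an acute-renal-failure
      admission (diagnosis 584.9 with procedure 39.95 only) that the
      exclusion rule must absorb.
    * ``single_visit_rate`` — non-cases get one unconfirmed nephrology
      visit, below every inclusion threshold.
    * ``case_death_rate`` / ``case_emigration_rate`` — planted cases
      die before, or move away by, the prevalence date and must drop
      from the cohort.
    * ``background_record_rate`` — persons get non-qualifying hospital,
      outpatient and dispensing records.
    * ``dialysis_false_positive_rate`` — non-cases get a dialysis-
      related outpatient service without a registry entry (they become
      algorithm dialysis cases but stay out of the gold standard).
    * ``dialysis_false_negative_rate`` — planted dialysis patients
      lose their algorithm-detectable dialysis records (a qualifying
      exemption keeps them in the cohort) while keeping their registry
      entry.
    """

    arf_admission_rate: float = 0.0
    single_visit_rate: float = 0.0
    case_death_rate: float = 0.0
    case_emigration_rate: float = 0.0
    background_record_rate: float = 0.0
    dialysis_false_positive_rate: float = 0.0
    dialysis_false_negative_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"noise rate {name} must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic-registry draw.

    Defaults follow the published study's shape: the age/sex structure
    and per-stratum prevalence mirror the regional stratum grid, about
    a fifth of cases are higher severity, and cases emit qualifying
    records in several sources.  Drug dispensings are emitted only for
    higher-severity cases, because a qualifying dispensing is itself a
    higher-severity criterion.
    """

    n_persons: int = 10_000
    seed: int = 0
    window: StudyWindow = DEFAULT_WINDOW
    age_sex_structure: Mapping[tuple[str, str], float] = field(
        default_factory=_default_structure
    )
    prevalence_by_stratum: Mapping[tuple[str, str], float] = field(
        default_factory=_default_prevalence
    )
    higher_severity_fraction: float = 0.213
    dialysis_fraction_of_higher: float = 0.30
    source_profile: Mapping[str, float] = field(
        default_factory=lambda: {"HDR": 0.55, "TER": 0.15, "OSSIS": 0.70, "PHARM": 0.35}
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        for prob in self.prevalence_by_stratum.values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError("stratum prevalence must be in [0, 1]")
        for prob in list(self.age_sex_structure.values()) + list(
            self.source_profile.values()
        ) + [self.higher_severity_fraction, self.dialysis_fraction_of_higher]:
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.age_sex_structure.values()) - 1.0) > 1e-9:
            raise ValueError("age_sex_structure must sum to 1")


# --------------------------------------------------------------------------
# ground truth

@dataclass
class PersonTruth:
    person: PersonID
    is_case: bool
    severity: Optional[str] = None  # "higher"/"lower", cases only
    on_dialysis: bool = False
    excluded_reason: Optional[str] = None  # None / "death" / "emigration"

    def __post_init__(self) -> None:
        if self.on_dialysis and self.severity != "higher":
            raise ValueError("dialysis implies higher severity")
        if self.severity is not None and not self.is_case:
            raise ValueError("severity defined only for cases")


@dataclass
class GroundTruth:
    """Planted truth for every generated person, plus the identities of
    injected dialysis classification errors."""

    truths: dict[PersonID, PersonTruth]
    dialysis_fp_ids: set[PersonID] = field(default_factory=set)
    dialysis_fn_ids: set[PersonID] = field(default_factory=set)

    def surviving_case_ids(self) -> set[PersonID]:
        """Planted cases not removed by death or emigration."""
        return {
            p for p, t in self.truths.items() if t.is_case and t.excluded_reason is None
        }

    def expected_cohort_ids(self) -> set[PersonID]:
        """What the pipeline should identify: surviving planted cases
        plus injected dialysis false positives."""
        return self.surviving_case_ids() | self.dialysis_fp_ids

    def expected_severity(self) -> dict[PersonID, str]:
        return {
            p: self.truths[p].severity for p in self.surviving_case_ids()
        } | {p: "higher" for p in self.dialysis_fp_ids}

    def expected_algorithm_dialysis_ids(self) -> set[PersonID]:
        surviving = {
            p for p in self.surviving_case_ids() if self.truths[p].on_dialysis
        }
        return (surviving - self.dialysis_fn_ids) | self.dialysis_fp_ids

    def expected_registry_ids(self) -> set[PersonID]:
        return {p for p in self.surviving_case_ids() if self.truths[p].on_dialysis}


@dataclass
class SimOutput:
    bundle: RecordBundle
    truth: GroundTruth
    config: SimConfig

    @property
    def demographics(self) -> list[Demographics]:
        return self.bundle.demographics

    def write(self, outdir: Union[str, Path]) -> None:
        """Write the six registry CSVs plus ``ground_truth.csv``."""
        outdir = Path(outdir)
        write_bundle(self.bundle, outdir)
        with open(outdir / "ground_truth.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["person_id", "is_case", "severity", "on_dialysis", "excluded_reason"]
            )
            for person in sorted(self.truth.truths):
                t = self.truth.truths[person]
                writer.writerow([
                    person.value,
                    int(t.is_case),
                    t.severity or "",
                    int(t.on_dialysis),
                    t.excluded_reason or "",
                ])


# --------------------------------------------------------------------------
# generation

def _person_rng(seed: int, index: int, channel: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, channel, index])


def _random_date(rng: np.random.Generator, start: Date, end: Date) -> Date:
    span = (end - start).days
    return start + datetime.timedelta(days=int(rng.integers(span + 1)))


def _birth_date_for_age(rng: np.random.Generator, age: int, reference: Date) -> Date:
    # any birth date in (reference - (age+1) years, reference - age years]
    hi = reference.replace(year=reference.year - age)
    lo = reference.replace(year=reference.year - age - 1) + datetime.timedelta(days=1)
    return _random_date(rng, lo, hi)


def generate(config: SimConfig) -> SimOutput:
    """Draw a full synthetic registry set with planted ground truth.

    Every planted case emits at least one record pattern per source in
    its drawn source set that satisfies the corresponding inclusion
    rule; non-cases emit nothing in the base output (noise channels
    add their records separately via :func:`noise_channels`).
    """
    window = config.window
    prevalence_date = window.prevalence_date
    strata = sorted(config.age_sex_structure)
    probs = np.array([config.age_sex_structure[s] for s in strata], dtype=float)
    probs = probs / probs.sum()

    bundle = RecordBundle()
    truths: dict[PersonID, PersonTruth] = {}

    for i in range(config.n_persons):
        rng = _person_rng(config.seed, i)
        person = PersonID(f"P{i:07d}")
        label, sex = strata[int(rng.choice(len(strata), p=probs))]
        low, high = _AGE_BOUNDS[label]
        age = int(rng.integers(low, high + 1))
        birth = _birth_date_for_age(rng, age, prevalence_date)
        bundle.demographics.append(
            Demographics(
                person=person,
                sex=sex,
                birth_date=birth,
                residence_intervals=((birth, None),),
            )
        )

        is_case = bool(rng.random() < config.prevalence_by_stratum.get((label, sex), 0.0))
        if not is_case:
            truths[person] = PersonTruth(person, is_case=False)
            continue

        higher = bool(rng.random() < config.higher_severity_fraction)
        on_dialysis = higher and bool(
            rng.random() < config.dialysis_fraction_of_higher
        )
        truths[person] = PersonTruth(
            person,
            is_case=True,
            severity="higher" if higher else "lower",
            on_dialysis=on_dialysis,
        )

        sources = {
            s for s, prob in sorted(config.source_profile.items()) if rng.random() < prob
        }
        if not higher:
            sources.discard("PHARM")  # a qualifying dispensing implies higher severity
        if on_dialysis:
            sources.add("OSSIS")
        if not sources:
            sources = {"OSSIS"}

        needs_severity_evidence = higher and not on_dialysis

        if "HDR" in sources:
            if needs_severity_evidence:
                dx = str(rng.choice(["585.4", "585.5", "585.6"]))
                needs_severity_evidence = False
            else:
                dx = str(rng.choice(["585.3", "585.9", "582.9", "403.90"]))
            admission = _random_date(rng, window.start, window.end)
            discharge = min(
                admission + datetime.timedelta(days=int(rng.integers(1, 15))), window.end
            )
            bundle.hdr.append(
                HospitalRecord(
                    person=person,
                    admission_date=admission,
                    discharge_date=discharge,
                    diagnoses=(dx, "401.9"),
                )
            )
        if "TER" in sources:
            code = "025.585"
            if needs_severity_evidence:
                code = "025.V42.0"  # transplant exemption doubles as severity evidence
                needs_severity_evidence = False
            bundle.ter.append(
                ExemptionRecord(
                    person=person,
                    code=code,
                    start_date=_random_date(rng, window.start, prevalence_date),
                )
            )
        if "OSSIS" in sources:
            if on_dialysis:
                bundle.ossis.append(
                    OutpatientRecord(
                        person=person,
                        service_date=_random_date(rng, window.start, window.end),
                        service_code="39.95.1",
                    )
                )
            else:
                first = _random_date(
                    rng, window.start, window.end - datetime.timedelta(days=30)
                )
                second = first + datetime.timedelta(days=int(rng.integers(1, 30)))
                bundle.ossis.append(
                    OutpatientRecord(person, first, "89.7", branch="29")
                )
                if rng.random() < 0.5:
                    bundle.ossis.append(
                        OutpatientRecord(person, second, "89.7", branch="29")
                    )
                else:
                    bundle.ossis.append(OutpatientRecord(person, second, "90.33.4"))
        if "PHARM" in sources or needs_severity_evidence:
            atc = str(rng.choice(["B03XA01", "B03XA02", "V03AE02"]))
            bundle.pharm.append(
                DrugRecord(
                    person=person,
                    dispensing_date=_random_date(rng, window.start, window.end),
                    atc=atc,
                )
            )
            needs_severity_evidence = False
        if on_dialysis:
            bundle.ldr.append(
                DialysisRegistryRecord(
                    person=person,
                    start_date=_random_date(rng, window.start, window.end),
                    modality=DialysisModality(
                        str(rng.choice(["hemodialysis", "peritoneal"]))
                    ),
                )
            )

    output = SimOutput(bundle=bundle, truth=GroundTruth(truths=truths), config=config)
    if any(
        getattr(config.noise, f) > 0.0 for f in config.noise.__dataclass_fields__
    ):
        output = noise_channels(config, output)
    return output


# --------------------------------------------------------------------------
# noise channels

def noise_channels(config: SimConfig, base: SimOutput) -> SimOutput:
    """Apply the configured perturbation channels to a base draw.

    With all rates zero the output equals the base.  Ground truth is
    updated so that killed/emigrated cases carry an exclusion reason
    and injected dialysis errors are listed.
    """
    noise = config.noise
    window = config.window
    prevalence_date = window.prevalence_date
    bundle = RecordBundle(
        demographics=list(base.bundle.demographics),
        hdr=list(base.bundle.hdr),
        ter=list(base.bundle.ter),
        ossis=list(base.bundle.ossis),
        pharm=list(base.bundle.pharm),
        ldr=list(base.bundle.ldr),
    )
    truths = {p: replace(t) for p, t in base.truth.truths.items()}
    fp_ids = set(base.truth.dialysis_fp_ids)
    fn_ids = set(base.truth.dialysis_fn_ids)

    demo_pos = {d.person: i for i, d in enumerate(bundle.demographics)}
    removed_dialysis: set[PersonID] = set()

    for i, demo in enumerate(list(base.bundle.demographics)):
        person = demo.person
        truth = truths[person]
        rng = _person_rng(config.seed, i, channel=1)

        if not truth.is_case:
            if rng.random() < noise.arf_admission_rate:
                admission = _random_date(rng, window.start, window.end)
                bundle.hdr.append(
                    HospitalRecord(
                        person=person,
                        admission_date=admission,
                        discharge_date=admission + datetime.timedelta(days=3),
                        diagnoses=("584.9",),
                        procedures=("39.95",),
                    )
                )
            if rng.random() < noise.single_visit_rate:
                bundle.ossis.append(
                    OutpatientRecord(
                        person, _random_date(rng, window.start, window.end),
                        "89.7", branch="29",
                    )
                )
            if rng.random() < noise.dialysis_false_positive_rate:
                bundle.ossis.append(
                    OutpatientRecord(
                        person, _random_date(rng, window.start, window.end), "39.95.1",
                    )
                )
                fp_ids.add(person)
        else:
            if truth.excluded_reason is None and rng.random() < noise.case_death_rate:
                death = _random_date(
                    rng, window.start + datetime.timedelta(days=30), prevalence_date
                )
                bundle.demographics[demo_pos[person]] = Demographics(
                    person=person,
                    sex=demo.sex,
                    birth_date=demo.birth_date,
                    death_date=max(death, demo.birth_date),
                    residence_intervals=demo.residence_intervals,
                )
                truth.excluded_reason = "death"
            elif (
                truth.excluded_reason is None
                and rng.random() < noise.case_emigration_rate
            ):
                moved = _random_date(
                    rng, window.start + datetime.timedelta(days=30), prevalence_date
                )
                moved = max(moved, demo.birth_date + datetime.timedelta(days=1))
                bundle.demographics[demo_pos[person]] = Demographics(
                    person=person,
                    sex=demo.sex,
                    birth_date=demo.birth_date,
                    residence_intervals=((demo.birth_date, moved),),
                )
                truth.excluded_reason = "emigration"
            if (
                truth.on_dialysis
                and truth.excluded_reason is None
                and rng.random() < noise.dialysis_false_negative_rate
            ):
                removed_dialysis.add(person)
                fn_ids.add(person)

        if rng.random() < noise.background_record_rate:
            service_date = _random_date(rng, window.start, window.end)
            bundle.ossis.append(
                OutpatientRecord(person, service_date, "90.44.1", branch="08")
            )
            bundle.pharm.append(
                DrugRecord(person, service_date, "C09AA05")
            )

    if removed_dialysis:
        bundle.ossis = [
            r
            for r in bundle.ossis
            if not (
                r.person in removed_dialysis
                and r.service_code.replace(".", "").startswith("3995")
            )
        ]
        bundle.hdr = [
            r
            for r in bundle.hdr
            if not (
                r.person in removed_dialysis
                and any(p.replace(".", "") in ("3995", "5498", "3895") for p in r.procedures)
            )
        ]
        # keep the degraded patients ascertainable as cases (but not as
        # dialysis-treated) via an exemption
        for person in sorted(removed_dialysis):
            bundle.ter.append(
                ExemptionRecord(
                    person=person, code="025.585", start_date=window.start,
                )
            )

    return SimOutput(
        bundle=bundle,
        truth=GroundTruth(truths=truths, dialysis_fp_ids=fp_ids, dialysis_fn_ids=fn_ids),
        config=config,
    )
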