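"""Validation of dialysis ascertainment against a gold-standard registry.

The dialysis registry enrolls every chronic dialysis patient in the
region, so it serves as ground truth for the subset of identified
cases that the algorithm flags as dialysis-treated.  Both sets are
restricted to persons alive and resident at the prevalence date; the
2x2 confusion matrix over the resident population yields sensitivity,
specificity, and positive/negative predictive values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Set

from .casefinder import CaseRecord, DEFAULT_WINDOW, StudyWindow
from .codelists import CodeCatalog
from .registry_io import (
    Demographics,
    DialysisRegistryRecord,
    PersonID,
    RecordBundle,
    resident_at,
)
from .severity import EvidenceKind, SeverityIndex
from .utils import round_half_away


@dataclass(frozen=True)
class ValidationResult:
    """Confusion counts and derived metrics, in percent.

    Metrics are rounded half-away-from-zero to one decimal.  A metric
    whose denominator is zero (e.g. PPV with an empty algorithm set)
    is ``None`` — reported as not-applicable, never as 0 or 100.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def _metric(numerator: int, denominator: int) -> Optional[float]:
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, 1)


def algorithm_dialysis_set(
    cases: Sequence[CaseRecord],
    bundle: RecordBundle,
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
) -> set[PersonID]:
    """Identified cases carrying dialysis evidence.

    Dialysis evidence is a dialysis or dialysis-access hospital
    procedure on a non-excluded discharge, or a dialysis-related
    outpatient service, inside the window — the same criterion the
    severity classifier uses.
    """
    index = SeverityIndex(bundle, catalog, window)
    out = set()
    for case in cases:
        if any(e.kind is EvidenceKind.DIALYSIS for e in index.evidence_for(case.person)):
            out.add(case.person)
    return out


def registry_gold_set(
    ldr: Sequence[DialysisRegistryRecord],
    demographics: Sequence[Demographics],
    window: StudyWindow = DEFAULT_WINDOW,
) -> set[PersonID]:
    """Gold-standard dialysis patients: registry entries started on or
    before the window end, alive and resident at the prevalence date."""
    demo_index = {d.person: d for d in demographics}
    prevalence_date = window.prevalence_date
    out = set()
    for record in ldr:
        if record.start_date > window.end:
            continue
        demo = demo_index.get(record.person)
        if demo is None:
            continue
        if demo.death_date is not None and demo.death_date <= prevalence_date:
            continue
        if not resident_at(demo, prevalence_date):
            continue
        out.add(record.person)
    return out


def confusion(
    algorithm_set: Set[PersonID],
    registry_set: Set[PersonID],
    population: Set[PersonID],
) -> ValidationResult:
    """2x2 confusion matrix of the algorithm against the gold standard.

    ``population`` is the true-negative denominator — by default the
    full resident-alive population, which is what gives specificity
    its region-wide meaning for a rare treatment; pass the cohort
    instead for a cohort-restricted reading.  Both sets must be
    subsets of the population.
    """
    algorithm_set = set(algorithm_set)
    registry_set = set(registry_set)
    population = set(population)
    stray = (algorithm_set | registry_set) - population
    if stray:
        raise ValueError(
            f"{len(stray)} person(s) outside the population: "
            + ", ".join(sorted(p.value for p in stray)[:10])
        )
    tp = len(algorithm_set & registry_set)
    fp = len(algorithm_set - registry_set)
    fn = len(registry_set - algorithm_set)
    tn = len(population) - tp - fp - fn
    return ValidationResult(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_metric(tp, tp + fn),
        specificity=_metric(tn, tn + fp),
        ppv=_metric(tp, tp + fp),
        npv=_metric(tn, tn + fn),
    )


def validate_dialysis(
    cases: Sequence[CaseRecord],
    bundle: RecordBundle,
    catalog: CodeCatalog,
    window: StudyWindow = DEFAULT_WINDOW,
    denominator: str = "population",
) -> ValidationResult:
    """End-to-end dialysis validation from a resolved cohort and bundle.

    ``denominator`` selects the true-negative base: ``"population"``
    (all persons alive and resident at the prevalence date) or
    ``"cohort"`` (identified cases only).
    """
    algorithm = algorithm_dialysis_set(cases, bundle, catalog, window)
    registry = registry_gold_set(bundle.ldr, bundle.demographics, window)
    prevalence_date = window.prevalence_date
    if denominator == "population":
        base = {
            d.person
            for d in bundle.demographics
            if (d.death_date is None or d.death_date > prevalence_date)
            and resident_at(d, prevalence_date)
        }
    elif denominator == "cohort":
        base = {c.person for c in cases} | registry
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return confusion(algorithm, registry, base)
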