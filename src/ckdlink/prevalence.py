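"""Crude, stratified and directly standardized prevalence rates.

Prevalence is reported per 100 population: identified cases alive and
resident at the prevalence date, divided by the resident population on
that date, within age-class x sex strata (default classes 0-18, 19-44,
45-64, 65-74, 75-84, 85+).  Confidence intervals use the Wald normal
approximation on the binomial proportion by default — adequate in the
large-denominator regime of regional registries — with Clopper-Pearson
available for small strata.  Direct standardization re-weights stratum
rates by an external reference population (e.g. the national resident
population) normalized within the margin being standardized.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .registry_io import Demographics, PersonID, resident_at
from .utils import round_half_away

Date = datetime.date


# --------------------------------------------------------------------------
# ages and age classes

def age_at(birth_date: Date, reference_date: Date) -> int:
    """Completed years of age at ``reference_date``.

    A birthday not yet reached in the reference year subtracts one;
    February 29 birthdays complete their year on March 1 in common
    years.
    """
    if birth_date > reference_date:
        raise ValueError("birth_date after reference_date")
    years = reference_date.year - birth_date.year
    if (reference_date.month, reference_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


@dataclass(frozen=True)
class AgeClass:
    """Closed age interval in completed years; ``high=None`` is open-ended."""

    label: str
    low: int
    high: Optional[int]

    def contains(self, age: int) -> bool:
        return age >= self.low and (self.high is None or age <= self.high)


DEFAULT_AGE_CLASSES: tuple[AgeClass, ...] = (
    AgeClass("0-18", 0, 18),
    AgeClass("19-44", 19, 44),
    AgeClass("45-64", 45, 64),
    AgeClass("65-74", 65, 74),
    AgeClass("75-84", 75, 84),
    AgeClass("85+", 85, None),
)


def age_class_of(age: int, classes: Sequence[AgeClass] = DEFAULT_AGE_CLASSES) -> AgeClass:
    for cls in classes:
        if cls.contains(age):
            return cls
    raise ValueError(f"age {age} not covered by the age-class partition")


# --------------------------------------------------------------------------
# rates

@dataclass(frozen=True)
class RateEstimate:
    """A prevalence rate per 100 with its 95% confidence interval."""

    rate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.rate <= self.ci_high <= 100.0):
            raise ValueError(
                f"need 0 <= ci_low <= rate <= ci_high <= 100, got "
                f"({self.ci_low}, {self.rate}, {self.ci_high})"
            )

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_away(self.rate, ndigits),
            round_half_away(self.ci_low, ndigits),
            round_half_away(self.ci_high, ndigits),
        )


def crude_rate(
    cases: int,
    population: int,
    ci_method: str = "wald",
    alpha: float = 0.05,
) -> RateEstimate:
    """Prevalence per 100 with a binomial confidence interval.

    ``ci_method`` is ``"wald"`` (normal approximation on the
    proportion) or ``"clopper-pearson"`` (exact).  Wald bounds are
    clipped to [0, 100].
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= cases <= population:
        raise ValueError("need 0 <= cases <= population")
    p = cases / population
    if ci_method == "wald":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(p * (1 - p) / population)
        low, high = max(0.0, p - half), min(1.0, p + half)
    elif ci_method == "clopper-pearson":
        low = stats.beta.ppf(alpha / 2, cases, population - cases + 1) if cases > 0 else 0.0
        high = (
            stats.beta.ppf(1 - alpha / 2, cases + 1, population - cases)
            if cases < population else 1.0
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RateEstimate(100.0 * p, 100.0 * low, 100.0 * high)


@dataclass(frozen=True)
class Stratum:
    """Cases and population of one age-class x sex cell."""

    age_class: AgeClass
    sex: str
    cases: int
    population: int

    def __post_init__(self) -> None:
        if not 0 <= self.cases <= self.population:
            raise ValueError("need 0 <= cases <= population in each stratum")


def rate_ratio(rate_m: float, rate_f: float, ndigits: int = 2) -> float:
    """Male:female rate ratio, rounded half-away-from-zero."""
    if rate_f <= 0:
        raise ValueError("female rate must be positive")
    return round_half_away(rate_m / rate_f, ndigits)


# --------------------------------------------------------------------------
# the stratified prevalence table

def strata_from_counts(
    counts: Mapping[tuple[str, str], tuple[int, int]],
    classes: Sequence[AgeClass] = DEFAULT_AGE_CLASSES,
) -> list[Stratum]:
    """Build strata from a ``(age_class_label, sex) -> (cases, population)``
    mapping (e.g. a published table)."""
    by_label = {c.label: c for c in classes}
    return [
        Stratum(by_label[label], sex, c, n)
        for (label, sex), (c, n) in sorted(counts.items())
    ]


def count_strata(
    cases: Sequence["PersonID"],
    demographics: Sequence[Demographics],
    prevalence_date: Date,
    classes: Sequence[AgeClass] = DEFAULT_AGE_CLASSES,
) -> list[Stratum]:
    """Tally cases and resident-alive population per age-class x sex.

    The denominator is every person in demographics alive and resident
    at the prevalence date; every case person must appear there.
    """
    case_ids = set(cases)
    demo_index = {d.person for d in demographics}
    missing = sorted(p.value for p in case_ids - demo_index)
    if missing:
        raise KeyError(f"case person(s) missing from demographics: {missing[:10]}")

    counts: dict[tuple[str, str], list[int]] = {
        (cls.label, sex): [0, 0] for cls in classes for sex in ("male", "female")
    }
    for demo in demographics:
        if demo.death_date is not None and demo.death_date <= prevalence_date:
            continue
        if not resident_at(demo, prevalence_date):
            continue
        label = age_class_of(age_at(demo.birth_date, prevalence_date), classes).label
        cell = counts[(label, demo.sex)]
        cell[1] += 1
        if demo.person in case_ids:
            cell[0] += 1
    return strata_from_counts({k: tuple(v) for k, v in counts.items()}, classes)


def prevalence_table(
    strata: Sequence[Stratum],
    ci_method: str = "wald",
    classes: Sequence[AgeClass] = DEFAULT_AGE_CLASSES,
) -> pd.DataFrame:
    """Assemble the full age x sex prevalence table.

    One row per age class plus a ``total`` row; for each sex and for
    both combined: cases, population, prevalence per 100 and its 95%
    CI; plus the male:female rate ratio.  Rates are unrounded — use
    :func:`format_table` for display at the conventional precision.
    """
    cell = {(s.age_class.label, s.sex): s for s in strata}
    labels = [c.label for c in classes]
    rows = []
    totals = {"male": [0, 0], "female": [0, 0]}
    for label in labels:
        row: dict = {"age_class": label}
        both = [0, 0]
        for sex in ("male", "female"):
            s = cell.get((label, sex), None)
            c, n = (s.cases, s.population) if s else (0, 0)
            totals[sex][0] += c
            totals[sex][1] += n
            both[0] += c
            both[1] += n
            _fill(row, sex, c, n, ci_method)
        _fill(row, "total", both[0], both[1], ci_method)
        if row["female_rate"] and row["female_rate"] > 0:
            row["rate_mf"] = rate_ratio(row["male_rate"], row["female_rate"])
        else:
            row["rate_mf"] = np.nan
        rows.append(row)
    total_row: dict = {"age_class": "total"}
    grand = [0, 0]
    for sex in ("male", "female"):
        c, n = totals[sex]
        grand[0] += c
        grand[1] += n
        _fill(total_row, sex, c, n, ci_method)
    _fill(total_row, "total", grand[0], grand[1], ci_method)
    total_row["rate_mf"] = (
        rate_ratio(total_row["male_rate"], total_row["female_rate"])
        if total_row["female_rate"] else np.nan
    )
    rows.append(total_row)
    return pd.DataFrame(rows).set_index("age_class")


def _fill(row: dict, prefix: str, cases: int, population: int, ci_method: str) -> None:
    row[f"{prefix}_cases"] = cases
    row[f"{prefix}_population"] = population
    if population > 0:
        est = crude_rate(cases, population, ci_method)
        row[f"{prefix}_rate"] = est.rate
        row[f"{prefix}_ci_low"] = est.ci_low
        row[f"{prefix}_ci_high"] = est.ci_high
    else:
        row[f"{prefix}_rate"] = np.nan
        row[f"{prefix}_ci_low"] = np.nan
        row[f"{prefix}_ci_high"] = np.nan


def stratified_rates(
    cases: Sequence[PersonID],
    demographics: Sequence[Demographics],
    prevalence_date: Date,
    classes: Sequence[AgeClass] = DEFAULT_AGE_CLASSES,
    ci_method: str = "wald",
) -> pd.DataFrame:
    """Stratify a resolved cohort against the full population and build
    the prevalence table."""
    strata = count_strata(cases, demographics, prevalence_date, classes)
    return prevalence_table(strata, ci_method, classes)


def format_table(table: pd.DataFrame, rate_digits: int = 2) -> pd.DataFrame:
    """Round a prevalence table for display (rates and CIs to 2
    decimals, ratios already at 2)."""
    out = table.copy()
    for col in out.columns:
        if col.endswith(("_rate", "_ci_low", "_ci_high")):
            out[col] = out[col].map(
                lambda v: round_half_away(v, rate_digits) if pd.notna(v) else v
            )
    return out


# --------------------------------------------------------------------------
# direct standardization

ReferencePopulation = Mapping[tuple[str, str], float]
"""Reference weights keyed by ``(age_class_label, sex)``; counts or
proportions, strictly positive, normalized within the margin used."""


def direct_standardized_rate(
    strata: Sequence[Stratum],
    reference: ReferencePopulation,
    ci_method: str = "normal",
    alpha: float = 0.05,
) -> RateEstimate:
    """Directly standardized prevalence per 100.

    The stratum rates are averaged with weights proportional to the
    reference population of the *same strata* (so passing only male
    strata standardizes within the male margin).  The default CI is a
    normal approximation with variance equal to the weighted sum of
    per-stratum binomial variances; ``ci_method="gamma"`` gives the
    more conservative gamma interval used for standardized rates of
    rare outcomes.
    """
    if not strata:
        raise ValueError("no strata")
    keys = [(s.age_class.label, s.sex) for s in strata]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate strata")
    try:
        raw = np.array([reference[k] for k in keys], dtype=float)
    except KeyError as exc:
        raise ValueError(f"reference population missing stratum {exc}") from exc
    if np.any(raw <= 0):
        raise ValueError("reference weights must be strictly positive")
    for s in strata:
        if s.population == 0:
            raise ValueError(
                f"zero-population stratum {s.age_class.label}/{s.sex} with nonzero weight"
            )
    weights = raw / raw.sum()
    p = np.array([s.cases / s.population for s in strata])
    n = np.array([s.population for s in strata], dtype=float)
    rate = float(np.sum(weights * p) * 100.0)
    var = float(np.sum(weights**2 * p * (1 - p) / n)) * 100.0**2
    if ci_method == "normal":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        low, high = max(0.0, rate - half), min(100.0, rate + half)
    elif ci_method == "gamma":
        # gamma interval on the weighted sum of counts (Fay-Feuer style),
        # using the largest single-stratum weight for the upper bound
        y = float(np.sum(weights * p)) * 100.0
        if y == 0:
            low, high = 0.0, 0.0
        else:
            wm = float(np.max(weights / n)) * 100.0
            shape = y**2 / var
            scale = var / y
            low = float(stats.gamma.ppf(alpha / 2, shape, scale=scale))
            shape_hi = (y + wm) ** 2 / (var + wm**2)
            scale_hi = (var + wm**2) / (y + wm)
            high = float(stats.gamma.ppf(1 - alpha / 2, shape_hi, scale=scale_hi))
        low, high = max(0.0, low), min(100.0, high)
        low, high = min(low, rate), max(high, rate)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RateEstimate(rate, low, high)


def load_reference_population(path) -> dict[tuple[str, str], float]:
    """Read a reference-population CSV with columns
    ``age_class,sex,weight``."""
    df = pd.read_csv(path, dtype={"age_class": str, "sex": str})
    expected = ["age_class", "sex", "weight"]
    if list(df.columns) != expected:
        raise ValueError(f"reference file needs columns {expected}, got {list(df.columns)}")
    return {
        (row.age_class, row.sex): float(row.weight) for row in df.itertuples()
    }
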