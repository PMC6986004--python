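import datetime

import numpy as np
import pytest

from ckdlink.prevalence import (
    DEFAULT_AGE_CLASSES,
    Stratum,
    age_at,
    age_class_of,
    count_strata,
    crude_rate,
    direct_standardized_rate,
    format_table,
    prevalence_table,
    rate_ratio,
    strata_from_counts,
)
from ckdlink.synthdata import table2_counts

from conftest import demo, pid

D = datetime.date


# --------------------------------------------------------------------------
# ages

def test_age_at_birthday_boundaries():
    assert age_at(D(1932, 12, 31), D(2017, 12, 31)) == 85   # birthday that day
    assert age_at(D(1933, 1, 1), D(2017, 12, 31)) == 84     # not yet reached
    assert age_at(D(2017, 12, 31), D(2017, 12, 31)) == 0
    with pytest.raises(ValueError):
        age_at(D(2018, 1, 1), D(2017, 12, 31))


def _age_oracle(birth: D, ref: D) -> int:
    """Count birthdays passed, iterating year by year (Feb 29 completes
    on Mar 1 in common years)."""
    age = 0
    year = birth.year + 1
    while True:
        try:
            birthday = birth.replace(year=year)
        except ValueError:
            birthday = D(year, 3, 1)
        if birthday > ref:
            return age
        age += 1
        year += 1


def test_age_at_matches_day_count_oracle():
    rng = np.random.default_rng(11)
    start = D(1910, 1, 1)
    for _ in range(400):
        birth = start + datetime.timedelta(days=int(rng.integers(0, 40_000)))
        ref = birth + datetime.timedelta(days=int(rng.integers(0, 40_000)))
        assert age_at(birth, ref) == _age_oracle(birth, ref), (birth, ref)


def test_default_age_classes_partition_all_ages():
    for age in range(0, 120):
        assert sum(c.contains(age) for c in DEFAULT_AGE_CLASSES) == 1
    assert age_class_of(85).label == "85+"


# --------------------------------------------------------------------------
# crude rates

def test_crude_rate_reproduces_printed_total():
    est = crude_rate(99_457, 5_636_510)
    assert est.rounded() == (1.76, 1.75, 1.78)


def test_crude_rate_edge_cases():
    assert crude_rate(0, 1000).rounded() == (0.0, 0.0, 0.0)
    assert crude_rate(1_604, 490_339).rounded()[0] == 0.33
    with pytest.raises(ValueError):
        crude_rate(5, 0)
    with pytest.raises(ValueError):
        crude_rate(11, 10)


def test_clopper_pearson_contains_rate_and_is_wider_for_small_n():
    wald = crude_rate(3, 50, "wald")
    exact = crude_rate(3, 50, "clopper-pearson")
    assert exact.ci_low <= exact.rate <= exact.ci_high
    assert exact.ci_high - exact.ci_low >= wald.ci_high - wald.ci_low


def test_ci_width_shrinks_with_population():
    narrow = crude_rate(1000, 100_000)
    wide = crude_rate(100, 10_000)
    assert narrow.rate == wide.rate
    ratio = (wide.ci_high - wide.ci_low) / (narrow.ci_high - narrow.ci_low)
    assert ratio == pytest.approx(np.sqrt(10), rel=1e-6)


def test_crude_rate_monotone_in_cases():
    rates = [crude_rate(c, 10_000).rate for c in range(0, 2000, 50)]
    assert rates == sorted(rates)


# --------------------------------------------------------------------------
# rate ratios

def test_rate_ratio_printed_values():
    assert rate_ratio(2.06, 1.50) == 1.37
    assert rate_ratio(2.35, 1.39) == 1.69
    assert rate_ratio(1.0, 1.0) == 1.00
    with pytest.raises(ValueError):
        rate_ratio(1.0, 0.0)


# --------------------------------------------------------------------------
# the published stratum grid through the table machinery

_PRINTED_MALE = {
    "0-18": (0.33, 0.31, 0.34),
    "19-44": (0.33, 0.32, 0.34),
    "45-64": (1.27, 1.25, 1.30),
    "65-74": (4.73, 4.65, 4.81),
    "75-84": (9.88, 9.74, 10.01),
    "85+": (14.18, 13.90, 14.46),
    "total": (2.06, 2.04, 2.07),
}
_PRINTED_FEMALE = {
    "0-18": (0.25, 0.24, 0.27),
    "19-44": (0.29, 0.28, 0.30),
    "45-64": (0.82, 0.80, 0.83),
    "65-74": (2.59, 2.54, 2.65),
    "75-84": (5.58, 5.50, 5.67),
    "85+": (8.18, 8.03, 8.33),
    "total": (1.50, 1.48, 1.51),
}
_PRINTED_TOTAL_RATE = {
    "0-18": 0.29, "19-44": 0.31, "45-64": 1.03, "65-74": 3.58,
    "75-84": 7.41, "85+": 10.15, "total": 1.76,
}
_PRINTED_MF = {
    "0-18": 1.30, "19-44": 1.14, "45-64": 1.56, "65-74": 1.83,
    "75-84": 1.77, "85+": 1.73, "total": 1.37,
}


def test_published_grid_reproduces_every_printed_cell():
    """Feeding the published stratum counts through the table machinery
    must reproduce every printed rate, CI bound and M/F ratio."""
    table = format_table(prevalence_table(strata_from_counts(table2_counts())))
    for label, (rate, lo, hi) in _PRINTED_MALE.items():
        row = table.loc[label]
        assert (row.male_rate, row.male_ci_low, row.male_ci_high) == (rate, lo, hi)
    for label, (rate, lo, hi) in _PRINTED_FEMALE.items():
        row = table.loc[label]
        assert (row.female_rate, row.female_ci_low, row.female_ci_high) == (rate, lo, hi)
    for label, rate in _PRINTED_TOTAL_RATE.items():
        assert table.loc[label].total_rate == rate
    for label, mf in _PRINTED_MF.items():
        assert table.loc[label].rate_mf == mf
    # row-sum property: strata add up to the printed totals
    assert table.loc["total"].total_cases == 99_457
    assert table.loc["total"].total_population == 5_636_510
    assert table.loc["total", ["total_ci_low", "total_ci_high"]].tolist() == [1.75, 1.78]


# --------------------------------------------------------------------------
# person-level stratification vs a per-person tally oracle

def test_count_strata_matches_per_person_tally(window):
    rng = np.random.default_rng(5)
    demographics, case_ids = [], []
    for i in range(500):
        age = int(rng.integers(0, 100))
        birth = D(2017, 12, 31) - datetime.timedelta(days=age * 366)
        sex = "male" if rng.random() < 0.5 else "female"
        death = D(2016, 1, 1) if rng.random() < 0.05 else None
        demographics.append(demo(i, sex=sex, birth=birth, death=death))
        if rng.random() < 0.1 and death is None:
            case_ids.append(pid(i))
    strata = count_strata(case_ids, demographics, window.prevalence_date)
    # oracle: independent per-person tally
    expected = {}
    for d in demographics:
        if d.death_date is not None and d.death_date <= window.prevalence_date:
            continue
        key = (age_class_of(age_at(d.birth_date, window.prevalence_date)).label, d.sex)
        cases, pop = expected.get(key, (0, 0))
        expected[key] = (cases + (d.person in set(case_ids)), pop + 1)
    for s in strata:
        exp_cases, exp_pop = expected.get((s.age_class.label, s.sex), (0, 0))
        assert (s.cases, s.population) == (exp_cases, exp_pop)
    assert sum(s.cases for s in strata) == len(case_ids)


def test_count_strata_rejects_unknown_case(window):
    with pytest.raises(KeyError):
        count_strata([pid(99)], [demo(1)], window.prevalence_date)


# --------------------------------------------------------------------------
# direct standardization

def test_standardization_with_study_weights_is_the_crude_rate():
    strata = strata_from_counts(table2_counts())
    reference = {(s.age_class.label, s.sex): float(s.population) for s in strata}
    est = direct_standardized_rate(strata, reference)
    crude = 100.0 * sum(s.cases for s in strata) / sum(s.population for s in strata)
    assert est.rate == pytest.approx(crude, rel=1e-12)


def test_single_stratum_standardizes_to_its_own_rate():
    s = Stratum(DEFAULT_AGE_CLASSES[2], "male", 50, 1000)
    est = direct_standardized_rate([s], {("45-64", "male"): 123.0})
    assert est.rate == pytest.approx(5.0)


def test_two_strata_hand_computation():
    # rates 1% and 3% with weights 0.25/0.75 -> 2.5%
    strata = [
        Stratum(DEFAULT_AGE_CLASSES[0], "male", 10, 1000),
        Stratum(DEFAULT_AGE_CLASSES[1], "male", 30, 1000),
    ]
    reference = {("0-18", "male"): 0.25, ("19-44", "male"): 0.75}
    assert direct_standardized_rate(strata, reference).rate == pytest.approx(2.5)


def test_standardization_errors():
    s = Stratum(DEFAULT_AGE_CLASSES[0], "male", 1, 100)
    with pytest.raises(ValueError):
        direct_standardized_rate([s], {("19-44", "male"): 1.0})  # partition mismatch
    with pytest.raises(ValueError):
        direct_standardized_rate([s], {("0-18", "male"): 0.0})   # non-positive weight
    with pytest.raises(ValueError):
        direct_standardized_rate([], {})


def test_gamma_interval_contains_normal_point_estimate():
    strata = strata_from_counts(table2_counts())
    reference = {(s.age_class.label, s.sex): float(s.population) for s in strata}
    normal = direct_standardized_rate(strata, reference, "normal")
    gamma = direct_standardized_rate(strata, reference, "gamma")
    assert gamma.rate == pytest.approx(normal.rate)
    assert gamma.ci_low <= gamma.rate <= gamma.ci_high
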