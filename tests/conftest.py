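import datetime

import pytest

from ckdlink.casefinder import StudyWindow
from ckdlink.codelists import default_catalog
from ckdlink.registry_io import (
    Demographics,
    DrugRecord,
    ExemptionRecord,
    HospitalRecord,
    OutpatientRecord,
    PersonID,
)

D = datetime.date


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def window():
    return StudyWindow(D(2012, 1, 1), D(2017, 12, 31))


def pid(i) -> PersonID:
    return PersonID(f"P{i}")


def demo(i, sex="male", birth=D(1950, 6, 15), death=None, residence=None) -> Demographics:
    if residence is None:
        residence = ((D(2000, 1, 1), None),)
    return Demographics(
        person=pid(i), sex=sex, birth_date=birth, death_date=death,
        residence_intervals=residence,
    )


def hosp(i, dx, procs=(), svcs=(), discharge=D(2015, 6, 1)) -> HospitalRecord:
    return HospitalRecord(
        person=pid(i),
        admission_date=discharge - datetime.timedelta(days=3),
        discharge_date=discharge,
        diagnoses=tuple(dx),
        procedures=tuple(procs),
        service_codes=tuple(svcs),
    )


def exemption(i, code="025.585", start=D(2014, 3, 1), end=None) -> ExemptionRecord:
    return ExemptionRecord(person=pid(i), code=code, start_date=start, end_date=end)


def visit(i, code="89.7", branch="29", on=D(2015, 2, 1)) -> OutpatientRecord:
    return OutpatientRecord(person=pid(i), service_date=on, service_code=code,
                            branch=branch)


def dispensing(i, atc="B03XA01", on=D(2015, 6, 1)) -> DrugRecord:
    return DrugRecord(person=pid(i), dispensing_date=on, atc=atc)
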