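from datetime import date, datetime, timedelta, timezone

import pytest

from labguard.datasets import default_ruleset
from labguard.records import Order, Patient, TestRequest, TestResult

UTC = timezone.utc
T0 = datetime(2015, 10, 1, 12, 0, tzinfo=UTC)


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture
def patient():
    return Patient(patient_id="P1", sex="F", birth_date=date(1950, 6, 15))


def make_order(analytes, *, order_id="O1", patient_id="P1", ward="MEDICINE",
               system="SAP", when=T0, priority="ROUTINE", sample_type="ANY"):
    return Order(
        order_id=order_id,
        patient_id=patient_id,
        ward_group=ward,
        requesting_system=system,
        ordered_at=when,
        requests=[
            TestRequest(analyte=a, priority=priority, sample_type=sample_type)
            for a in analytes
        ],
    )


def make_prior(analyte, hours_before, *, patient_id="P1", value=None,
               units="", when=T0, executed=True):
    return TestResult(
        patient_id=patient_id,
        analyte=analyte,
        collected_at=when - timedelta(hours=hours_before),
        value=value,
        units=units,
        executed=executed,
    )
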