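import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from hypnovigil.faers_io import DrugMention, DrugRole, RawReport, SafetyCase
from hypnovigil.lexicon import load_default_lexicon

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def groups(lexicon):
    return lexicon[0]


@pytest.fixture(scope="session")
def smq(lexicon):
    return lexicon[1]


def build_case(
    case_id="C1",
    reactions=(),
    drugs=(),
    country="US",
    event_date=dt.date(2018, 6, 1),
    fda_date=dt.date(2018, 7, 1),
    version=1,
    primary_id=None,
):
    """Hand-rolled SafetyCase for unit tests."""
    report = RawReport(
        primary_id=primary_id or f"{case_id}-{version}",
        case_id=case_id,
        case_version=version,
        fda_receipt_date=fda_date,
        event_date=event_date,
        occurrence_country=country,
    )
    mentions = tuple(
        DrugMention(
            report_key=report.primary_id,
            sequence=i + 1,
            role=DrugRole(role),
            verbatim_name=name,
            active_ingredient=None,
        )
        for i, (name, role) in enumerate(drugs)
    )
    return SafetyCase(
        case_id=case_id,
        report=report,
        drugs=mentions,
        reactions=frozenset(reactions),
    )


@pytest.fixture
def make_case():
    return build_case
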