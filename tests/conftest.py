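import datetime as dt

import pytest

from rorscreen.case_pipeline import default_vocabulary
from rorscreen.data_model import AdrEntry, AgeCategory, CaseReport, DrugEntry, DrugRole, Sex
from rorscreen.drug_classes import default_class_table


@pytest.fixture(scope="session")
def classes():
    return default_class_table()


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


def make_case(
    case_id,
    drugs,
    adrs,
    sex=Sex.male,
    age=AgeCategory.forties,
    date=dt.date(2017, 6, 1),
):
    """Terse case constructor: drugs as (name, role) pairs, adrs as terms."""
    return CaseReport(
        case_id=case_id,
        sex=sex,
        age_category=age,
        report_date=date,
        drugs=[DrugEntry(n, DrugRole(r)) for n, r in drugs],
        adrs=[AdrEntry(t) for t in adrs],
    )


@pytest.fixture
def small_cases():
    """A hand-built mini database covering the cascade's branches."""
    return [
        # TD on an FGA with SGA + lithium co-use
        make_case(
            "c01",
            [("haloperidol", "suspected"), ("risperidone", "concomitant"),
             ("lithium carbonate", "concomitant")],
            ["tardive dyskinesia", "nausea"],
        ),
        # TD on an SGA with concomitant FGA
        make_case(
            "c02",
            [("risperidone", "suspected"), ("haloperidol", "concomitant")],
            ["tardive dyskinesia"],
            sex=Sex.female,
            age=AgeCategory.sixties,
        ),
        # akathisia only (competing movement case for the TD screen)
        make_case("c03", [("olanzapine", "suspected")], ["akathisia"]),
        # reference case: non-movement ADR on a non-antipsychotic
        make_case("c04", [("acetaminophen", "suspected")], ["rash"]),
        # concomitant-only antipsychotic link: dropped by the role filter
        make_case(
            "c05",
            [("quetiapine", "concomitant"), ("loxoprofen", "suspected")],
            ["dystonia"],
        ),
        # pediatric case: excluded
        make_case(
            "c06",
            [("haloperidol", "suspected")],
            ["tremor"],
            age=AgeCategory.neonate,
        ),
        # clozapine-exposed TD case: excluded from movement screens
        make_case(
            "c07",
            [("haloperidol", "suspected"), ("clozapine", "concomitant")],
            ["tardive dyskinesia"],
        ),
        # nonspecific term dropped; remaining reference ADR kept
        make_case(
            "c08",
            [("aripiprazole", "suspected")],
            ["long qt syndrome", "nausea"],
        ),
        # unknown sex: kept for demographics, dropped for ROR sets
        make_case(
            "c09",
            [("haloperidol", "suspected")],
            ["tardive dyskinesia"],
            sex=Sex.unknown,
        ),
    ]
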