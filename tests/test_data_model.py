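import datetime as dt

import pandas as pd
import pytest

from rorscreen.data_model import (
    AgeCategory,
    AgeGroup,
    DialectConfig,
    LoadError,
    ReportPeriod,
    derive_age_group,
    derive_period,
    read_database,
    write_database,
)
from rorscreen.synthetic_srs import paper_shaped_scenario, generate


@pytest.mark.parametrize(
    "category,expected",
    [
        (AgeCategory.under_10, AgeGroup.under60),
        (AgeCategory.teens, AgeGroup.under60),
        (AgeCategory.fifties, AgeGroup.under60),
        (AgeCategory.sixties, AgeGroup.sixty_plus),
        (AgeCategory.eighties_plus, AgeGroup.sixty_plus),
        (AgeCategory.unknown, AgeGroup.unknown),
    ],
)
def test_age_group_mapping(category, expected):
    assert derive_age_group(category) is expected


@pytest.mark.parametrize("category", [AgeCategory.fetus, AgeCategory.neonate, AgeCategory.infant])
def test_age_group_rejects_pediatric(category):
    with pytest.raises(ValueError):
        derive_age_group(category)


@pytest.mark.parametrize(
    "date,expected",
    [
        (dt.date(2011, 4, 1), ReportPeriod.p2011_2015),
        (dt.date(2015, 12, 31), ReportPeriod.p2011_2015),
        (dt.date(2016, 1, 1), ReportPeriod.p2016_2020),
        (dt.date(2020, 3, 31), ReportPeriod.p2016_2020),
    ],
)
def test_period_boundaries(date, expected):
    assert derive_period(date) is expected


@pytest.mark.parametrize("date", [dt.date(2011, 3, 31), dt.date(2020, 4, 1), dt.date(2005, 1, 1)])
def test_period_rejects_out_of_window(date):
    with pytest.raises(LoadError):
        derive_period(date)


def _write_three(tmp_path, demo, drug, reac):
    paths = tmp_path / "demo.csv", tmp_path / "drug.csv", tmp_path / "reac.csv"
    for df, p in zip((demo, drug, reac), paths):
        df.to_csv(p, index=False)
    return paths


def test_join_attaches_rows_by_case(tmp_path):
    demo = pd.DataFrame(
        {
            "case_id": ["a", "b"],
            "sex": ["male", "female"],
            "age_category": ["40s", "60s"],
            "report_date": ["2015-05-01", "2018-01-02"],
        }
    )
    drug = pd.DataFrame(
        {
            "case_id": ["a", "a", "b"],
            "generic_name": ["haloperidol", "biperiden", "risperidone"],
            "role": ["suspected", "concomitant", "suspected"],
        }
    )
    reac = pd.DataFrame({"case_id": ["a", "b"], "adr_term": ["tremor", "akathisia"]})
    result = read_database(*_write_three(tmp_path, demo, drug, reac))
    assert len(result.cases) == 2
    by_id = {c.case_id: c for c in result.cases}
    assert len(by_id["a"].drugs) == 2 and len(by_id["a"].adrs) == 1
    assert result.diagnostics.orphan_drug_rows == 0


def test_orphan_rows_reported_not_attached(tmp_path):
    demo = pd.DataFrame(
        {
            "case_id": ["a"],
            "sex": ["male"],
            "age_category": ["40s"],
            "report_date": ["2015-05-01"],
        }
    )
    drug = pd.DataFrame(
        {"case_id": ["a", "zz"], "generic_name": ["haloperidol", "ghost"], "role": ["suspected"] * 2}
    )
    reac = pd.DataFrame({"case_id": ["a"], "adr_term": ["tremor"]})
    result = read_database(*_write_three(tmp_path, demo, drug, reac))
    assert result.diagnostics.orphan_drug_rows == 1
    assert "zz" in result.diagnostics.orphan_case_ids
    assert all(d.generic_name != "ghost" for c in result.cases for d in c.drugs)
    # conservation: attached + orphans = input rows
    assert result.diagnostics.n_drug_rows == 2


def test_missing_column_is_a_load_error(tmp_path):
    demo = pd.DataFrame({"case_id": ["a"], "sex": ["male"], "report_date": ["2015-05-01"]})
    drug = pd.DataFrame({"case_id": [], "generic_name": [], "role": []})
    reac = pd.DataFrame({"case_id": [], "adr_term": []})
    with pytest.raises(LoadError, match="age_category"):
        read_database(*_write_three(tmp_path, demo, drug, reac))


def test_unparseable_date_names_row(tmp_path):
    demo = pd.DataFrame(
        {
            "case_id": ["a"],
            "sex": ["male"],
            "age_category": ["40s"],
            "report_date": ["not-a-date"],
        }
    )
    drug = pd.DataFrame({"case_id": ["a"], "generic_name": ["x"], "role": ["suspected"]})
    reac = pd.DataFrame({"case_id": ["a"], "adr_term": ["tremor"]})
    with pytest.raises(LoadError, match="row 2"):
        read_database(*_write_three(tmp_path, demo, drug, reac))


def test_load_is_row_order_independent(tmp_path):
    cfg = paper_shaped_scenario(n_reports=200, seed=4)
    db = generate(cfg)
    d1 = tmp_path / "fwd"
    db.write(d1)
    # shuffle rows of each table and reload
    d2 = tmp_path / "shuf"
    d2.mkdir()
    for name in ("demo.csv", "drug.csv", "reac.csv"):
        df = pd.read_csv(d1 / name, dtype=str)
        df.sample(frac=1.0, random_state=9).to_csv(d2 / name, index=False)
    r1 = read_database(d1 / "demo.csv", d1 / "drug.csv", d1 / "reac.csv")
    r2 = read_database(d2 / "demo.csv", d2 / "drug.csv", d2 / "reac.csv")
    ids1 = [c.case_id for c in r1.cases]
    ids2 = [c.case_id for c in r2.cases]
    assert ids1 == ids2
    for c1, c2 in zip(r1.cases, r2.cases):
        assert sorted((d.generic_name, d.role) for d in c1.drugs) == sorted(
            (d.generic_name, d.role) for d in c2.drugs
        )
        assert sorted(a.term for a in c1.adrs) == sorted(a.term for a in c2.adrs)


def test_generator_output_round_trips(tmp_path):
    cfg = paper_shaped_scenario(n_reports=500, seed=1)
    cfg = cfg.model_copy(update={"duplicate_rate": 0.0})
    db = generate(cfg)
    paths = db.write(tmp_path)
    result = read_database(paths["demo"], paths["drug"], paths["reac"])
    assert result.cases == db.cases()
    assert result.diagnostics.orphan_drug_rows == 0


def test_write_read_inverse(tmp_path, small_cases):
    demo, drug, reac = tmp_path / "d.csv", tmp_path / "g.csv", tmp_path / "r.csv"
    write_database(small_cases, demo, drug, reac)
    back = read_database(demo, drug, reac)
    assert back.cases == sorted(small_cases, key=lambda c: c.case_id)


def test_dialect_column_mapping(tmp_path):
    dialect = DialectConfig.model_validate(
        {
            "columns": {
                "case_id": "id_no",
                "sex": "sx",
                "age_category": "age",
                "report_date": "repdate",
                "generic_name": "drug",
                "role": "involvement",
                "adr_term": "pt",
            },
            "date_format": "%Y/%m/%d",
        }
    )
    demo = pd.DataFrame(
        {"id_no": ["k1"], "sx": ["female"], "age": ["70s"], "repdate": ["2019/11/30"]}
    )
    drug = pd.DataFrame({"id_no": ["k1"], "drug": ["quetiapine"], "involvement": ["suspected"]})
    reac = pd.DataFrame({"id_no": ["k1"], "pt": ["parkinsonism"]})
    paths = tmp_path / "a.csv", tmp_path / "b.csv", tmp_path / "c.csv"
    for df, p in zip((demo, drug, reac), paths):
        df.to_csv(p, index=False)
    result = read_database(*paths, dialect=dialect)
    case = result.cases[0]
    assert case.report_date == dt.date(2019, 11, 30)
    assert case.drugs[0].generic_name == "quetiapine"
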