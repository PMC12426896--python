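"""Domain types and readers/writers for a JADER-dialect spontaneous-report database.

A spontaneous reporting system (SRS) database in this dialect consists of three
linked delimited-text tables sharing a case-identifier column:

* a demographics table (one row per case: sex, age category, report date),
* a drug table (one row per drug per case, with an involvement role), and
* a reaction table (one row per reported adverse-reaction preferred term per case).

Column names, encoding and the date format are not fixed by the dialect and are
supplied through a :class:`DialectConfig`.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel

__all__ = [
    "DrugRole",
    "Sex",
    "AgeCategory",
    "ReportPeriod",
    "AgeGroup",
    "DrugEntry",
    "AdrEntry",
    "CaseReport",
    "DialectConfig",
    "LoadDiagnostics",
    "LoadResult",
    "LoadError",
    "read_database",
    "write_database",
    "cases_to_frame",
    "derive_age_group",
    "derive_period",
    "STUDY_WINDOW",
]

STUDY_WINDOW = (dt.date(2011, 4, 1), dt.date(2020, 3, 31))


class DrugRole(str, enum.Enum):
    """Reporter-assigned involvement of a drug in the reported reaction."""

    suspected = "suspected"
    interaction = "interaction"
    concomitant = "concomitant"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class AgeCategory(str, enum.Enum):
    """Coarse categorical age as stored in the reporting system."""

    fetus = "fetus"
    neonate = "neonate"
    infant = "infant"
    under_10 = "under_10"
    teens = "10s"
    twenties = "20s"
    thirties = "30s"
    forties = "40s"
    fifties = "50s"
    sixties = "60s"
    seventies = "70s"
    eighties_plus = "80s_plus"
    unknown = "unknown"


#: Age categories that are excluded before any adult analysis.
PEDIATRIC_EXCLUDED = frozenset(
    {AgeCategory.fetus, AgeCategory.neonate, AgeCategory.infant}
)

_UNDER60 = {
    AgeCategory.under_10,
    AgeCategory.teens,
    AgeCategory.twenties,
    AgeCategory.thirties,
    AgeCategory.forties,
    AgeCategory.fifties,
}
_SIXTY_PLUS = {AgeCategory.sixties, AgeCategory.seventies, AgeCategory.eighties_plus}


class ReportPeriod(str, enum.Enum):
    """Reported-year bucket used as a binary covariate."""

    p2011_2015 = "2011-2015"
    p2016_2020 = "2016-2020"


class AgeGroup(str, enum.Enum):
    """Binary age covariate (under / at-or-over 60 years)."""

    under60 = "under60"
    sixty_plus = "sixty_plus"
    unknown = "unknown"


@dataclass(frozen=True)
class DrugEntry:
    generic_name: str
    role: DrugRole


@dataclass(frozen=True)
class AdrEntry:
    term: str

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise ValueError("ADR term must be a non-empty string")


@dataclass
class CaseReport:
    """One deduplicated spontaneous report."""

    case_id: str
    sex: Sex
    age_category: AgeCategory
    report_date: dt.date
    drugs: list[DrugEntry] = field(default_factory=list)
    adrs: list[AdrEntry] = field(default_factory=list)


def derive_age_group(age_category: AgeCategory) -> AgeGroup:
    """Collapse the categorical age into the binary <60 / >=60 covariate.

    Fetus/neonate/infant categories are excluded upstream and are a contract
    violation here.
    """
    age_category = AgeCategory(age_category)
    if age_category in PEDIATRIC_EXCLUDED:
        raise ValueError(
            f"age category {age_category.value!r} must be excluded before age grouping"
        )
    if age_category in _UNDER60:
        return AgeGroup.under60
    if age_category in _SIXTY_PLUS:
        return AgeGroup.sixty_plus
    return AgeGroup.unknown


def derive_period(report_date: dt.date) -> ReportPeriod:
    """Bucket a report date into the 2011-2015 / 2016-2020 reported-year periods."""
    if not (STUDY_WINDOW[0] <= report_date <= STUDY_WINDOW[1]):
        raise LoadError(
            f"report date {report_date.isoformat()} outside the study window "
            f"{STUDY_WINDOW[0].isoformat()}..{STUDY_WINDOW[1].isoformat()}"
        )
    return ReportPeriod.p2011_2015 if report_date.year <= 2015 else ReportPeriod.p2016_2020


class LoadError(ValueError):
    """Raised when the three-table database cannot be loaded consistently."""


class ColumnMap(BaseModel):
    """Column names of the three tables in the concrete files."""

    case_id: str = "case_id"
    sex: str = "sex"
    age_category: str = "age_category"
    report_date: str = "report_date"
    generic_name: str = "generic_name"
    role: str = "role"
    adr_term: str = "adr_term"


class DialectConfig(BaseModel):
    """File-level conventions of a concrete database distribution.

    ``date_field`` exists because reporting systems carry several candidate
    dates per case; which one defines the "reported year" is the user's call.
    """

    columns: ColumnMap = ColumnMap()
    encoding: str = "utf-8"  # the real distribution may need "cp932"
    delimiter: str = ","
    date_format: str = "%Y-%m-%d"
    date_field: str | None = None  # overrides columns.report_date when set
    sex_values: dict[str, str] = {"male": "male", "female": "female", "unknown": "unknown"}
    role_values: dict[str, str] = {
        "suspected": "suspected",
        "interaction": "interaction",
        "concomitant": "concomitant",
    }
    age_values: dict[str, str] = {}  # file value -> AgeCategory value; identity if empty

    @classmethod
    def from_file(cls, path: str | Path) -> "DialectConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.model_validate(data)


@dataclass
class LoadDiagnostics:
    """Row accounting for one load: every input row is either attached or an orphan."""

    n_cases: int = 0
    n_drug_rows: int = 0
    n_reac_rows: int = 0
    orphan_drug_rows: int = 0
    orphan_reac_rows: int = 0
    orphan_case_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_cases": self.n_cases,
                "n_drug_rows": self.n_drug_rows,
                "n_reac_rows": self.n_reac_rows,
                "orphan_drug_rows": self.orphan_drug_rows,
                "orphan_reac_rows": self.orphan_reac_rows,
                "orphan_case_ids": sorted(set(self.orphan_case_ids)),
                "attached_drug_rows": self.n_drug_rows - self.orphan_drug_rows,
                "attached_reac_rows": self.n_reac_rows - self.orphan_reac_rows,
            },
            indent=2,
        )


@dataclass
class LoadResult:
    cases: list[CaseReport]
    diagnostics: LoadDiagnostics


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise LoadError(f"{fname}: missing required column(s) {missing}")


def _parse_date(value: str, fmt: str, fname: str, row: int) -> dt.date:
    try:
        return dt.datetime.strptime(str(value).strip(), fmt).date()
    except ValueError as exc:
        raise LoadError(f"{fname}: unparseable date {value!r} at row {row}") from exc


def read_database(
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    dialect: DialectConfig | None = None,
) -> LoadResult:
    """Load and join the three-table database into :class:`CaseReport` objects.

    One ``CaseReport`` is produced per identifier in the demographics table;
    drug and reaction rows are attached by identifier. Drug or reaction rows
    whose identifier is absent from the demographics table are counted as
    orphans in the diagnostics and never silently dropped into a case.
    Output is canonically sorted by ``case_id`` with entry order preserved
    within each case, so the result is independent of input row order.
    """
    dialect = dialect or DialectConfig()
    cols = dialect.columns
    read_kw = dict(sep=dialect.delimiter, encoding=dialect.encoding, dtype=str)
    demo = pd.read_csv(demo_path, **read_kw)
    drug = pd.read_csv(drug_path, **read_kw)
    reac = pd.read_csv(reac_path, **read_kw)

    date_col = dialect.date_field or cols.report_date
    _require_columns(demo, [cols.case_id, cols.sex, cols.age_category, date_col], str(demo_path))
    _require_columns(drug, [cols.case_id, cols.generic_name, cols.role], str(drug_path))
    _require_columns(reac, [cols.case_id, cols.adr_term], str(reac_path))

    diag = LoadDiagnostics(
        n_drug_rows=len(drug), n_reac_rows=len(reac)
    )

    sex_map = dialect.sex_values
    role_map = dialect.role_values
    age_map = dialect.age_values

    cases: dict[str, CaseReport] = {}
    for i, row in enumerate(demo.itertuples(index=False)):
        rec = dict(zip(demo.columns, row))
        cid = str(rec[cols.case_id])
        if cid in cases:
            raise LoadError(f"{demo_path}: duplicate case identifier {cid!r}")
        date = _parse_date(rec[date_col], dialect.date_format, str(demo_path), i + 2)
        derive_period(date)  # reject out-of-window dates at load
        raw_sex = str(rec[cols.sex]).strip()
        raw_age = str(rec[cols.age_category]).strip()
        try:
            sex = Sex(sex_map.get(raw_sex, raw_sex))
            age = AgeCategory(age_map.get(raw_age, raw_age))
        except ValueError as exc:
            raise LoadError(f"{demo_path}: row {i + 2}: {exc}") from exc
        cases[cid] = CaseReport(
            case_id=cid, sex=sex, age_category=age, report_date=date
        )

    for tbl, path, attach in ((drug, drug_path, "drug"), (reac, reac_path, "reac")):
        for rec in tbl.to_dict("records"):
            cid = str(rec[cols.case_id])
            case = cases.get(cid)
            if case is None:
                if attach == "drug":
                    diag.orphan_drug_rows += 1
                else:
                    diag.orphan_reac_rows += 1
                diag.orphan_case_ids.append(cid)
                continue
            if attach == "drug":
                raw_role = str(rec[cols.role]).strip()
                try:
                    role = DrugRole(role_map.get(raw_role, raw_role))
                except ValueError as exc:
                    raise LoadError(f"{path}: unknown drug role {raw_role!r}") from exc
                case.drugs.append(
                    DrugEntry(generic_name=str(rec[cols.generic_name]).strip(), role=role)
                )
            else:
                case.adrs.append(AdrEntry(term=str(rec[cols.adr_term]).strip()))

    diag.n_cases = len(cases)
    ordered = [cases[cid] for cid in sorted(cases)]
    return LoadResult(cases=ordered, diagnostics=diag)


def write_database(
    cases: Iterable[CaseReport],
    demo_path: str | Path,
    drug_path: str | Path,
    reac_path: str | Path,
    dialect: DialectConfig | None = None,
) -> None:
    """Write cases back out as the three delimited tables (inverse of read)."""
    dialect = dialect or DialectConfig()
    cols = dialect.columns
    demo_rows, drug_rows, reac_rows = [], [], []
    for case in cases:
        demo_rows.append(
            {
                cols.case_id: case.case_id,
                cols.sex: case.sex.value,
                cols.age_category: case.age_category.value,
                (dialect.date_field or cols.report_date): case.report_date.strftime(
                    dialect.date_format
                ),
            }
        )
        for d in case.drugs:
            drug_rows.append(
                {
                    cols.case_id: case.case_id,
                    cols.generic_name: d.generic_name,
                    cols.role: d.role.value,
                }
            )
        for a in case.adrs:
            reac_rows.append({cols.case_id: case.case_id, cols.adr_term: a.term})
    kw = dict(sep=dialect.delimiter, index=False, encoding=dialect.encoding)
    pd.DataFrame(demo_rows).to_csv(demo_path, **kw)
    pd.DataFrame(drug_rows).to_csv(drug_path, **kw)
    pd.DataFrame(reac_rows).to_csv(reac_path, **kw)


def cases_to_frame(cases: Iterable[CaseReport]) -> pd.DataFrame:
    """Explode cases into one row per (case, ADR term, drug) link.

    This tidy triple-level frame is the working representation of the curation
    pipeline; demographic columns are repeated on every row.
    """
    rows = []
    for case in cases:
        period = derive_period(case.report_date)
        for adr in case.adrs:
            for d in case.drugs:
                rows.append(
                    {
                        "case_id": case.case_id,
                        "adr_term": adr.term,
                        "generic_name": d.generic_name,
                        "role": d.role.value,
                        "sex": case.sex.value,
                        "age_category": case.age_category.value,
                        "period": period.value,
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "adr_term",
            "generic_name",
            "role",
            "sex",
            "age_category",
            "period",
        ],
    )
    return frame
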