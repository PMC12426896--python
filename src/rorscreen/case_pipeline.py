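"""Case curation for the disproportionality screen.

The cascade mirrors standard spontaneous-report practice:

1. expand reports into (case, ADR term, drug) triples and deduplicate —
   multiple rows are one case when identification number, ADR and suspected
   drug generic name all coincide;
2. keep only links whose drug role is *suspected* (concomitant and
   drug-drug-interaction links are dropped);
3. drop nonspecific ADR terms known to be antipsychotic- or injection-related
   regardless of causal signal (configurable list);
4. drop cases with pediatric age categories (fetus / neonate / infant);
5. for movement-disorder (TD/EPS) case selection, drop TD/EPS cases in which
   clozapine was used in any role — clozapine is reserved for
   treatment-resistant disease, so its reports are confounded by prior
   antipsychotic exposure.

For each ADR of interest the analysis set keeps that ADR's cases and the
reference cases carrying no TD/EPS term at all; cases carrying a different
TD/EPS term are removed ("competing" movement-disorder cases). A case
contributes one analysis unit per distinct suspected drug, so a single case
may appear under several drug columns — the multiplicity of report-level
counting is preserved deliberately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

from .data_model import (
    CaseReport,
    DrugRole,
    PEDIATRIC_EXCLUDED,
    Sex,
    cases_to_frame,
    derive_age_group,
)
from .drug_classes import DrugClass, DrugClassTable, normalize_name

__all__ = [
    "CaseTriple",
    "AdrVocabulary",
    "FlowCounts",
    "AnalysisSet",
    "deduplicate",
    "apply_exclusions",
    "build_analysis_set",
    "concomitant_flags",
    "family_units",
    "curate",
    "default_vocabulary",
]


class CaseTriple(NamedTuple):
    """The deduplication key: identification number, ADR, suspected drug name."""

    case_id: str
    adr_term: str
    generic_name: str


DEFAULT_EPS_TERMS = (
    "akathisia",
    "dyskinesia",
    "dystonia",
    "parkinsonism",
    "parkinsonian gait",
    "bradykinesia",
    "dysarthria",
    "anarthria",
    "cogwheel rigidity",
    "tremor",
    "akinesia",
    "hypersalivation",
)

DEFAULT_NONSPECIFIC = (
    "long qt syndrome",
    "anaphylaxis",
    "injection site reaction",
)


@dataclass(frozen=True)
class AdrVocabulary:
    """Preferred-term vocabulary driving case selection.

    Terms are matched case-insensitively after whitespace normalization.
    """

    td_terms: frozenset[str] = frozenset({"tardive dyskinesia"})
    eps_terms: frozenset[str] = frozenset(DEFAULT_EPS_TERMS)
    nonspecific_exclusions: frozenset[str] = frozenset(DEFAULT_NONSPECIFIC)

    def __post_init__(self) -> None:
        norm = lambda terms: frozenset(normalize_name(t) for t in terms)
        object.__setattr__(self, "td_terms", norm(self.td_terms))
        object.__setattr__(self, "eps_terms", norm(self.eps_terms))
        object.__setattr__(
            self, "nonspecific_exclusions", norm(self.nonspecific_exclusions)
        )
        if self.td_terms & self.eps_terms:
            raise ValueError("TD and EPS term sets must be disjoint")

    @property
    def movement_terms(self) -> frozenset[str]:
        return self.td_terms | self.eps_terms

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AdrVocabulary":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            td_terms=frozenset(data.get("td_terms", ["tardive dyskinesia"])),
            eps_terms=frozenset(data.get("eps_terms", DEFAULT_EPS_TERMS)),
            nonspecific_exclusions=frozenset(
                data.get("nonspecific_exclusions", DEFAULT_NONSPECIFIC)
            ),
        )


def default_vocabulary() -> AdrVocabulary:
    return AdrVocabulary()


@dataclass
class FlowCounts:
    """Per-stage accounting: input = excluded + retained, chained across stages."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, label: str, n_input: int, n_excluded: int) -> None:
        retained = n_input - n_excluded
        if n_excluded < 0 or retained < 0:
            raise AssertionError(f"flow stage {label!r}: negative count")
        if self.stages and self.stages[-1][3] != n_input:
            raise AssertionError(
                f"flow stage {label!r}: input {n_input} != previous retained "
                f"{self.stages[-1][3]}"
            )
        self.stages.append((label, n_input, n_excluded, retained))

    def validate(self) -> None:
        for label, n_input, n_excluded, retained in self.stages:
            if n_input != n_excluded + retained:
                raise AssertionError(f"flow conservation violated at {label!r}")

    def to_json(self) -> str:
        self.validate()
        return json.dumps(
            [
                {"stage": s, "input": i, "excluded": e, "retained": r}
                for s, i, e, r in self.stages
            ],
            indent=2,
        )


def deduplicate(triples: Iterable[CaseTriple]) -> list[CaseTriple]:
    """Collapse exact (case, ADR, drug) duplicates, keeping first occurrence."""
    seen: dict[CaseTriple, None] = {}
    for t in triples:
        key = CaseTriple(
            t.case_id, normalize_name(t.adr_term), normalize_name(t.generic_name)
        )
        if key not in seen:
            seen[key] = None
    return list(seen)


def _dedup_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["adr_term"] = frame["adr_term"].map(normalize_name)
    frame["generic_name"] = frame["generic_name"].map(normalize_name)
    return frame.drop_duplicates(
        subset=["case_id", "adr_term", "generic_name"], keep="first"
    )


def _clozapine_case_ids(
    cases: Iterable[CaseReport], classes: DrugClassTable, any_role: bool
) -> set[str]:
    out = set()
    for case in cases:
        for d in case.drugs:
            if classes.is_clozapine(d.generic_name) and (
                any_role or d.role is DrugRole.suspected
            ):
                out.add(case.case_id)
                break
    return out


def apply_exclusions(
    cases: Sequence[CaseReport],
    vocab: AdrVocabulary,
    classes: DrugClassTable,
    clozapine_any_role: bool = True,
) -> tuple[pd.DataFrame, FlowCounts]:
    """Run the triple-level exclusion cascade; returns (retained triples, flow).

    The returned frame holds deduplicated suspected-drug triples of adult cases
    with specific ADR terms; TD/EPS triples of clozapine-exposed cases are
    removed. Counts at every stage satisfy input = excluded + retained.
    """
    flow = FlowCounts()
    frame = cases_to_frame(cases)
    raw = len(frame)

    frame = _dedup_frame(frame)
    flow.add("deduplicate (case, ADR, drug) triples", raw, raw - len(frame))

    keep = frame["role"] == DrugRole.suspected.value
    flow.add("keep suspected-drug links only", len(frame), int((~keep).sum()))
    frame = frame[keep]

    nonspecific = frame["adr_term"].isin(vocab.nonspecific_exclusions)
    flow.add("drop nonspecific ADR terms", len(frame), int(nonspecific.sum()))
    frame = frame[~nonspecific]

    pediatric = frame["age_category"].isin({a.value for a in PEDIATRIC_EXCLUDED})
    flow.add("drop fetus/neonate/infant cases", len(frame), int(pediatric.sum()))
    frame = frame[~pediatric]

    cloz_ids = _clozapine_case_ids(cases, classes, clozapine_any_role)
    movement = frame["adr_term"].isin(vocab.movement_terms)
    drop_cloz = movement & frame["case_id"].isin(cloz_ids)
    flow.add("drop clozapine-exposed TD/EPS cases", len(frame), int(drop_cloz.sum()))
    frame = frame[~drop_cloz]

    flow.validate()
    return frame.reset_index(drop=True), flow


def concomitant_flags(
    case: CaseReport, focal_drug: str, classes: DrugClassTable
) -> tuple[bool, bool, bool, bool]:
    """(FGA, SGA, anticholinergic, lithium) co-use flags for one focal drug.

    A flag is true iff some drug entry *other than the focal one* maps to the
    class, regardless of that entry's role. Repeated entries of the focal drug
    itself never set a flag.
    """
    focal = normalize_name(focal_drug)
    fga = sga = antich = lith = False
    for d in case.drugs:
        name = normalize_name(d.generic_name)
        if name == focal:
            continue
        cls = classes.classify(name).drug_class
        if cls is DrugClass.FGA:
            fga = True
        elif cls is DrugClass.SGA:
            sga = True
        elif cls is DrugClass.anticholinergic:
            antich = True
        elif cls is DrugClass.lithium:
            lith = True
    return fga, sga, antich, lith


@dataclass
class _CaseContext:
    """Per-case covariates and per-class drug-name sets, computed once."""

    covariates: dict[str, tuple[str, str]]  # case_id -> (sex, age_group)
    class_names: dict[str, dict[DrugClass, frozenset[str]]]


_FLAG_CLASSES = (
    DrugClass.FGA,
    DrugClass.SGA,
    DrugClass.anticholinergic,
    DrugClass.lithium,
)


def _build_context(cases: Sequence[CaseReport], classes: DrugClassTable) -> _CaseContext:
    covariates: dict[str, tuple[str, str]] = {}
    class_names: dict[str, dict[DrugClass, frozenset[str]]] = {}
    for case in cases:
        if case.age_category in PEDIATRIC_EXCLUDED:
            age = "pediatric"  # excluded upstream; placeholder never reaches units
        else:
            age = derive_age_group(case.age_category).value
        covariates[case.case_id] = (case.sex.value, age)
        per_class: dict[DrugClass, set[str]] = {c: set() for c in _FLAG_CLASSES}
        for d in case.drugs:
            name = normalize_name(d.generic_name)
            cls = classes.classify(name).drug_class
            if cls in per_class:
                per_class[cls].add(name)
        class_names[case.case_id] = {c: frozenset(s) for c, s in per_class.items()}
    return _CaseContext(covariates, class_names)


def _flag(names: frozenset[str], focal: str) -> bool:
    return bool(names) and (len(names) > 1 or focal not in names)


def _units_for_pairs(
    pairs: pd.DataFrame, outcome: str, ctx: _CaseContext, period_by_case: pd.Series
) -> pd.DataFrame:
    """Attach covariates and co-use flags to distinct (case, drug) pairs."""
    recs = []
    cov = ctx.covariates
    cls_names = ctx.class_names
    for cid, drug in pairs.itertuples(index=False):
        sex, age = cov[cid]
        names = cls_names[cid]
        recs.append(
            (
                cid,
                drug,
                outcome,
                sex,
                age,
                _flag(names[DrugClass.FGA], drug),
                _flag(names[DrugClass.SGA], drug),
                _flag(names[DrugClass.anticholinergic], drug),
                _flag(names[DrugClass.lithium], drug),
            )
        )
    units = pd.DataFrame(
        recs,
        columns=[
            "case_id",
            "generic_name",
            "outcome",
            "sex",
            "age_group",
            "conc_fga",
            "conc_sga",
            "conc_anticholinergic",
            "conc_lithium",
        ],
    )
    units["period"] = units["case_id"].map(period_by_case)
    return units


_UNIT_COLUMNS = [
    "case_id",
    "generic_name",
    "outcome",
    "sex",
    "age_group",
    "conc_fga",
    "conc_sga",
    "conc_anticholinergic",
    "conc_lithium",
    "period",
]


@dataclass
class AnalysisSet:
    """Units retained for one ADR of interest after competing-case removal."""

    adr_of_interest: str
    units: pd.DataFrame
    for_ror: bool

    def __len__(self) -> int:
        return len(self.units)


def _empty_units() -> pd.DataFrame:
    return pd.DataFrame(columns=_UNIT_COLUMNS)


def _interest_and_competing(
    retained: pd.DataFrame, vocab: AdrVocabulary
) -> tuple[pd.DataFrame, pd.Series]:
    movement = retained[retained["adr_term"].isin(vocab.movement_terms)]
    terms_by_case = movement.groupby("case_id")["adr_term"].agg(frozenset)
    return movement, terms_by_case


def _assemble_set(
    retained: pd.DataFrame,
    adr: str,
    vocab: AdrVocabulary,
    ctx: _CaseContext,
    terms_by_case: pd.Series,
    reference_units: pd.DataFrame,
    period_by_case: pd.Series,
    for_ror: bool,
) -> AnalysisSet:
    has_term = terms_by_case.apply(lambda s: adr in s)
    interest_cases = set(terms_by_case.index[has_term])
    pairs = retained.loc[
        (retained["adr_term"] == adr) & retained["case_id"].isin(interest_cases),
        ["case_id", "generic_name"],
    ].drop_duplicates()
    interest_units = _units_for_pairs(pairs, "adr_of_interest", ctx, period_by_case)
    units = pd.concat([interest_units, reference_units], ignore_index=True)
    if for_ror and len(units):
        known = (units["sex"] != Sex.unknown.value) & (units["age_group"] != "unknown")
        units = units[known]
    return AnalysisSet(adr, units.reset_index(drop=True)[_UNIT_COLUMNS], for_ror)


def _reference_units(
    retained: pd.DataFrame,
    vocab: AdrVocabulary,
    ctx: _CaseContext,
    terms_by_case: pd.Series,
    period_by_case: pd.Series,
) -> pd.DataFrame:
    """Units of cases carrying no TD/EPS term; shared across all screens."""
    movement_cases = set(terms_by_case.index)
    ref = retained[~retained["case_id"].isin(movement_cases)]
    pairs = ref[["case_id", "generic_name"]].drop_duplicates()
    if not len(pairs):
        return _empty_units()
    return _units_for_pairs(pairs, "reference_adr", ctx, period_by_case)


def build_analysis_set(
    cases: Sequence[CaseReport],
    retained: pd.DataFrame,
    adr_of_interest: str,
    vocab: AdrVocabulary,
    classes: DrugClassTable,
    for_ror: bool = True,
) -> AnalysisSet:
    """Assemble the per-ADR analysis units from the retained triple frame.

    ``outcome`` is ``adr_of_interest`` when the case carries the term of
    interest, ``reference_adr`` when the case carries no TD/EPS term at all;
    cases carrying a different TD/EPS term (and not the term of interest) are
    absent. With ``for_ror`` true, units of unknown sex or unknown binary age
    are additionally removed, matching the screen's complete-case requirement.
    """
    adr = normalize_name(adr_of_interest)
    if adr not in vocab.movement_terms:
        raise ValueError(
            f"ADR of interest {adr_of_interest!r} is not in the TD/EPS vocabulary"
        )
    if not len(retained):
        return AnalysisSet(adr, _empty_units(), for_ror)
    ctx = _build_context(cases, classes)
    period_by_case = retained.drop_duplicates("case_id").set_index("case_id")["period"]
    _, terms_by_case = _interest_and_competing(retained, vocab)
    ref_units = _reference_units(retained, vocab, ctx, terms_by_case, period_by_case)
    return _assemble_set(
        retained, adr, vocab, ctx, terms_by_case, ref_units, period_by_case, for_ror
    )


def family_units(
    cases: Sequence[CaseReport],
    retained: pd.DataFrame,
    terms: Iterable[str],
    classes: DrugClassTable,
) -> pd.DataFrame:
    """Demographic units for a family of ADR terms (e.g., all EPS terms).

    One unit per (case, suspected drug) pair linked to any term in the family;
    unknown sex/age are retained, since demographic tables show "Unknown" rows.
    """
    terms = {normalize_name(t) for t in terms}
    ctx = _build_context(cases, classes)
    age_cat = {c.case_id: c.age_category.value for c in cases}
    sel = retained[retained["adr_term"].isin(terms)]
    if not len(sel):
        return pd.DataFrame(columns=_UNIT_COLUMNS + ["age_category"])
    period_by_case = retained.drop_duplicates("case_id").set_index("case_id")["period"]
    pairs = sel[["case_id", "generic_name"]].drop_duplicates()
    units = _units_for_pairs(pairs, "adr_of_interest", ctx, period_by_case)
    units["age_category"] = units["case_id"].map(age_cat)
    return units.reset_index(drop=True)


def curate(
    cases: Sequence[CaseReport],
    vocab: AdrVocabulary | None = None,
    classes: DrugClassTable | None = None,
    for_ror: bool = True,
    clozapine_any_role: bool = True,
) -> tuple[dict[str, AnalysisSet], FlowCounts]:
    """Full cascade: exclusions plus one analysis set per TD/EPS term.

    The reference units (cases with no TD/EPS term) are identical across all
    screens and are computed once.
    """
    from .drug_classes import default_class_table

    vocab = vocab or default_vocabulary()
    classes = classes or default_class_table()
    retained, flow = apply_exclusions(cases, vocab, classes, clozapine_any_role)
    if not len(retained):
        sets = {
            term: AnalysisSet(term, _empty_units(), for_ror)
            for term in sorted(vocab.movement_terms)
        }
        return sets, flow
    ctx = _build_context(cases, classes)
    period_by_case = retained.drop_duplicates("case_id").set_index("case_id")["period"]
    _, terms_by_case = _interest_and_competing(retained, vocab)
    ref_units = _reference_units(retained, vocab, ctx, terms_by_case, period_by_case)
    sets = {
        term: _assemble_set(
            retained, term, vocab, ctx, terms_by_case, ref_units, period_by_case, for_ror
        )
        for term in sorted(vocab.movement_terms)
    }
    return sets, flow
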