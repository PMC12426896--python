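"""Synthetic spontaneous-reporting-system generator with known ground truth.

Each synthetic report draws demographics (sex, categorical age, report date),
a focal suspected drug, optional co-used drugs (with class-correlated co-use
to create confounding), and a set of adverse-reaction preferred terms. Term
assignment is a per-term independent Bernoulli whose log-odds is the term's
baseline plus the log odds-multipliers of matching *suspected* drugs plus
planted covariate effects (movement-disorder terms only):

    logit Pr(term) = logit(base_t) + sum_d log OR(d, t)
                     + b_age 1{age>=60} + b_sex 1{female} + b_period 1{2016-2020}

Under this additive structure every planted odds multiplier is a well-defined
conditional odds ratio and is recoverable by the screen. Reports are resampled
until they carry at least one term (a reaction-free report cannot exist in a
reporting system); with the small per-term baselines used here the induced
distortion of planted odds ratios is negligible relative to sampling noise.
Duplicate rows are emitted at a configurable rate to exercise deduplication.
The same seed and config always produce byte-identical output files.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .data_model import (
    AdrEntry,
    AgeCategory,
    CaseReport,
    DialectConfig,
    DrugEntry,
    DrugRole,
    Sex,
)
from .drug_classes import DrugClass, DrugClassTable, SgaGroup, default_class_table

__all__ = [
    "DrugSpec",
    "AdrSpec",
    "EffectSpec",
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticDatabase",
    "generate",
    "paper_shaped_scenario",
]


class DrugSpec(BaseModel):
    name: str
    drug_class: str = "other"  # FGA / SGA / anticholinergic / lithium / other
    sga_group: str = "none"
    use_prob: float = Field(gt=0)  # marginal weight for the focal-drug draw


class AdrSpec(BaseModel):
    term: str
    base_prob: float = Field(gt=0, lt=1)
    movement: bool = False  # TD/EPS flag


class EffectSpec(BaseModel):
    """Planted odds multiplier for (drug selector, term).

    ``drug`` is a generic name, a class label (``FGA``, ``SGA``), or an SGA
    group selector (``SGA:g1`` .. ``SGA:g4``); it matches suspected drugs.
    """

    drug: str
    term: str
    odds_multiplier: float = Field(gt=0)


class PolypharmacyConfig(BaseModel):
    mean_extra: float = Field(ge=0, default=0.8)
    role_probs: dict[str, float] = {"suspected": 0.25, "interaction": 0.05, "concomitant": 0.70}
    # co-use probability per class, given an antipsychotic focal drug
    couse: dict[str, float] = {
        "anticholinergic": 0.35,
        "lithium": 0.07,
        "FGA": 0.30,
        "SGA": 0.40,
    }


class Demographics(BaseModel):
    sex_probs: dict[str, float] = {"male": 0.52, "female": 0.48}
    age_probs: dict[str, float] = {
        "fetus": 0.002,
        "neonate": 0.003,
        "infant": 0.005,
        "under_10": 0.01,
        "10s": 0.04,
        "20s": 0.12,
        "30s": 0.16,
        "40s": 0.20,
        "50s": 0.17,
        "60s": 0.13,
        "70s": 0.10,
        "80s_plus": 0.05,
    }
    period_probs: dict[str, float] = {"2011-2015": 0.45, "2016-2020": 0.55}


class Missingness(BaseModel):
    sex_unknown: float = Field(ge=0, lt=1, default=0.02)
    age_unknown: float = Field(ge=0, lt=1, default=0.05)


class CovariateEffects(BaseModel):
    """Planted log-odds shifts applied to movement-disorder terms."""

    age_sixty_plus: float = 0.0
    female: float = 0.0
    period_2016_2020: float = 0.0


class GeneratorConfig(BaseModel):
    n_reports: int = Field(gt=0)
    drug_menu: list[DrugSpec]
    adr_menu: list[AdrSpec]
    effects: list[EffectSpec] = []
    covariate_effects: CovariateEffects = CovariateEffects()
    demographics: Demographics = Demographics()
    missingness: Missingness = Missingness()
    polypharmacy: PolypharmacyConfig = PolypharmacyConfig()
    duplicate_rate: float = Field(ge=0, lt=1, default=0.05)
    seed: int = 0

    @model_validator(mode="after")
    def _check_menus(self) -> "GeneratorConfig":
        if not self.drug_menu or not self.adr_menu:
            raise ValueError("drug and ADR menus must be non-empty")
        if sum(d.use_prob for d in self.drug_menu) <= 0:
            raise ValueError("degenerate drug menu: zero total use probability")
        names = [d.name for d in self.drug_menu]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in menu")
        return self

    def class_table(self) -> DrugClassTable:
        """Classification table implied by the menu (for pipeline runs)."""
        from .drug_classes import _build  # shared constructor/validation

        rows = [
            {
                "name": d.name,
                "class": d.drug_class,
                "group": None if d.sga_group == "none" else d.sga_group,
            }
            for d in self.drug_menu
        ]
        return _build(rows)


@dataclass
class GroundTruth:
    """Planted effects, retrievable per (drug selector, term)."""

    effects: dict[tuple[str, str], float]
    covariate_effects: dict[str, float]

    def odds_ratio(self, drug: str, term: str) -> float:
        return self.effects.get((drug, term), 1.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "effects": [
                    {"drug": d, "term": t, "odds_multiplier": m}
                    for (d, t), m in sorted(self.effects.items())
                ],
                "covariate_effects": self.covariate_effects,
            },
            indent=2,
        )


_PERIOD_WINDOWS = {
    "2011-2015": (dt.date(2011, 4, 1), dt.date(2015, 12, 31)),
    "2016-2020": (dt.date(2016, 1, 1), dt.date(2020, 3, 31)),
}


@dataclass
class SyntheticDatabase:
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig
    _case_records: list[CaseReport]

    def cases(self) -> list[CaseReport]:
        return self._case_records

    def write(self, out_dir: str | Path, dialect: DialectConfig | None = None) -> dict[str, Path]:
        """Write the three tables (duplicate rows included), truth and config."""
        dialect = dialect or DialectConfig()
        cols = dialect.columns
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "demo": out / "demo.csv",
            "drug": out / "drug.csv",
            "reac": out / "reac.csv",
            "truth": out / "truth.json",
            "config": out / "config.yaml",
        }
        kw = dict(sep=dialect.delimiter, index=False, encoding=dialect.encoding)
        self.demo.rename(
            columns={
                "case_id": cols.case_id,
                "sex": cols.sex,
                "age_category": cols.age_category,
                "report_date": dialect.date_field or cols.report_date,
            }
        ).to_csv(paths["demo"], **kw)
        self.drug.rename(
            columns={
                "case_id": cols.case_id,
                "generic_name": cols.generic_name,
                "role": cols.role,
            }
        ).to_csv(paths["drug"], **kw)
        self.reac.rename(
            columns={"case_id": cols.case_id, "adr_term": cols.adr_term}
        ).to_csv(paths["reac"], **kw)
        paths["truth"].write_text(self.truth.to_json())
        paths["config"].write_text(yaml.safe_dump(self.config.model_dump(), sort_keys=True))
        return paths


def _matches(selector: str, name: str, cls) -> bool:
    if selector == name:
        return True
    if selector == "FGA":
        return cls.drug_class is DrugClass.FGA
    if selector == "SGA":
        return cls.drug_class is DrugClass.SGA
    if selector.startswith("SGA:"):
        return cls.sga_group is not SgaGroup.none and cls.sga_group.value == selector[4:]
    return False


def generate(config: GeneratorConfig) -> SyntheticDatabase:
    """Generate the three-table database plus ground truth for one config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    classes = config.class_table()
    demo_cfg = config.demographics

    def _draw(labels_probs: dict[str, float], size: int) -> np.ndarray:
        labels = list(labels_probs)
        p = np.array([labels_probs[k] for k in labels], dtype=float)
        p = p / p.sum()
        idx = rng.choice(len(labels), size=size, p=p)
        return np.array(labels, dtype=object)[idx]

    sex = _draw(demo_cfg.sex_probs, n)
    sex[rng.random(n) < config.missingness.sex_unknown] = "unknown"
    age = _draw(demo_cfg.age_probs, n)
    age[rng.random(n) < config.missingness.age_unknown] = "unknown"
    period = _draw(demo_cfg.period_probs, n)

    dates = np.empty(n, dtype=object)
    for label, (start, end) in _PERIOD_WINDOWS.items():
        mask = period == label
        span = (end - start).days
        offsets = rng.integers(0, span + 1, size=int(mask.sum()))
        dates[mask] = [start + dt.timedelta(days=int(o)) for o in offsets]

    menu_names = [d.name for d in config.drug_menu]
    menu_probs = np.array([d.use_prob for d in config.drug_menu], dtype=float)
    menu_probs = menu_probs / menu_probs.sum()
    focal_idx = rng.choice(len(menu_names), size=n, p=menu_probs)

    by_class: dict[str, list[str]] = {}
    for d in config.drug_menu:
        by_class.setdefault(d.drug_class, []).append(d.name)

    poly = config.polypharmacy
    role_labels = list(poly.role_probs)
    role_p = np.array([poly.role_probs[r] for r in role_labels], dtype=float)
    role_p = role_p / role_p.sum()
    n_extra = rng.poisson(poly.mean_extra, size=n)

    antipsychotic_focal = np.array(
        [
            classes.classify(menu_names[i]).drug_class in (DrugClass.FGA, DrugClass.SGA)
            for i in focal_idx
        ]
    )
    couse_draws = {
        cls: ((rng.random(n) < p) & antipsychotic_focal, rng.random(n))
        for cls, p in poly.couse.items()
        if by_class.get(cls)
    }

    # pre-draw the variable-length randomness in flat arrays (speed)
    total_extra = int(n_extra.sum())
    extra_idx = rng.choice(len(menu_names), size=total_extra, p=menu_probs)
    extra_role_idx = rng.choice(len(role_labels), size=total_extra, p=role_p)
    extra_offsets = np.concatenate([[0], np.cumsum(n_extra)])

    drugs_per_report: list[list[tuple[str, str]]] = []
    for i in range(n):
        focal = menu_names[focal_idx[i]]
        entries = [(focal, DrugRole.suspected.value)]
        present = {focal}
        for cls, (mask, upick) in couse_draws.items():
            if mask[i]:
                pool = [x for x in by_class[cls] if x != focal]
                if pool:
                    pick = pool[int(upick[i] * len(pool))]
                    if pick not in present:
                        entries.append((pick, DrugRole.concomitant.value))
                        present.add(pick)
        for j in range(extra_offsets[i], extra_offsets[i + 1]):
            pick = menu_names[extra_idx[j]]
            if pick in present:
                continue
            entries.append((pick, role_labels[extra_role_idx[j]]))
            present.add(pick)
        drugs_per_report.append(entries)

    # per-report suspected-drug sets drive the planted effects
    suspected_sets = [
        frozenset(name for name, role in entries if role == DrugRole.suspected.value)
        for entries in drugs_per_report
    ]

    terms = [a.term for a in config.adr_menu]
    base_logit = np.array(
        [math.log(a.base_prob / (1 - a.base_prob)) for a in config.adr_menu]
    )
    movement = np.array([a.movement for a in config.adr_menu])

    logits = np.tile(base_logit, (n, 1))
    for eff in config.effects:
        col = terms.index(eff.term)
        log_m = math.log(eff.odds_multiplier)
        unique_names = {nm for s in suspected_sets for nm in s}
        matching = {
            nm for nm in unique_names if _matches(eff.drug, nm, classes.classify(nm))
        }
        if matching:
            hit = np.array([bool(s & matching) for s in suspected_sets])
            logits[hit, col] += log_m

    cov = config.covariate_effects
    if any((cov.age_sixty_plus, cov.female, cov.period_2016_2020)):
        age_hi = np.isin(age, ("60s", "70s", "80s_plus")).astype(float)
        female = (sex == "female").astype(float)
        late = (period == "2016-2020").astype(float)
        shift = (
            cov.age_sixty_plus * age_hi + cov.female * female + cov.period_2016_2020 * late
        )
        logits[:, movement] += shift[:, None]

    probs = 1.0 / (1.0 + np.exp(-logits))
    term_matrix = rng.random((n, len(terms))) < probs
    # resample reaction-free reports: a report without reactions cannot exist
    empty = ~term_matrix.any(axis=1)
    while empty.any():
        idx = np.where(empty)[0]
        term_matrix[idx] = rng.random((len(idx), len(terms))) < probs[idx]
        empty[idx] = ~term_matrix[idx].any(axis=1)

    case_records: list[CaseReport] = []
    width = len(str(n))
    for i in range(n):
        cid = f"C{i + 1:0{width}d}"
        case_records.append(
            CaseReport(
                case_id=cid,
                sex=Sex(sex[i]),
                age_category=AgeCategory(age[i]),
                report_date=dates[i],
                drugs=[DrugEntry(nm, DrugRole(role)) for nm, role in drugs_per_report[i]],
                adrs=[AdrEntry(terms[j]) for j in np.where(term_matrix[i])[0]],
            )
        )

    demo_rows, drug_rows, reac_rows = [], [], []
    dup = config.duplicate_rate
    n_drug_total = sum(len(c.drugs) for c in case_records)
    n_reac_total = sum(len(c.adrs) for c in case_records)
    dup_drug = rng.random(n_drug_total) < dup if dup > 0 else np.zeros(n_drug_total, bool)
    dup_reac = rng.random(n_reac_total) < dup if dup > 0 else np.zeros(n_reac_total, bool)
    di = ri = 0
    for case in case_records:
        demo_rows.append(
            (case.case_id, case.sex.value, case.age_category.value,
             case.report_date.strftime("%Y-%m-%d"))
        )
        for d in case.drugs:
            row = (case.case_id, d.generic_name, d.role.value)
            drug_rows.append(row)
            if dup_drug[di]:
                drug_rows.append(row)
            di += 1
        for a in case.adrs:
            row = (case.case_id, a.term)
            reac_rows.append(row)
            if dup_reac[ri]:
                reac_rows.append(row)
            ri += 1

    demo = pd.DataFrame(demo_rows, columns=["case_id", "sex", "age_category", "report_date"])
    drug = pd.DataFrame(drug_rows, columns=["case_id", "generic_name", "role"])
    reac = pd.DataFrame(reac_rows, columns=["case_id", "adr_term"])

    truth = GroundTruth(
        effects={(e.drug, e.term): e.odds_multiplier for e in config.effects},
        covariate_effects={
            "age_sixty_plus": cov.age_sixty_plus,
            "female": cov.female,
            "period_2016_2020": cov.period_2016_2020,
        },
    )
    return SyntheticDatabase(demo, drug, reac, truth, config, case_records)


# --------------------------------------------------------------------------
# ready-made scenario


_MOVEMENT_TERMS = (
    "tardive dyskinesia",
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

#: (FGA multiplier, SGA multiplier) per movement term; the FGA > SGA ordering
#: for TD, dyskinesia and parkinsonism mirrors the qualitative pattern a
#: generation contrast is expected to show.
_SCENARIO_EFFECTS: dict[str, tuple[float, float]] = {
    "tardive dyskinesia": (12.0, 6.0),
    "akathisia": (6.0, 6.0),
    "dyskinesia": (8.0, 4.0),
    "dystonia": (6.0, 6.0),
    "parkinsonism": (10.0, 4.0),
    "parkinsonian gait": (3.0, 3.0),
    "bradykinesia": (3.0, 3.0),
    "dysarthria": (2.0, 2.0),
    "anarthria": (2.0, 2.0),
    "cogwheel rigidity": (2.0, 2.0),
    "tremor": (4.0, 4.0),
    "akinesia": (3.0, 3.0),
    "hypersalivation": (4.0, 4.0),
}

_REFERENCE_TERMS = (
    "nausea",
    "rash",
    "hepatic function abnormal",
    "interstitial lung disease",
    "pyrexia",
    "headache",
    "diarrhoea",
    "thrombocytopenia",
    "dizziness",
    "insomnia",
)


def paper_shaped_scenario(
    n_reports: int = 100_000, seed: int = 13, equalized_effects: bool = False
) -> GeneratorConfig:
    """A ready-made config shaped like an antipsychotic movement-disorder screen.

    Thirteen TD/EPS terms, a pool of non-movement reference reactions, FGA and
    SGA (group 1-4) drug menus with anticholinergic and lithium co-use, and
    planted effect sizes ordered FGA > SGA for TD, dyskinesia and parkinsonism.
    With ``equalized_effects`` the FGA and SGA multipliers are set equal
    (both at the FGA level), removing the generation contrast.
    """
    table = default_class_table()
    fga_names = ("haloperidol", "chlorpromazine", "levomepromazine", "sulpiride")
    sga_names = (
        "risperidone",
        "perospirone",
        "blonanserin",
        "paliperidone",
        "olanzapine",
        "quetiapine",
        "aripiprazole",
        "brexpiprazole",
    )
    other_names = (
        "acetaminophen",
        "loxoprofen",
        "lamotrigine",
        "valproate semisodium",
        "amlodipine",
        "clarithromycin",
        "pregabalin",
        "warfarin",
    )
    menu = []
    for nm in fga_names:
        menu.append(DrugSpec(name=nm, drug_class="FGA", use_prob=0.08 / len(fga_names)))
    for nm in sga_names:
        cls = table.classify(nm)
        menu.append(
            DrugSpec(
                name=nm,
                drug_class="SGA",
                sga_group=cls.sga_group.value,
                use_prob=0.15 / len(sga_names),
            )
        )
    menu.append(DrugSpec(name="clozapine", drug_class="SGA", sga_group="g3", use_prob=0.004))
    menu.append(DrugSpec(name="biperiden", drug_class="anticholinergic", use_prob=0.01))
    menu.append(DrugSpec(name="lithium carbonate", drug_class="lithium", use_prob=0.006))
    for nm in other_names:
        menu.append(DrugSpec(name=nm, drug_class="other", use_prob=0.75 / len(other_names)))

    adr_menu = [
        AdrSpec(term=t, base_prob=0.004, movement=True) for t in _MOVEMENT_TERMS
    ]
    adr_menu += [AdrSpec(term=t, base_prob=0.045, movement=False) for t in _REFERENCE_TERMS]
    # nonspecific terms exercised by the exclusion cascade
    adr_menu += [
        AdrSpec(term="long qt syndrome", base_prob=0.01, movement=False),
        AdrSpec(term="anaphylaxis", base_prob=0.01, movement=False),
        AdrSpec(term="injection site reaction", base_prob=0.01, movement=False),
    ]

    effects = []
    for term, (fga_or, sga_or) in _SCENARIO_EFFECTS.items():
        if equalized_effects:
            sga_or = fga_or
        effects.append(EffectSpec(drug="FGA", term=term, odds_multiplier=fga_or))
        effects.append(EffectSpec(drug="SGA", term=term, odds_multiplier=sga_or))

    return GeneratorConfig(
        n_reports=n_reports,
        drug_menu=menu,
        adr_menu=adr_menu,
        effects=effects,
        seed=seed,
    )


def null_calibration_scenario(n_reports: int, seed: int) -> GeneratorConfig:
    """Paper-shaped menus with no planted effects, for type-I / coverage studies.

    Movement-term baselines are raised to 0.02 so every screen cell carries
    enough counts for the exact interval's discreteness to be negligible;
    with tiny cells exact conditional intervals are guaranteed-conservative
    and coverage would sit above any realistic nominal band.
    """
    cfg = paper_shaped_scenario(n_reports=n_reports, seed=seed)
    cfg = cfg.model_copy(deep=True)
    cfg.effects = []
    for adr in cfg.adr_menu:
        if adr.movement:
            adr.base_prob = 0.02
    return cfg


def recovery_scenario(
    n_reports: int,
    seed: int,
    planted_or: float = 5.0,
    covariate_effects: CovariateEffects | None = None,
) -> GeneratorConfig:
    """A clean single-effect config for parameter-recovery studies.

    One planted odds multiplier (FGA -> tardive dyskinesia) on a slim menu;
    extra drugs are never co-suspected, so no report carries more than one
    suspected drug and the planted conditional odds ratio is exactly the
    screen's estimand (the non-target movement-term factors cancel between
    the interest and reference outcome probabilities).
    """
    menu = [
        DrugSpec(name="haloperidol", drug_class="FGA", use_prob=0.06),
        DrugSpec(name="chlorpromazine", drug_class="FGA", use_prob=0.04),
        DrugSpec(name="biperiden", drug_class="anticholinergic", use_prob=0.01),
        DrugSpec(name="lithium carbonate", drug_class="lithium", use_prob=0.005),
        DrugSpec(name="acetaminophen", use_prob=0.45),
        DrugSpec(name="loxoprofen", use_prob=0.435),
    ]
    adr_menu = [
        AdrSpec(term="tardive dyskinesia", base_prob=0.01, movement=True),
        AdrSpec(term="akathisia", base_prob=0.01, movement=True),
        AdrSpec(term="nausea", base_prob=0.06, movement=False),
        AdrSpec(term="rash", base_prob=0.05, movement=False),
        AdrSpec(term="pyrexia", base_prob=0.04, movement=False),
    ]
    return GeneratorConfig(
        n_reports=n_reports,
        drug_menu=menu,
        adr_menu=adr_menu,
        effects=[
            EffectSpec(drug="FGA", term="tardive dyskinesia", odds_multiplier=planted_or)
        ],
        covariate_effects=covariate_effects or CovariateEffects(),
        polypharmacy=PolypharmacyConfig(
            mean_extra=0.5,
            role_probs={"interaction": 0.1, "concomitant": 0.9},
            couse={"anticholinergic": 0.3, "lithium": 0.05},
        ),
        duplicate_rate=0.0,
        seed=seed,
    )
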