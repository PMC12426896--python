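"""Config-driven classification of generic drug names.

Drugs are classified as first-generation antipsychotic (FGA), second-generation
antipsychotic (SGA, subdivided into pharmacology-based groups 1-4 following the
Neuroscience-based Nomenclature), anticholinergic, lithium, or other. The group
scheme: group 1 — dopamine + serotonin receptor antagonists; group 2 — dopamine
+ serotonin + norepinephrine antagonists; group 3 — multimodal agents; group 4 —
dopamine/serotonin partial agonists-antagonists.

The shipped default table is a reconstruction of that scheme for antipsychotics
marketed in Japan; users reproducing a specific published analysis should load
the exact roster used there. Every screen records the classification-table
checksum so outputs are traceable to the table that produced them.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "DrugClass",
    "SgaGroup",
    "DrugClassTable",
    "load_class_table",
    "default_class_table",
    "normalize_name",
    "ClassTableError",
]


class DrugClass(str, enum.Enum):
    FGA = "FGA"
    SGA = "SGA"
    anticholinergic = "anticholinergic"
    lithium = "lithium"
    other = "other"


class SgaGroup(str, enum.Enum):
    g1 = "g1"
    g2 = "g2"
    g3 = "g3"
    g4 = "g4"
    none = "none"


class ClassTableError(ValueError):
    """Configuration problem in a drug-classification table."""


def normalize_name(name: str) -> str:
    """Canonical form used for matching: lowercase, whitespace collapsed."""
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class Classification:
    drug_class: DrugClass
    sga_group: SgaGroup = SgaGroup.none
    clozapine: bool = False  # distinguished marker driving the curation exclusion


_UNKNOWN = Classification(DrugClass.other, SgaGroup.none)


class DrugClassTable:
    """Immutable generic-name -> (class, SGA group) lookup."""

    def __init__(self, entries: dict[str, Classification]):
        for name, cls in entries.items():
            if (cls.drug_class is DrugClass.SGA) != (cls.sga_group is not SgaGroup.none):
                raise ClassTableError(
                    f"{name!r}: SGA group must be set exactly when class is SGA"
                )
        self._entries = dict(entries)

    def classify(self, name: str) -> Classification:
        """Total over all strings: unknown names map to class ``other``."""
        return self._entries.get(normalize_name(name), _UNKNOWN)

    def is_clozapine(self, name: str) -> bool:
        return self.classify(name).clozapine

    def names(self) -> list[str]:
        return sorted(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def checksum(self) -> str:
        payload = json.dumps(
            {
                n: [c.drug_class.value, c.sga_group.value, c.clozapine]
                for n, c in sorted(self._entries.items())
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(
            {
                "checksum": self.checksum(),
                "entries": {
                    n: {
                        "class": c.drug_class.value,
                        "sga_group": c.sga_group.value,
                        "clozapine": c.clozapine,
                    }
                    for n, c in sorted(self._entries.items())
                },
            },
            indent=2,
        )


def _build(rows: list[dict]) -> DrugClassTable:
    entries: dict[str, Classification] = {}
    for row in rows:
        name = normalize_name(row["name"])
        drug_class = DrugClass(str(row["class"]))
        raw_group = str(row.get("group") or "none").strip().lower()
        group = SgaGroup.none if raw_group in ("", "-", "none", "nan") else SgaGroup(raw_group)
        if drug_class is not DrugClass.SGA and group is not SgaGroup.none:
            raise ClassTableError(f"{name!r}: group set on non-SGA class")
        if drug_class is DrugClass.SGA and group is SgaGroup.none:
            raise ClassTableError(f"{name!r}: SGA entry missing group")
        cls = Classification(drug_class, group, clozapine=(name == "clozapine"))
        if name in entries and entries[name] != cls:
            raise ClassTableError(f"conflicting duplicate classification for {name!r}")
        entries[name] = cls
    return DrugClassTable(entries)


def load_class_table(path: str | Path) -> DrugClassTable:
    """Load a classification table from CSV (name,class,group) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        rows = [
            {"name": name, "class": spec.get("class"), "group": spec.get("group")}
            if isinstance(spec, dict)
            else {"name": name, "class": spec, "group": None}
            for name, spec in data.items()
        ]
    else:
        df = pd.read_csv(path, dtype=str)
        missing = {"name", "class"} - set(df.columns)
        if missing:
            raise ClassTableError(f"{path}: missing column(s) {sorted(missing)}")
        if "group" not in df.columns:
            df["group"] = None
        rows = df.to_dict("records")
    return _build(rows)


# Reconstructed default roster (marked as such in the module docstring):
# pharmacology-based grouping of antipsychotics marketed in Japan, plus the
# anticholinergics and lithium salts needed for concomitant-use covariates.
_DEFAULT_ROWS: list[tuple[str, str, str | None]] = [
    # first-generation antipsychotics
    ("haloperidol", "FGA", None),
    ("chlorpromazine", "FGA", None),
    ("levomepromazine", "FGA", None),
    ("fluphenazine", "FGA", None),
    ("perphenazine", "FGA", None),
    ("sulpiride", "FGA", None),
    ("sultopride", "FGA", None),
    ("tiapride", "FGA", None),
    ("bromperidol", "FGA", None),
    ("timiperone", "FGA", None),
    ("spiperone", "FGA", None),
    ("pimozide", "FGA", None),
    ("zotepine", "FGA", None),
    ("propericiazine", "FGA", None),
    ("oxypertine", "FGA", None),
    ("nemonapride", "FGA", None),
    ("mosapramine", "FGA", None),
    # SGA group 1: dopamine + serotonin antagonists
    ("risperidone", "SGA", "g1"),
    ("perospirone", "SGA", "g1"),
    ("blonanserin", "SGA", "g1"),
    ("lurasidone", "SGA", "g1"),
    # SGA group 2: dopamine + serotonin + norepinephrine antagonists
    ("paliperidone", "SGA", "g2"),
    ("olanzapine", "SGA", "g2"),
    ("asenapine", "SGA", "g2"),
    # SGA group 3: multimodal
    ("quetiapine", "SGA", "g3"),
    ("clozapine", "SGA", "g3"),
    # SGA group 4: partial agonists-antagonists
    ("aripiprazole", "SGA", "g4"),
    ("brexpiprazole", "SGA", "g4"),
    # anticholinergics used against drug-induced parkinsonism
    ("biperiden", "anticholinergic", None),
    ("trihexyphenidyl", "anticholinergic", None),
    ("promethazine", "anticholinergic", None),
    ("piroheptine", "anticholinergic", None),
    ("mazaticol", "anticholinergic", None),
    # lithium salts
    ("lithium carbonate", "lithium", None),
]


def default_class_table() -> DrugClassTable:
    """The reconstructed default classification table."""
    return _build([{"name": n, "class": c, "group": g} for n, c, g in _DEFAULT_ROWS])
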