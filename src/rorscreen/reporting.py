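"""Report tables, forest plots and flow accounting.

Demographic tables follow the usual case-characteristics layout of
pharmacovigilance papers: one column per drug group (FGAs, SGAs total, SGA
groups 1-4, non-antipsychotics), rows for sex, age bands, the binary age
covariate, concomitant drug use, and report period, each shown as "n (pct)"
with percentages of the column total to two decimals. Display rounding never
touches the machine-readable output; formatted and numeric frames are
separate objects.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .case_pipeline import FlowCounts
from .disproportionality import DrugGroup, group_mask
from .drug_classes import DrugClassTable

__all__ = [
    "demographics_table",
    "demographics_counts",
    "flow_accounting",
    "forest_plot",
]

_COLUMNS = [
    DrugGroup.fga,
    DrugGroup.sga_total,
    DrugGroup.sga_g1,
    DrugGroup.sga_g2,
    DrugGroup.sga_g3,
    DrugGroup.sga_g4,
    DrugGroup.non_antipsychotics,
]

_AGE_BANDS = [
    ("< 20", {"under_10", "10s"}),
    ("20-39", {"20s", "30s"}),
    ("40-59", {"40s", "50s"}),
    ("60-79", {"60s", "70s"}),
    (">= 80", {"80s_plus"}),
    ("Age unknown", {"unknown"}),
]


def _count_rows(units: pd.DataFrame) -> list[tuple[str, pd.Series]]:
    """(row label, boolean mask) pairs over the demographic unit frame."""
    rows: list[tuple[str, pd.Series]] = []
    rows.append(("Male", units["sex"] == "male"))
    rows.append(("Female", units["sex"] == "female"))
    rows.append(("Sex unknown", units["sex"] == "unknown"))
    for label, cats in _AGE_BANDS:
        rows.append((label, units["age_category"].isin(cats)))
    rows.append(("< 60 years", units["age_group"] == "under60"))
    rows.append((">= 60 years", units["age_group"] == "sixty_plus"))
    rows.append(("Age group unknown", units["age_group"] == "unknown"))
    rows.append(("Concomitant FGAs", units["conc_fga"]))
    rows.append(("Concomitant SGAs", units["conc_sga"]))
    rows.append(("Concomitant anticholinergics", units["conc_anticholinergic"]))
    rows.append(("Concomitant lithium", units["conc_lithium"]))
    rows.append(("2011-2015", units["period"] == "2011-2015"))
    rows.append(("2016-2020", units["period"] == "2016-2020"))
    return rows


def demographics_counts(
    units: pd.DataFrame, classes: DrugClassTable
) -> pd.DataFrame:
    """Numeric demographic summary: counts and percentages per drug-group column."""
    out: dict[str, dict[str, float]] = {}
    for group in _COLUMNS:
        if len(units):
            mask = group_mask(units["generic_name"], group, classes)
            col_units = units[mask]
        else:
            col_units = units
        n = len(col_units)
        col: dict[str, float] = {"n": n}
        for label, sel in _count_rows(col_units):
            k = int(sel.sum())
            col[f"{label} n"] = k
            col[f"{label} pct"] = round(100.0 * k / n, 2) if n else math.nan
        out[group.value] = col
    return pd.DataFrame(out)


def demographics_table(units: pd.DataFrame, classes: DrugClassTable) -> pd.DataFrame:
    """Formatted "n (pct)" demographic table; empty columns show blank cells."""
    counts = demographics_counts(units, classes)
    labels = [lab for lab, _ in _count_rows(units if len(units) else _empty_units())]
    rows = {"n": {g: str(int(counts.loc["n", g])) for g in counts.columns}}
    for label in labels:
        formatted = {}
        for g in counts.columns:
            n = counts.loc["n", g]
            if n == 0:
                formatted[g] = ""
            else:
                k = int(counts.loc[f"{label} n", g])
                pct = counts.loc[f"{label} pct", g]
                formatted[g] = f"{k} ({pct:.2f})"
        rows[label] = formatted
    return pd.DataFrame(rows).T[counts.columns]


def _empty_units() -> pd.DataFrame:
    from .case_pipeline import _UNIT_COLUMNS

    return pd.DataFrame(columns=_UNIT_COLUMNS + ["age_category"])


def flow_accounting(flow: FlowCounts) -> str:
    """Validate per-stage conservation and export the flow as JSON."""
    flow.validate()
    return flow.to_json()


def forest_plot(
    rows: pd.DataFrame,
    path: str | Path,
    title: str | None = None,
    xlim: tuple[float, float] | None = None,
) -> Path:
    """Forest plot of screen rows on a log-scaled odds-ratio axis.

    One marker and whisker per row; the dashed line marks the null odds ratio
    of 1. Confidence bounds at 0 or +inf (boundary cells) are drawn as
    censoring arrowheads; rows with undefined intervals are skipped. Output is
    deterministic for fixed input (fixed SVG hash salt, no timestamps).
    """
    rows = rows.reset_index(drop=True)
    finite_vals = [
        v
        for col in ("ror", "ci_low", "ci_high")
        for v in rows[col]
        if isinstance(v, (int, float)) and np.isfinite(v) and v > 0
    ]
    if not finite_vals:
        import warnings

        warnings.warn("forest plot input has no drawable rows", stacklevel=2)
        finite_vals = [1.0]
    lo = min(min(finite_vals) / 2, 0.5)
    hi = max(max(finite_vals) * 2, 2.0)
    if xlim:
        lo, hi = xlim

    with matplotlib.rc_context({"svg.hashsalt": "rorscreen"}):
        height = max(2.0, 0.32 * len(rows) + 1.2)
        fig, ax = plt.subplots(figsize=(7, height))
        ax.set_xscale("log")
        ax.axvline(1.0, color="0.4", linestyle="--", linewidth=0.8)
        ypos = np.arange(len(rows))[::-1]
        labels = []
        for y, rec in zip(ypos, rows.to_dict("records")):
            label = " / ".join(
                str(rec[c]) for c in ("adr", "drug_group") if c in rec and pd.notna(rec[c])
            )
            labels.append(label or f"row {len(rows) - y}")
            ror, cl, ch = rec.get("ror"), rec.get("ci_low"), rec.get("ci_high")
            undefined = any(
                v is None or (isinstance(v, float) and math.isnan(v)) for v in (cl, ch)
            )
            if undefined:
                continue
            left = max(cl, lo) if cl > 0 else lo
            right = min(ch, hi) if math.isfinite(ch) else hi
            ax.plot([left, right], [y, y], color="k", linewidth=1.0)
            if cl <= 0 or cl < lo:
                ax.plot([left], [y], marker="<", color="k", markersize=5)
            if not math.isfinite(ch) or ch > hi:
                ax.plot([right], [y], marker=">", color="k", markersize=5)
            if isinstance(ror, (int, float)) and np.isfinite(ror) and ror > 0:
                ax.plot([ror], [y], marker="s", color="k", markersize=4)
        ax.set_yticks(ypos)
        ax.set_yticklabels(labels, fontsize=7)
        ax.set_xlim(lo, hi)
        ax.set_xlabel("Reporting odds ratio (log scale)")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
        plt.close(fig)
    return path
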