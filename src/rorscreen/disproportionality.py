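"""Crude disproportionality screen: 2x2 tables, reporting odds ratios, exact inference.

The reporting odds ratio (ROR) compares the odds of a target adverse reaction
among reports naming a drug group of interest against the same odds among
reports naming a reference group, on the standard 2x2 layout::

                         ADR of interest   other (non-target) ADR
    drug of interest            a                  b
    reference drugs             c                  d

    ROR = (a * d) / (b * c)

Inference conditions on both margins: the count ``a`` then follows Fisher's
noncentral hypergeometric law with odds parameter psi, which yields the exact
two-sided p-value (minimum-likelihood rule) and exact (Cornfield-type)
confidence limits obtained by inverting the conditional tails:

    lower limit:  Pr(A >= a | psi) = alpha / 2
    upper limit:  Pr(A <= a | psi) = alpha / 2

A signal is declared for the drug of interest when the lower 95% limit exceeds
1, and for the reference when the upper limit stays below 1.

Zero cells are reported with the conventions used in disproportionality
screens (0, +inf, or undefined) rather than continuity-corrected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .drug_classes import DrugClass, DrugClassTable, SgaGroup

if TYPE_CHECKING:  # pragma: no cover
    from .case_pipeline import AnalysisSet

__all__ = [
    "ContingencyTable",
    "Signal",
    "RorResult",
    "DrugGroup",
    "ScreenSpec",
    "crude_ror",
    "fisher_exact_p",
    "exact_ci",
    "woolf_ci",
    "conditional_mle",
    "detect_signal",
    "build_contingency",
    "run_screen",
    "screen_from_cells",
    "default_screen_specs",
    "format_screen_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of the screen's 2x2 layout (all nonnegative integers)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


class Signal(str, enum.Enum):
    drug_of_interest = "drug_of_interest"
    reference = "reference"
    none = "none"
    undetermined = "undetermined"


@dataclass(frozen=True)
class RorResult:
    ror: float  # nan when undefined
    ci_low: float | None
    ci_high: float | None
    p_value: float
    signal: Signal
    alpha: float = 0.05


def crude_ror(t: ContingencyTable) -> float:
    """Sample cross-product odds ratio with zero-cell conventions.

    Returns nan when no information exists about the target-ADR contrast
    (both target cells zero, or both non-target cells zero).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        return math.nan
    if (a == 0 and b == 0) or (c == 0 and d == 0):
        return math.nan  # an empty drug-group row carries no contrast
    if a == 0 or d == 0:
        return 0.0
    if b == 0 or c == 0:
        return math.inf
    return (a * d) / (b * c)


def fisher_exact_p(t: ContingencyTable) -> float:
    """Two-sided exact p under odds ratio 1 (minimum-likelihood summation)."""
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def _support_and_logcoef(t: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support of the conditional count and log binomial-product coefficients."""
    n_total = t.n
    row1 = t.a + t.b
    col1 = t.a + t.c
    lo = max(0, col1 - (n_total - row1))
    hi = min(row1, col1)
    k = np.arange(lo, hi + 1)
    logcoef = (
        special.gammaln(row1 + 1)
        - special.gammaln(k + 1)
        - special.gammaln(row1 - k + 1)
        + special.gammaln(n_total - row1 + 1)
        - special.gammaln(col1 - k + 1)
        - special.gammaln(n_total - row1 - (col1 - k) + 1)
    )
    return k, logcoef


def _tail_ge(a: int, k: np.ndarray, logcoef: np.ndarray, log_psi: float) -> float:
    """Pr(A >= a | psi) on the conditional law, max-shifted for stability."""
    logw = logcoef + k * log_psi
    w = np.exp(logw - logw.max())
    i = int(a - k[0])
    return float(w[i:].sum() / w.sum())


def _tail_le(a: int, k: np.ndarray, logcoef: np.ndarray, log_psi: float) -> float:
    logw = logcoef + k * log_psi
    w = np.exp(logw - logw.max())
    i = int(a - k[0])
    return float(w[: i + 1].sum() / w.sum())


def _solve_monotone(f, lo: float, hi: float) -> float:
    """Expand [lo, hi] until f brackets 0, then brentq; f monotone in log psi."""
    flo, fhi = f(lo), f(hi)
    for _ in range(80):
        if flo == 0.0:
            return lo
        if fhi == 0.0:
            return hi
        if flo * fhi < 0:
            break
        if abs(flo) < abs(fhi):
            lo -= 20.0
            flo = f(lo)
        else:
            hi += 20.0
            fhi = f(hi)
    else:  # pragma: no cover - tails are strictly monotone, bracket must appear
        raise RuntimeError("failed to bracket exact-CI root")
    return optimize.brentq(f, lo, hi, xtol=1e-9)


def exact_ci(t: ContingencyTable, alpha: float = 0.05) -> tuple[float, float] | None:
    """Exact conditional (Cornfield) confidence limits for the odds ratio.

    Returns ``None`` when the conditional support is a single point (a margin
    is zero), where the data carry no information about the odds ratio. At the
    support boundaries the one-sided conventions apply: lower limit 0 when
    ``a`` is minimal, upper limit +inf when ``a`` is maximal.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    k, logcoef = _support_and_logcoef(t)
    if len(k) == 1:
        return None
    a = t.a
    half = alpha / 2.0

    # Haldane-corrected Woolf interval seeds the bracket (pure speed-up: the
    # expansion loop guarantees correctness regardless of the seed).
    ah, bh, ch, dh = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
    center = math.log((ah * dh) / (bh * ch))
    spread = 3.0 * math.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh) + 1.0

    if a == k[0]:
        low = 0.0
    else:
        low = math.exp(
            _solve_monotone(
                lambda s: _tail_ge(a, k, logcoef, s) - half,
                center - spread,
                center + spread,
            )
        )
    if a == k[-1]:
        high = math.inf
    else:
        high = math.exp(
            _solve_monotone(
                lambda s: half - _tail_le(a, k, logcoef, s),
                center - spread,
                center + spread,
            )
        )
    return low, high


def conditional_mle(t: ContingencyTable) -> float:
    """Conditional maximum-likelihood odds ratio (solves E[A | psi] = a)."""
    k, logcoef = _support_and_logcoef(t)
    if len(k) == 1:
        return math.nan
    a = t.a
    if a == k[0]:
        return 0.0
    if a == k[-1]:
        return math.inf

    def mean_minus_a(log_psi: float) -> float:
        logw = logcoef + k * log_psi
        w = np.exp(logw - special.logsumexp(logw))
        return float(np.dot(w, k)) - a

    return math.exp(_solve_monotone(mean_minus_a, -40.0, 40.0))


def woolf_ci(t: ContingencyTable, alpha: float = 0.05) -> tuple[float, float] | None:
    """Asymptotic log-scale (Woolf) interval; None when any cell is zero."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return None
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def detect_signal(ci_low: float | None, ci_high: float | None) -> Signal:
    """Classify a 95% interval against the null odds ratio of 1."""
    if ci_low is None or ci_high is None:
        return Signal.undetermined
    if isinstance(ci_low, float) and math.isnan(ci_low):
        return Signal.undetermined
    if isinstance(ci_high, float) and math.isnan(ci_high):
        return Signal.undetermined
    if ci_low > 1.0:
        return Signal.drug_of_interest
    if ci_high < 1.0:
        return Signal.reference
    return Signal.none


def analyze_table(
    t: ContingencyTable, alpha: float = 0.05, ci_method: str = "exact",
    include_p: bool = True,
) -> RorResult:
    """Full crude analysis of one 2x2 table.

    Screens conventionally report no interval when the point estimate itself
    is degenerate (0, +inf or undefined from a zero target cell): such rows
    print "0 NA-NA" / "NA NA-NA" and classify as undetermined.
    """
    ror = crude_ror(t)
    if ci_method == "exact":
        ci = exact_ci(t, alpha)
    elif ci_method == "woolf":
        ci = woolf_ci(t, alpha)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    if not (isinstance(ror, float) and math.isfinite(ror) and ror > 0):
        ci = None
    p = fisher_exact_p(t) if include_p else math.nan
    if ci is None:
        return RorResult(ror, None, None, p, Signal.undetermined, alpha)
    return RorResult(ror, ci[0], ci[1], p, detect_signal(*ci), alpha)


# --------------------------------------------------------------------------
# screen assembly


class DrugGroup(str, enum.Enum):
    """Drug-group selectors used as screen rows and references."""

    fga = "FGAs"
    sga_total = "SGAs total"
    sga_g1 = "SGA group 1"
    sga_g2 = "SGA group 2"
    sga_g3 = "SGA group 3"
    sga_g4 = "SGA group 4"
    non_antipsychotics = "Non-antipsychotics"


_GROUP_PRED = {
    DrugGroup.fga: lambda cls: cls.drug_class is DrugClass.FGA,
    DrugGroup.sga_total: lambda cls: cls.drug_class is DrugClass.SGA,
    DrugGroup.sga_g1: lambda cls: cls.sga_group is SgaGroup.g1,
    DrugGroup.sga_g2: lambda cls: cls.sga_group is SgaGroup.g2,
    DrugGroup.sga_g3: lambda cls: cls.sga_group is SgaGroup.g3,
    DrugGroup.sga_g4: lambda cls: cls.sga_group is SgaGroup.g4,
    DrugGroup.non_antipsychotics: lambda cls: cls.drug_class
    not in (DrugClass.FGA, DrugClass.SGA),
}


def group_mask(names: pd.Series, group: DrugGroup, classes: DrugClassTable) -> np.ndarray:
    pred = _GROUP_PRED[group]
    lookup = {n: pred(classes.classify(n)) for n in names.unique()}
    return names.map(lookup).to_numpy(dtype=bool)


@dataclass(frozen=True)
class ScreenSpec:
    adr_of_interest: str
    drug_of_interest: DrugGroup
    reference: DrugGroup

    def __post_init__(self) -> None:
        if self.drug_of_interest == self.reference:
            raise ValueError("drug of interest and reference must be disjoint groups")


def build_contingency(
    analysis_set: "AnalysisSet", spec: ScreenSpec, classes: DrugClassTable
) -> ContingencyTable:
    """Count analysis units into the screen's 2x2 cells.

    Units whose suspected drug falls in neither selector contribute to no cell.
    """
    units = analysis_set.units
    if len(units) == 0:
        return ContingencyTable(0, 0, 0, 0)
    interest = group_mask(units["generic_name"], spec.drug_of_interest, classes)
    reference = group_mask(units["generic_name"], spec.reference, classes)
    outcome = (units["outcome"] == "adr_of_interest").to_numpy()
    a = int(np.sum(interest & outcome))
    b = int(np.sum(interest & ~outcome))
    c = int(np.sum(reference & outcome))
    d = int(np.sum(reference & ~outcome))
    return ContingencyTable(a, b, c, d)


def default_screen_specs(adr_terms: Iterable[str]) -> list[ScreenSpec]:
    """The full screen grid: 6 groups vs non-antipsychotics, 5 SGA groups vs FGAs."""
    interest_groups = [
        DrugGroup.fga,
        DrugGroup.sga_total,
        DrugGroup.sga_g1,
        DrugGroup.sga_g2,
        DrugGroup.sga_g3,
        DrugGroup.sga_g4,
    ]
    specs = []
    for adr in adr_terms:
        for g in interest_groups:
            specs.append(ScreenSpec(adr, g, DrugGroup.non_antipsychotics))
        for g in interest_groups[1:]:
            specs.append(ScreenSpec(adr, g, DrugGroup.fga))
    return specs


def run_screen(
    analysis_sets: Mapping[str, "AnalysisSet"],
    specs: Iterable[ScreenSpec],
    classes: DrugClassTable,
    alpha: float = 0.05,
    ci_method: str = "exact",
    include_cmle: bool = False,
    include_p: bool = True,
    fdr_adjust: bool = False,
) -> pd.DataFrame:
    """Analyze every screen cell; one output row per (ADR, group, reference).

    A degenerate cell (zero margins) yields an undetermined row rather than
    aborting the screen. With ``fdr_adjust`` a Benjamini-Hochberg adjusted
    p-value column (``p_adj``) is appended across all screen cells; the
    signal rule itself remains CI-based and unadjusted.
    """
    rows = []
    mask_cache: dict[tuple[int, DrugGroup], np.ndarray] = {}

    def _mask(aset: "AnalysisSet", group: DrugGroup) -> np.ndarray:
        key = (id(aset), group)
        if key not in mask_cache:
            mask_cache[key] = group_mask(aset.units["generic_name"], group, classes)
        return mask_cache[key]

    for spec in specs:
        aset = analysis_sets[spec.adr_of_interest]
        if len(aset.units) == 0:
            t = ContingencyTable(0, 0, 0, 0)
        else:
            interest = _mask(aset, spec.drug_of_interest)
            reference = _mask(aset, spec.reference)
            outcome = (aset.units["outcome"] == "adr_of_interest").to_numpy()
            t = ContingencyTable(
                int(np.sum(interest & outcome)),
                int(np.sum(interest & ~outcome)),
                int(np.sum(reference & outcome)),
                int(np.sum(reference & ~outcome)),
            )
        res = analyze_table(t, alpha=alpha, ci_method=ci_method, include_p=include_p)
        row = {
            "adr": spec.adr_of_interest,
            "drug_group": spec.drug_of_interest.value,
            "reference": spec.reference.value,
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "ror": res.ror,
            "ci_low": math.nan if res.ci_low is None else res.ci_low,
            "ci_high": math.nan if res.ci_high is None else res.ci_high,
            "p": res.p_value,
            "signal": res.signal.value,
        }
        if include_cmle:
            row["cmle"] = conditional_mle(t)
        rows.append(row)
    out = pd.DataFrame(rows)
    if fdr_adjust:
        if not include_p:
            raise ValueError("fdr_adjust requires include_p")
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out.attrs["classification_checksum"] = classes.checksum()
    return out


def screen_from_cells(
    cells: pd.DataFrame, alpha: float = 0.05, ci_method: str = "exact"
) -> pd.DataFrame:
    """Analyze externally supplied 2x2 cell counts (columns a, b, c, d).

    This is the reproduction path for published screens whose cell counts are
    printed: feed the cells, get back the full ROR / CI / p / signal rows with
    the same conventions as :func:`run_screen`. Identifier columns present in
    the input (e.g. ``adr``, ``drug_group``) are carried through.
    """
    required = {"a", "b", "c", "d"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table missing column(s) {sorted(missing)}")
    rows = []
    for rec in cells.to_dict("records"):
        t = ContingencyTable(int(rec["a"]), int(rec["b"]), int(rec["c"]), int(rec["d"]))
        res = analyze_table(t, alpha=alpha, ci_method=ci_method)
        out = dict(rec)
        out.update(
            ror=res.ror,
            ci_low=math.nan if res.ci_low is None else res.ci_low,
            ci_high=math.nan if res.ci_high is None else res.ci_high,
            p=res.p_value,
            signal=res.signal.value,
        )
        rows.append(out)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# display formatting (machine columns are never rounded; these are for report
# tables mirroring the usual journal layout)


def format_ror(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if math.isinf(x):
        return "Inf"
    return f"{x:.2f}".rstrip("0").rstrip(".")


def format_ci(low: float, high: float) -> str:
    if any(isinstance(v, float) and math.isnan(v) for v in (low, high)):
        return "NA-NA"
    lo = "0.00" if low == 0 else f"{low:.2f}"
    hi = "Inf" if math.isinf(high) else f"{high:.2f}"
    return f"{lo}-{hi}"


def format_p(p: float) -> str:
    if p < 0.001:
        return "< 0.001"
    if p > 0.99:
        return "> 0.99"
    return f"{p:.2f}" if p >= 0.01 else f"{p:.3f}"


def format_screen_table(screen: pd.DataFrame) -> pd.DataFrame:
    """Human-readable screen table; the machine frame is left untouched."""
    out = screen.copy()
    out["ROR"] = [format_ror(x) for x in screen["ror"]]
    out["95% CI"] = [format_ci(l, h) for l, h in zip(screen["ci_low"], screen["ci_high"])]
    out["p"] = [format_p(p) for p in screen["p"]]
    keep = [c for c in ("adr", "drug_group", "reference", "a", "b", "c", "d") if c in out]
    return out[keep + ["ROR", "95% CI", "p", "signal"]]
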