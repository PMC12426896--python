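"""Covariate-adjusted reporting odds ratios via logistic regression.

The adjusted ROR is the exponentiated exposure coefficient of a binary-outcome
log-odds model

    logit Pr(ADR of interest) = b0 + b_exposure * drug_group
                                + b_age * 1{age >= 60} + b_sex * 1{female}
                                + b_period * 1{2016-2020}
                                + concomitant-use indicators,

fit by maximum likelihood on the same analysis units as the crude screen
(complete cases only: unknown sex/age removed upstream). Confidence limits are
Wald intervals on the log-odds scale. Complete or quasi-separation — a drug
group perfectly predicting the outcome — leaves the likelihood without a
finite maximizer; such fits are flagged and reported with the conventional
0.00 to +inf bounds instead of a spurious finite estimate.

Reference levels: male, age < 60, period 2011-2015, no concomitant use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .disproportionality import DrugGroup, group_mask
from .drug_classes import DrugClassTable

if TYPE_CHECKING:  # pragma: no cover
    from .case_pipeline import AnalysisSet

__all__ = ["AdjustedSpec", "AdjustedResult", "build_design", "fit_logodds", "adjusted_ror"]

#: covariate name -> unit-frame column and coded level
_COVARIATE_CODING = {
    "age_group": ("age_group", "sixty_plus"),
    "sex": ("sex", "female"),
    "period": ("period", "2016-2020"),
    "concomitant_fga": ("conc_fga", True),
    "concomitant_sga": ("conc_sga", True),
    "concomitant_anticholinergic": ("conc_anticholinergic", True),
    "concomitant_lithium": ("conc_lithium", True),
}

DEFAULT_COVARIATES = (
    "age_group",
    "sex",
    "period",
    "concomitant_anticholinergic",
    "concomitant_lithium",
)

#: |log-odds coefficient| beyond which a failed fit is read as separation
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class AdjustedSpec:
    """Exposure contrast and covariate list for one adjusted screen cell.

    The cross-generation co-use covariate is added automatically: concomitant
    FGA use when the exposure group is an SGA selector, concomitant SGA use
    when the exposure is the FGA selector.
    """

    exposure: DrugGroup
    reference: DrugGroup
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05

    def resolved_covariates(self) -> tuple[str, ...]:
        cov = list(self.covariates)
        sga_groups = {
            DrugGroup.sga_total,
            DrugGroup.sga_g1,
            DrugGroup.sga_g2,
            DrugGroup.sga_g3,
            DrugGroup.sga_g4,
        }
        if self.exposure in sga_groups and "concomitant_fga" not in cov:
            cov.insert(0, "concomitant_fga")
        if self.exposure is DrugGroup.fga and "concomitant_sga" not in cov:
            cov.insert(0, "concomitant_sga")
        for name in cov:
            if name not in _COVARIATE_CODING:
                raise ValueError(f"unknown covariate {name!r}")
        return tuple(cov)


@dataclass
class AdjustedResult:
    adjusted_ror: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    separation: bool
    coefficients: dict[str, float] = field(default_factory=dict)
    dropped_columns: tuple[str, ...] = ()


def build_design(
    analysis_set: "AnalysisSet", spec: AdjustedSpec, classes: DrugClassTable
) -> tuple[np.ndarray, pd.DataFrame]:
    """Outcome vector and design frame (constant + exposure + covariates).

    Units outside both the exposure and reference selectors are excluded.
    Covariate columns without variation are dropped with a warning; a constant
    outcome or constant exposure is an error (no estimable contrast).
    """
    units = analysis_set.units
    if analysis_set.for_ror is False:
        raise ValueError("adjusted models require a complete-case analysis set (for_ror=True)")
    exp_mask = group_mask(units["generic_name"], spec.exposure, classes)
    ref_mask = group_mask(units["generic_name"], spec.reference, classes)
    sel = exp_mask | ref_mask
    sub = units[sel]
    exposure = exp_mask[sel].astype(float)

    y = (sub["outcome"] == "adr_of_interest").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has no variation in the selected units")
    if len(np.unique(exposure)) < 2:
        raise ValueError("exposure indicator has no variation in the selected units")

    design = pd.DataFrame({"const": np.ones(len(sub)), "exposure": exposure},
                          index=sub.index)
    dropped = []
    for name in spec.resolved_covariates():
        col, level = _COVARIATE_CODING[name]
        x = (sub[col] == level).to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            dropped.append(name)
            warnings.warn(f"covariate {name!r} has no variation; dropped", stacklevel=2)
            continue
        design[name] = x
    design.attrs["dropped_columns"] = tuple(dropped)
    return y, design


def fit_logodds(
    outcome: np.ndarray, design: pd.DataFrame, alpha: float = 0.05
) -> AdjustedResult:
    """Maximum-likelihood logistic fit; the exposure coefficient is the target.

    When the iteration cap is hit with a diverging exposure coefficient the
    fit is reported as separated: point estimate 0 or +inf by the sign of the
    divergence, bounds 0.00 to +inf, p from the likelihood-ratio-free Wald
    statistic degenerating to ~1 (reported as 1.0).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(outcome, design)
        try:
            fit = model.fit(disp=0, maxiter=100, gtol=1e-8, method="bfgs")
        except Exception:
            fit = model.fit(disp=0, maxiter=100, method="newton", warn_convergence=False)
    params = dict(zip(design.columns, np.asarray(fit.params, dtype=float)))
    beta = params["exposure"]
    retvals = getattr(fit, "mle_retvals", {}) or {}
    converged = bool(retvals.get("converged", True))
    separated = abs(beta) > SEPARATION_BOUND

    if separated:
        point = 0.0 if beta < 0 else math.inf
        return AdjustedResult(
            adjusted_ror=point,
            ci_low=0.0,
            ci_high=math.inf,
            p_value=1.0,
            converged=False,
            separation=True,
            coefficients=params,
            dropped_columns=design.attrs.get("dropped_columns", ()),
        )

    i = list(design.columns).index("exposure")
    se = float(np.sqrt(np.asarray(fit.cov_params())[i, i]))
    zcrit = norm.ppf(1 - alpha / 2)
    ci_low = math.exp(beta - zcrit * se)
    ci_high = math.exp(beta + zcrit * se)
    p = 2 * norm.sf(abs(beta) / se) if se > 0 else math.nan
    return AdjustedResult(
        adjusted_ror=math.exp(beta),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        converged=converged,
        separation=False,
        coefficients=params,
        dropped_columns=design.attrs.get("dropped_columns", ()),
    )


def adjusted_ror(
    analysis_set: "AnalysisSet", spec: AdjustedSpec, classes: DrugClassTable
) -> AdjustedResult:
    """Build the design and fit; the one-call adjusted counterpart of a screen cell."""
    y, design = build_design(analysis_set, spec, classes)
    return fit_logodds(y, design, alpha=spec.alpha)


def adjusted_screen(
    analysis_sets: dict[str, "AnalysisSet"],
    specs: Sequence[tuple[str, AdjustedSpec]],
    classes: DrugClassTable,
) -> pd.DataFrame:
    """Adjusted results for many (ADR, spec) cells; failures become flagged rows."""
    rows = []
    for adr, spec in specs:
        base = {
            "adr": adr,
            "drug_group": spec.exposure.value,
            "reference": spec.reference.value,
        }
        try:
            res = adjusted_ror(analysis_sets[adr], spec, classes)
            base.update(
                adj_ror=res.adjusted_ror,
                adj_ci_low=res.ci_low,
                adj_ci_high=res.ci_high,
                adj_p=res.p_value,
                converged=res.converged,
                separation=res.separation,
            )
        except Exception as exc:  # a failed cell must never abort the screen
            base.update(
                adj_ror=math.nan,
                adj_ci_low=math.nan,
                adj_ci_high=math.nan,
                adj_p=math.nan,
                converged=False,
                separation=False,
                error=str(exc),
            )
        rows.append(base)
    return pd.DataFrame(rows)
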