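import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rorscreen.case_pipeline import curate
from rorscreen.disproportionality import (
    ContingencyTable,
    DrugGroup,
    ScreenSpec,
    Signal,
    build_contingency,
    crude_ror,
    conditional_mle,
    default_screen_specs,
    detect_signal,
    exact_ci,
    fisher_exact_p,
    format_ci,
    format_p,
    format_ror,
    format_screen_table,
    run_screen,
    screen_from_cells,
    woolf_ci,
)
from rorscreen.synthetic_srs import paper_shaped_scenario, generate
from tests import oracles


# ---------------------------------------------------------------- point estimate

@pytest.mark.parametrize(
    "cells,expected",
    [
        ((1, 1, 1, 1), 1.0),
        ((2, 3, 1, 4), (2 * 4) / (3 * 1)),
        ((0, 5, 3, 7), 0.0),
        ((3, 5, 0, 7), math.inf),
        ((0, 5, 0, 7), math.nan),
        ((2, 0, 3, 0), math.nan),
        ((5, 0, 3, 7), math.inf),
        ((2, 5, 3, 0), 0.0),
    ],
)
def test_crude_ror_conventions(cells, expected):
    got = crude_ror(ContingencyTable(*cells))
    if isinstance(expected, float) and math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == expected


@settings(max_examples=60, derandomize=True)
@given(st.tuples(*[st.integers(1, 30)] * 4))
def test_ror_reciprocal_under_selector_swap(cells):
    a, b, c, d = cells
    r1 = crude_ror(ContingencyTable(a, b, c, d))
    r2 = crude_ror(ContingencyTable(c, d, a, b))
    assert r1 * r2 == pytest.approx(1.0, rel=1e-12)


# ---------------------------------------------------------------- exact p

def test_fisher_p_degenerate_margin_is_one():
    assert fisher_exact_p(ContingencyTable(0, 4, 0, 6)) == 1.0


def test_fisher_p_strong_signal_below_point_001():
    assert fisher_exact_p(ContingencyTable(10, 100, 5, 500)) < 0.001


@settings(max_examples=150, derandomize=True)
@given(st.tuples(*[st.integers(0, 12)] * 4))
def test_fisher_p_matches_enumeration(cells):
    t = ContingencyTable(*cells)
    assert fisher_exact_p(t) == pytest.approx(
        oracles.fisher_p_enumeration(*cells), abs=1e-12
    )


# ---------------------------------------------------------------- exact CI

def test_symmetric_table_bounds_reciprocal():
    low, high = exact_ci(ContingencyTable(1, 1, 1, 1))
    assert low * high == pytest.approx(1.0, abs=1e-6)


def test_boundary_conventions():
    low, high = exact_ci(ContingencyTable(0, 5, 3, 7))
    assert low == 0.0 and math.isfinite(high)
    low, high = exact_ci(ContingencyTable(5, 0, 3, 7))
    assert math.isinf(high) and low > 0
    assert exact_ci(ContingencyTable(0, 5, 0, 7)) is None


def test_exact_ci_alpha_validation():
    with pytest.raises(ValueError):
        exact_ci(ContingencyTable(1, 1, 1, 1), alpha=1.5)


@settings(max_examples=120, derandomize=True, deadline=None)
@given(st.tuples(*[st.integers(0, 10)] * 4))
def test_exact_ci_matches_bisection_oracle(cells):
    t = ContingencyTable(*cells)
    got = exact_ci(t)
    want = oracles.exact_ci_bisection(*cells)
    if want is None:
        assert got is None
        return
    for g, w in zip(got, want):
        if math.isinf(w) or w == 0.0:
            assert g == w
        else:
            assert g == pytest.approx(w, rel=1e-6)


def test_exact_ci_matches_scipy_conditional():
    from scipy.stats.contingency import odds_ratio

    for cells in [(12, 7, 4, 19), (186, 914, 220, 13510), (3, 30, 9, 14)]:
        t = ContingencyTable(*cells)
        got = exact_ci(t)
        ref = odds_ratio(t.as_array(), kind="conditional").confidence_interval()
        assert got[0] == pytest.approx(ref.low, rel=1e-6)
        assert got[1] == pytest.approx(ref.high, rel=1e-6)


def test_exact_ci_monotone_in_a():
    """Shifting a unit from b to a (margins a+b, c+d fixed... support permitting)
    never decreases either bound."""
    b0, c, d = 20, 8, 30
    prev = (0.0, 0.0)
    for a in range(1, 15):
        ci = exact_ci(ContingencyTable(a, b0 - a + 14, c, d))
        assert ci[0] >= prev[0] - 1e-12
        prev = ci


def test_exact_ci_approaches_woolf_for_large_cells():
    t = ContingencyTable(150, 400, 120, 500)
    ex = exact_ci(t)
    wf = woolf_ci(t)
    width_ex = math.log(ex[1]) - math.log(ex[0])
    width_wf = math.log(wf[1]) - math.log(wf[0])
    assert abs(width_ex - width_wf) / width_wf < 0.05


def test_conditional_mle_close_to_scipy():
    from scipy.stats.contingency import odds_ratio

    t = ContingencyTable(12, 7, 4, 19)
    assert conditional_mle(t) == pytest.approx(
        odds_ratio(t.as_array(), kind="conditional").statistic, rel=1e-6
    )


# ---------------------------------------------------------------- signal rule

@pytest.mark.parametrize(
    "ci,expected",
    [
        ((125.64, 188.34), Signal.drug_of_interest),
        ((0.35, 0.52), Signal.reference),
        ((0.86, 9.67), Signal.none),
        ((None, None), Signal.undetermined),
        ((math.nan, math.nan), Signal.undetermined),
        ((0.0, math.inf), Signal.none),
    ],
)
def test_detect_signal(ci, expected):
    assert detect_signal(*ci) is expected


def test_signal_consistent_with_exact_p_small_tables():
    """Where the exact CI excludes 1, the minlike exact p is (almost always)
    below alpha; discrepancies on small supports are allowed to be marginal
    only in the conservative direction (signal without p < alpha never by a
    wide margin)."""
    for a, b, c, d in oracles.all_tables(18, total_min=16):
        t = ContingencyTable(a, b, c, d)
        ci = exact_ci(t)
        if ci is None:
            continue
        sig = detect_signal(*ci)
        if sig is Signal.drug_of_interest:
            # exact tests and exact CIs can disagree marginally near the
            # boundary; the CI-based signal must still be near-significant
            assert fisher_exact_p(t) < 0.06


# ---------------------------------------------------------------- screen assembly

def _screen_sets(n=6000, seed=11):
    cfg = paper_shaped_scenario(n_reports=n, seed=seed)
    db = generate(cfg)
    classes = cfg.class_table()
    sets, _ = curate(db.cases(), classes=classes)
    return db, cfg, classes, sets


def test_build_contingency_counts_and_disjointness(small_cases, vocab, classes):
    from rorscreen.case_pipeline import apply_exclusions, build_analysis_set

    retained, _ = apply_exclusions(small_cases, vocab, classes)
    aset = build_analysis_set(small_cases, retained, "tardive dyskinesia", vocab, classes)
    t = build_contingency(
        aset,
        ScreenSpec("tardive dyskinesia", DrugGroup.fga, DrugGroup.non_antipsychotics),
        classes,
    )
    # c01 haloperidol TD -> a; references c04 + c08: c04 acetaminophen -> d,
    # c08 aripiprazole is SGA so neither cell
    assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)
    t2 = build_contingency(
        aset,
        ScreenSpec("tardive dyskinesia", DrugGroup.sga_total, DrugGroup.fga),
        classes,
    )
    assert (t2.a, t2.b, t2.c, t2.d) == (1, 1, 1, 0)


def test_screen_grid_cardinality_and_checksum():
    db, cfg, classes, sets = _screen_sets()
    specs = default_screen_specs(sorted(sets))
    out = run_screen(sets, specs, classes, include_p=False)
    assert len(out) == 13 * (6 + 5)
    assert out.attrs["classification_checksum"] == classes.checksum()
    assert set(out.columns) >= {"adr", "drug_group", "reference", "a", "b", "c", "d",
                                "ror", "ci_low", "ci_high", "p", "signal"}


def test_screen_contingency_matches_pandas_bookkeeping():
    """Screen cells equal counts recomputed independently from generator truth."""
    db, cfg, classes, sets = _screen_sets(n=4000, seed=11)
    units = sets["tardive dyskinesia"].units
    fga_names = {"haloperidol", "chlorpromazine", "levomepromazine", "sulpiride"}
    interest = units.generic_name.isin(fga_names)
    outcome = units.outcome == "adr_of_interest"
    expected_a = int((interest & outcome).sum())
    t = build_contingency(
        sets["tardive dyskinesia"],
        ScreenSpec("tardive dyskinesia", DrugGroup.fga, DrugGroup.non_antipsychotics),
        classes,
    )
    assert t.a == expected_a


# ---------------------------------------------------------------- cells path

def test_screen_from_cells_edge_rows():
    cells = pd.DataFrame(
        {
            "label": ["zero-interest", "double-zero", "plain"],
            "a": [0, 0, 12],
            "b": [500, 500, 400],
            "c": [5, 0, 6],
            "d": [8000, 8000, 900],
        }
    )
    out = screen_from_cells(cells)
    zero = out[out.label == "zero-interest"].iloc[0]
    assert zero.ror == 0.0 and math.isnan(zero.ci_low) and zero.p > 0.99
    dz = out[out.label == "double-zero"].iloc[0]
    assert math.isnan(dz.ror)
    plain = out[out.label == "plain"].iloc[0]
    assert plain.ror == pytest.approx((12 * 900) / (400 * 6))


def test_screen_from_cells_requires_cells():
    with pytest.raises(ValueError, match="missing"):
        screen_from_cells(pd.DataFrame({"a": [1], "b": [2], "c": [3]}))


# ---------------------------------------------------------------- formatting

@pytest.mark.parametrize(
    "value,expected",
    [(153.9000234, "153.9"), (95.3, "95.3"), (26.0, "26"), (0.62, "0.62"),
     (math.nan, "NA"), (math.inf, "Inf")],
)
def test_format_ror(value, expected):
    assert format_ror(value) == expected


def test_format_ci_and_p():
    assert format_ci(math.nan, math.nan) == "NA-NA"
    assert format_ci(0.0, math.inf) == "0.00-Inf"
    assert format_ci(125.639, 188.341) == "125.64-188.34"
    assert format_p(0.0004) == "< 0.001"
    assert format_p(0.997) == "> 0.99"
    assert format_p(0.064999) == "0.06"
    assert format_p(0.005) == "0.005"


def test_display_rounding_leaves_machine_frame_untouched():
    db, cfg, classes, sets = _screen_sets(n=3000, seed=2)
    out = run_screen(sets, default_screen_specs(["tardive dyskinesia"]), classes)
    before = out.copy(deep=True)
    fmt = format_screen_table(out)
    pd.testing.assert_frame_equal(out, before)
    assert "ROR" in fmt.columns and "ror" not in fmt.columns


def test_fdr_adjusted_column_optional():
    db, cfg, classes, sets = _screen_sets(n=3000, seed=8)
    specs = default_screen_specs(["tardive dyskinesia", "akathisia"])
    plain = run_screen(sets, specs, classes)
    assert "p_adj" not in plain.columns
    adj = run_screen(sets, specs, classes, fdr_adjust=True)
    assert "p_adj" in adj.columns
    # BH never decreases a p-value and preserves the [0, 1] range
    assert (adj.p_adj >= adj.p - 1e-12).all() and (adj.p_adj <= 1.0).all()
    with pytest.raises(ValueError, match="include_p"):
        run_screen(sets, specs, classes, include_p=False, fdr_adjust=True)
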