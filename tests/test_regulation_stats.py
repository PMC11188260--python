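"""Shortlisting filters, VST, correlation/trend/enrichment statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nmdkit.stats import (
    DeltaPSIRecord,
    KnockdownContrast,
    ShortlistCutoffs,
    adjust_correlations,
    bh_fdr,
    fisher_enrichment,
    kendall_trend,
    shortlist_regulator_dependent,
    shortlist_responsive,
    test_gene_corr,
    vst_psi,
)


# -- VST --------------------------------------------------------------------


def test_vst_fixed_points():
    assert vst_psi(0.0) == 0.0
    assert vst_psi(1.0) == pytest.approx(1.0)
    assert vst_psi(0.5) == pytest.approx(0.5)


@settings(max_examples=100, deadline=None)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_vst_is_monotone_and_symmetric(x, y):
    if x < y:
        assert vst_psi(x) < vst_psi(y)
    # abs tolerance reflects sqrt/arcsin conditioning near the endpoints
    assert vst_psi(1.0 - x) == pytest.approx(1.0 - vst_psi(x), abs=1e-7)


def test_vst_rejects_out_of_range():
    with pytest.raises(ValueError):
        vst_psi(1.2)


# -- correlation ------------------------------------------------------------


def test_nr_event_perfect_correlation():
    psi = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
    expr = vst_psi(psi)  # expression tracks VST_PSI exactly
    res = test_gene_corr("e", "NR", psi, expr)
    assert res.r == pytest.approx(1.0)


def test_ns_orientation_mirrors_nr_on_complemented_psi():
    rng = np.random.default_rng(42)
    psi = rng.uniform(0.05, 0.95, size=6)
    expr = rng.normal(size=6)
    ns = test_gene_corr("e", "NS", psi, expr)
    nr = test_gene_corr("e", "NR", 1.0 - psi, expr)
    # VST symmetry makes the two computations identical
    assert ns.r == pytest.approx(nr.r, abs=1e-12)
    assert ns.p == pytest.approx(nr.p, abs=1e-12)
    assert ns.orientation == "1-VST" and nr.orientation == "VST"


def test_rising_ns_inclusion_with_falling_expression_gives_r_plus_one():
    psi = np.array([0.1, 0.25, 0.45, 0.7, 0.9])
    expr = 1.0 - vst_psi(psi)  # expression falls as inclusion rises
    res = test_gene_corr("e", "NS", psi, expr)
    assert res.r == pytest.approx(1.0)


def test_pearson_p_near_exact_permutation_enumeration():
    """Two-sided t-based p at n=5 sits within the resolution of the exact
    permutation null (granularity 2/120) for a moderately strong r."""
    psi = np.array([0.2, 0.35, 0.45, 0.6, 0.8])
    expr = np.array([0.30, 0.42, 0.40, 0.62, 0.70])
    res = test_gene_corr("e", "NR", psi, expr)
    v = vst_psi(psi)
    r_obs = abs(sps.pearsonr(v, expr)[0])
    count = sum(
        abs(sps.pearsonr(v, perm)[0]) >= r_obs - 1e-12
        for perm in itertools.permutations(expr)
    )
    p_perm = count / math.factorial(5)
    assert res.p == pytest.approx(p_perm, abs=2 / 120)


def test_zero_variance_reported_not_significant():
    res = test_gene_corr("e", "NR", [0.5] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
    assert math.isnan(res.r) and res.p == 1.0
    assert res.reason == "zero-variance" and not res.facilitating


def test_too_few_timepoints_flagged():
    res = test_gene_corr("e", "NS", [0.1, 0.9], [1.0, 2.0])
    assert res.reason == "too-few-timepoints"


def test_fdr_adjustment_within_strata():
    results = [
        test_gene_corr(
            f"e{k}", "NR",
            np.linspace(0.1, 0.9, 5),
            np.linspace(0.1, 0.9, 5) + 0.01 * np.random.default_rng(k).normal(size=5),
        )
        for k in range(6)
    ]
    strata = {f"e{k}": ("NS-CE" if k < 3 else "NR-CE") for k in range(6)}
    adjust_correlations(results, strata)
    for res in results:
        assert res.fdr >= res.p - 1e-15


def test_mean_recovered_r_tracks_planted_rho():
    from nmdkit.fixtures import plant_correlation

    rng = np.random.default_rng(123)
    for rho in (0.0, 0.6):
        rs = []
        for _ in range(200):
            psi = np.sort(rng.uniform(0.05, 0.95, size=5))
            expr = plant_correlation(vst_psi(psi), rho, rng)
            rs.append(test_gene_corr("e", "NR", psi, expr).r)
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs) - rho) <= 3 * se + 1e-9


# -- Kendall trend ----------------------------------------------------------


def test_kendall_tau_limits():
    down = kendall_trend([5.0, 4.0, 3.0, 2.0, 1.0])
    up = kendall_trend([1.0, 2.0, 3.0, 4.0, 5.0])
    assert down.tau == pytest.approx(-1.0) and down.is_downregulated()
    assert up.tau == pytest.approx(1.0) and up.is_upregulated()


def test_kendall_exact_p_matches_full_enumeration():
    values = [10.0, 7.0, 8.0, 3.0, 1.0]
    res = kendall_trend(values)
    taus = [
        sps.kendalltau(range(5), perm).statistic
        for perm in itertools.permutations(values)
    ]
    p_enum = np.mean([abs(t) >= abs(res.tau) - 1e-12 for t in taus])
    assert res.p == pytest.approx(p_enum, abs=1e-12)


def test_all_tied_series_is_null():
    res = kendall_trend([2.0, 2.0, 2.0, 2.0])
    assert res.tau == 0.0 and res.p == 1.0


def test_kendall_needs_four_points():
    with pytest.raises(ValueError):
        kendall_trend([1.0, 2.0, 3.0])


# -- Fisher -----------------------------------------------------------------


def _hypergeom_p_greater(a, b, c, d):
    """Direct summation oracle: P(X >= a) for the top-left cell."""
    n1, n2, m = a + b, c + d, a + c
    denom = math.comb(n1 + n2, m)
    lo = max(0, m - n2)
    hi = min(n1, m)
    return sum(
        math.comb(n1, x) * math.comb(n2, m - x) for x in range(a, hi + 1)
    ) / denom


def test_fisher_diagonal_table_closed_form():
    odds, p = fisher_enrichment([[10, 0], [0, 10]])
    assert p == pytest.approx(1 / math.comb(20, 10))


def test_fisher_balanced_table_exceeds_half():
    _, p = fisher_enrichment([[5, 5], [5, 5]])
    assert p > 0.5
    assert p == pytest.approx(_hypergeom_p_greater(5, 5, 5, 5))


def test_fisher_zero_margin_is_null():
    odds, p = fisher_enrichment([[0, 0], [3, 7]])
    assert p == 1.0 and math.isnan(odds)


@settings(max_examples=200, deadline=None)
@given(st.tuples(*[st.integers(0, 8)] * 4))
def test_fisher_matches_summation_oracle(cells):
    a, b, c, d = cells
    odds, p = fisher_enrichment([[a, b], [c, d]])
    if min(a + b, c + d, a + c, b + d) == 0:
        assert p == 1.0
    else:
        assert p == pytest.approx(_hypergeom_p_greater(a, b, c, d), rel=1e-9)


# -- BH ---------------------------------------------------------------------


def test_bh_single_p_unchanged():
    assert bh_fdr([0.03])[0] == pytest.approx(0.03)


def test_bh_stepup_hand_example():
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_all_ones():
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)


# -- shortlisting -----------------------------------------------------------

EFFECTS = {"ns": "NS", "nr": "NR"}


def _entry_ids(entries):
    return {(e.event_id, e.reason) for e in entries}


def test_shortlist_rules():
    records = [
        DeltaPSIRecord("ns", "c1", 0.15, 0.95, 0.5),  # responsive NS
        DeltaPSIRecord("ns", "c2", 0.05, 0.99, 0.95),  # high-inclusion NS
        DeltaPSIRecord("nr", "c1", 0.2, 0.99, 0.5),  # wrong sign -> excluded
        DeltaPSIRecord("nr", "c2", -0.2, 0.95, 0.5),  # responsive NR
        DeltaPSIRecord("nr", "c3", -0.05, 0.5, 0.05),  # low-inclusion NR
        DeltaPSIRecord("ns", "c3", 0.15, 0.5, 0.5),  # low probability
    ]
    kept = shortlist_responsive(records, EFFECTS)
    assert _entry_ids(kept) == {
        ("ns", "responsive"),
        ("ns", "near-constitutive"),
        ("nr", "responsive"),
        ("nr", "near-constitutive"),
    }


def test_shortlist_stringent_preset():
    rec = DeltaPSIRecord("ns", "c1", 0.15, 0.96, 0.5)
    assert shortlist_responsive([rec], EFFECTS)  # default cutoffs keep it
    assert not shortlist_responsive(
        [rec], EFFECTS, ShortlistCutoffs.stringent()
    )


def test_shortlist_order_invariant_and_deduplicated():
    recs = [
        DeltaPSIRecord("ns", "c1", 0.15, 0.95, 0.5),
        DeltaPSIRecord("nr", "c1", -0.3, 0.99, 0.5),
    ]
    fwd = shortlist_responsive(recs + recs, EFFECTS)
    rev = shortlist_responsive(list(reversed(recs)), EFFECTS)
    assert _entry_ids(fwd) == _entry_ids(rev)
    assert len(fwd) == 2


def test_shortlist_warns_on_unknown_event():
    with pytest.warns(UserWarning):
        kept = shortlist_responsive(
            [DeltaPSIRecord("mystery", "c1", 0.5, 0.99, 0.5)], EFFECTS
        )
    assert kept == []


# -- regulator dependence ---------------------------------------------------


def _corr(event_id, r, p):
    from nmdkit.stats import CorrelationResult

    return CorrelationResult(event_id, r, p, 5)


def test_single_kd_esc_has_priority():
    contrasts = [
        KnockdownContrast("e", "NPC", "double", 0.3, 0.95),
        KnockdownContrast("e", "ESC", "single", 0.25, 0.95),
    ]
    calls = shortlist_regulator_dependent(
        contrasts, {"e": _corr("e", -0.5, 0.002)}
    )
    assert calls[0].dependent and calls[0].source == "single:ESC"


def test_matching_signs_excluded():
    contrasts = [KnockdownContrast("e", "ESC", "single", 0.3, 0.99)]
    calls = shortlist_regulator_dependent(
        contrasts, {"e": _corr("e", 0.4, 0.01)}
    )
    assert not calls[0].dependent
    assert calls[0].reason == "correlation-sign-matches-dpsi"


def test_opposite_signs_included():
    contrasts = [KnockdownContrast("e", "ESC", "single", 0.3, 0.99)]
    calls = shortlist_regulator_dependent(
        contrasts, {"e": _corr("e", -0.5, 0.002)}
    )
    assert calls[0].dependent


def test_missing_timecourse_correlation_excluded():
    contrasts = [KnockdownContrast("e", "ESC", "single", 0.3, 0.99)]
    calls = shortlist_regulator_dependent(contrasts, {})
    assert not calls[0].dependent
    assert calls[0].reason == "no-timecourse-correlation"
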