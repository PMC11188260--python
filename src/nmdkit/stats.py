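"""Splicing-regulation statistics: shortlisting, correlation, trends,
enrichment and multiple-testing correction.

PSI values are fractions in [0, 1] throughout. The variance-stabilizing
transform for proportions is the arcsine-square-root with a 2/pi factor so
that the transformed scale stays inside [0, 1]:

    VST_PSI = 2 * arcsin(sqrt(PSI)) / pi

The splicing-expression statistic correlates variance-stabilized gene
expression with VST_PSI for NMD-repressing events and with 1 - VST_PSI for
NMD-stimulating events, so that a positive coefficient always means "the
NMD-protective splicing pattern tracks expression".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# -- records ---------------------------------------------------------------


@dataclass
class PSIRecord:
    event_id: str
    sample_id: str
    condition: str
    timepoint: float
    psi: float

    def __post_init__(self):
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi must be in [0,1], got {self.psi}")


@dataclass
class DeltaPSIRecord:
    """One Whippet-style contrast row (CHX-DMSO, Nucleus-Cytoplasm, KD-control)."""

    event_id: str
    contrast: str
    dpsi: float
    probability: float
    psi_mean: float | None = None

    def __post_init__(self):
        if not -1.0 <= self.dpsi <= 1.0:
            raise ValueError(f"dpsi must be in [-1,1], got {self.dpsi}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0,1]")


@dataclass
class CorrelationResult:
    event_id: str
    r: float
    p: float
    n: int
    fdr: float = math.nan
    orientation: str = "VST"  # VST (NR) or 1-VST (NS)
    low_power: bool = False
    reason: str = ""

    @property
    def facilitating(self) -> bool:
        """Significant positive correlation of the protective pattern with
        expression (r > 0, p < 0.05, FDR < 0.1)."""
        return (
            np.isfinite(self.r)
            and self.r > 0
            and self.p < 0.05
            and self.fdr < 0.1
        )


@dataclass
class TrendResult:
    series_id: str
    tau: float
    p: float
    n: int

    def is_downregulated(self, tau_cut: float = -0.75, p_cut: float = 0.05):
        return self.tau < tau_cut and self.p < p_cut

    def is_upregulated(self, tau_cut: float = 0.75, p_cut: float = 0.05):
        return self.tau > tau_cut and self.p < p_cut


# -- transforms ------------------------------------------------------------


def vst_psi(psi):
    """Arcsine-square-root VST mapping [0,1] -> [0,1]; fixed points 0, 1/2, 1."""
    arr = np.asarray(psi, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("PSI values must lie in [0, 1]")
    out = 2.0 * np.arcsin(np.sqrt(arr)) / np.pi
    return float(out) if np.isscalar(psi) else out


def inverse_vst_psi(v):
    arr = np.asarray(v, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("VST values must lie in [0, 1]")
    out = np.sin(arr * np.pi / 2.0) ** 2
    return float(out) if np.isscalar(v) else out


# -- shortlisting ----------------------------------------------------------


@dataclass
class ShortlistCutoffs:
    """Responsiveness cutoffs; the stringent preset is |dPSI|>0.25, p>0.95."""

    dpsi: float = 0.1
    prob: float = 0.9
    high: float = 0.9
    low: float = 0.1

    @classmethod
    def stringent(cls) -> "ShortlistCutoffs":
        return cls(dpsi=0.25, prob=0.95)


@dataclass
class ShortlistEntry:
    event_id: str
    contrast: str
    nmd_effect: str
    reason: str  # responsive | near-constitutive


def shortlist_responsive(
    records: list[DeltaPSIRecord],
    effects: dict[str, str],
    cutoffs: ShortlistCutoffs | None = None,
) -> list[ShortlistEntry]:
    """Retain NS events with dPSI above / NR events with dPSI below the
    cutoff at high posterior probability, plus the near-constitutive rule:
    NS events with mean PSI > high and NR events with mean PSI < low are kept
    regardless, since they cannot shift splicing much but may still be
    regulated at the gene level."""
    cut = cutoffs or ShortlistCutoffs()
    seen: set[tuple[str, str]] = set()
    out: list[ShortlistEntry] = []
    for rec in records:
        eff = effects.get(rec.event_id)
        if eff is None:
            warnings.warn(
                f"ΔPSI record for uncatalogued event {rec.event_id}; skipped",
                stacklevel=2,
            )
            continue
        if eff not in ("NS", "NR") or (rec.event_id, rec.contrast) in seen:
            continue
        seen.add((rec.event_id, rec.contrast))
        responsive = rec.probability > cut.prob and (
            rec.dpsi > cut.dpsi if eff == "NS" else rec.dpsi < -cut.dpsi
        )
        near_const = rec.psi_mean is not None and (
            rec.psi_mean > cut.high if eff == "NS" else rec.psi_mean < cut.low
        )
        if responsive:
            out.append(
                ShortlistEntry(rec.event_id, rec.contrast, eff, "responsive")
            )
        elif near_const:
            out.append(
                ShortlistEntry(
                    rec.event_id, rec.contrast, eff, "near-constitutive"
                )
            )
    out.sort(key=lambda e: (e.event_id, e.contrast))
    return out


# -- correlation and trend statistics --------------------------------------


def test_gene_corr(
    event_id: str,
    nmd_effect: str,
    psi_series,
    expr_series,
    min_n: int = 3,
    psi_is_vst: bool = False,
) -> CorrelationResult:
    """Pearson correlation of the NMD-protective splicing pattern with
    (variance-stabilized) gene expression across matched timepoints.

    ``expr_series`` is assumed already variance-stabilized (or otherwise
    transformed); PSI fractions are VST-transformed here unless
    ``psi_is_vst``. Orientation: VST_PSI for NR events, 1 - VST_PSI for NS.
    """
    if nmd_effect not in ("NS", "NR"):
        raise ValueError("event must be NMD-stimulating (NS) or -repressing (NR)")
    psi = np.asarray(psi_series, dtype=float)
    expr = np.asarray(expr_series, dtype=float)
    if psi.shape != expr.shape:
        raise ValueError("psi and expression series must align")
    n = psi.size
    orientation = "1-VST" if nmd_effect == "NS" else "VST"
    if n < min_n:
        return CorrelationResult(
            event_id, math.nan, math.nan, n, orientation=orientation,
            reason="too-few-timepoints",
        )
    v = psi if psi_is_vst else vst_psi(psi)
    protective = 1.0 - v if nmd_effect == "NS" else v
    if np.ptp(protective) == 0 or np.ptp(expr) == 0:
        return CorrelationResult(
            event_id, math.nan, 1.0, n, orientation=orientation,
            low_power=n < 5, reason="zero-variance",
        )
    r, p = sps.pearsonr(protective, expr)
    return CorrelationResult(
        event_id, float(r), float(p), n, orientation=orientation,
        low_power=n < 5,
    )


# the leading "test" is domain vocabulary (a statistical test), not a
# pytest case
test_gene_corr.__test__ = False  # type: ignore[attr-defined]


def adjust_correlations(
    results: list[CorrelationResult],
    strata: dict[str, str] | None = None,
) -> list[CorrelationResult]:
    """BH-adjust correlation p-values, by default within strata (e.g.
    NS-CE / NR-CE / other) supplied as event_id -> stratum; pass ``None``
    for a single global adjustment."""
    groups: dict[str, list[CorrelationResult]] = {}
    for res in results:
        key = (strata or {}).get(res.event_id, "all")
        groups.setdefault(key, []).append(res)
    for members in groups.values():
        testable = [m for m in members if np.isfinite(m.p)]
        if not testable:
            continue
        adj = bh_fdr([m.p for m in testable])
        for m, q in zip(testable, adj):
            m.fdr = float(q)
    return results


def kendall_trend(values, times=None, series_id: str = "") -> TrendResult:
    """Kendall tau-b of a series against time (or its own order).

    Exact two-sided p-value by enumeration for n <= 8 without ties,
    tie-corrected normal approximation otherwise; an all-tied series is
    reported as tau 0, p 1.
    """
    y = np.asarray(values, dtype=float)
    t = np.arange(y.size) if times is None else np.asarray(times, dtype=float)
    if y.size < 4:
        raise ValueError("trend test needs at least 4 points")
    if np.ptp(y) == 0:
        return TrendResult(series_id, 0.0, 1.0, y.size)
    has_ties = len(set(y)) < y.size or len(set(t)) < t.size
    method = "exact" if (y.size <= 8 and not has_ties) else "asymptotic"
    res = sps.kendalltau(t, y, method=method)
    return TrendResult(series_id, float(res.statistic), float(res.pvalue), y.size)


def fisher_enrichment(table, alternative: str = "greater"):
    """One-sided Fisher's exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)``; a zero margin gives p = 1 with undefined
    (NaN) odds ratio.
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("expected a non-negative 2x2 table")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        return math.nan, 1.0
    odds, p = sps.fisher_exact(tab, alternative=alternative)
    return float(odds), float(p)


def bh_fdr(pvals):
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# -- regulator (e.g. PTBP1) dependence -------------------------------------


@dataclass
class KnockdownContrast:
    """A KD-vs-control ΔPSI observation in one cell type."""

    event_id: str
    cell_type: str  # ESC | NPC
    knockdown: str  # single | double
    dpsi: float
    probability: float


@dataclass
class RegulatorCall:
    event_id: str
    dependent: bool
    source: str = ""  # e.g. "single:ESC"
    dpsi_kd: float = math.nan
    r: float = math.nan
    reason: str = ""


_PRIORITY = {
    ("single", "ESC"): 0,
    ("single", "NPC"): 1,
    ("double", "ESC"): 2,
    ("double", "NPC"): 3,
}


def shortlist_regulator_dependent(
    contrasts: list[KnockdownContrast],
    timecourse_corr: dict[str, CorrelationResult],
    dpsi_cut: float = 0.1,
    prob_cut: float = 0.9,
    p_cut: float = 0.05,
) -> list[RegulatorCall]:
    """Events dependent on a splicing regulator (the PTBP1 workflow).

    An event qualifies iff (a) it responds to the knockdown in at least one
    contrast (|dPSI| > 0.1, probability > 0.9), annotated from the
    highest-priority significant contrast (single-KD before double-KD, ESC
    before NPC); (b) its PSI correlates with regulator expression across the
    time course (p < 0.05); and (c) the correlation sign is opposite to the
    knockdown dPSI sign, as expected for a direct repressor/activator.
    """
    by_event: dict[str, list[KnockdownContrast]] = {}
    for c in contrasts:
        if abs(c.dpsi) > dpsi_cut and c.probability > prob_cut:
            by_event.setdefault(c.event_id, []).append(c)

    calls = []
    for event_id, sig in sorted(by_event.items()):
        best = min(
            sig, key=lambda c: _PRIORITY.get((c.knockdown, c.cell_type), 99)
        )
        source = f"{best.knockdown}:{best.cell_type}"
        corr = timecourse_corr.get(event_id)
        if corr is None or not np.isfinite(corr.r):
            calls.append(
                RegulatorCall(
                    event_id, False, source, best.dpsi,
                    reason="no-timecourse-correlation",
                )
            )
            continue
        if corr.p >= p_cut:
            calls.append(
                RegulatorCall(
                    event_id, False, source, best.dpsi, corr.r,
                    reason="correlation-not-significant",
                )
            )
            continue
        if math.copysign(1, corr.r) == math.copysign(1, best.dpsi):
            calls.append(
                RegulatorCall(
                    event_id, False, source, best.dpsi, corr.r,
                    reason="correlation-sign-matches-dpsi",
                )
            )
            continue
        calls.append(RegulatorCall(event_id, True, source, best.dpsi, corr.r))
    return calls


# -- expression transform substitute ---------------------------------------


def transform_expression(counts, pseudocount: float = 1.0):
    """log2(1 + median-of-ratios-normalized counts).

    A light-weight stand-in for a model-based variance-stabilizing
    transform of an expression matrix (genes x samples); adequate for
    correlation analyses on toy and medium-size data. Pre-transformed
    matrices can be supplied to the correlation functions directly.
    """
    import pandas as pd

    mat = (
        counts.astype(float)
        if isinstance(counts, pd.DataFrame)
        else pd.DataFrame(np.asarray(counts, dtype=float))
    )
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat.replace(0, np.nan)).mean(axis=1)
    ratios = np.log(mat.replace(0, np.nan)).sub(log_geo, axis=0)
    size_factors = np.exp(ratios.median(axis=0)).fillna(1.0)
    normed = mat.div(size_factors, axis=1)
    return np.log2(pseudocount + normed)
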