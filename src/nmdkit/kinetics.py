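"""Kinetic model of coordinated NMD-dependent and NMD-independent gene
downregulation.

Productive (NMD-escaping) mRNA abundance R(t) follows

    dR/dt = r_t(t) * r_n(t) * v_sr  -  k_dr * R(t),      k_dr = ln2 / t_half

where v_sr is the synthesis rate (molecules/cell/h), r_t in [0,1] scales
synthesis for transcriptional repression and r_n in [0,1] for AS-NMD
repression (the fraction of transcripts spliced productively,
r_n = 1 - PSI_CHX/100). NMD-sensitive isoforms are assumed short-lived and
do not contribute to R. Both repression factors are piecewise-constant
schedules, so R(t) relaxes exponentially toward the segment steady state
R* = r_t * r_n * v_sr / k_dr at rate k_dr on each constant segment.

Four coordination scenarios are modelled: AS-NMD acting alone, or
preceding / coinciding with / following the onset of transcriptional
repression within the day 2-4 window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

HOURS_PER_DAY = 24.0

#: transcriptome-median parameter set: synthesis rate for mouse NIH 3T3
#: cells, half-life for proliferating/differentiating mouse ESCs.
PRESETS = {
    "median": {"v_sr": 1.76, "t_half": 7.08},
    #: averaged over the three experimentally dissected genes
    #: (Fmnl3, Iqgap1, Ripk1)
    "gene-averaged": {"v_sr": 2.63, "t_half": 5.11},
}

#: default repression depths: transcription 1 -> 0.39 (late/early expression
#: ratio of NS-CE mutants), AS-NMD 0.78 -> 0.12 (from early/late PSI_CHX).
DEFAULT_RT = (1.0, 0.39)
DEFAULT_RN = (0.78, 0.12)


def decay_constant(t_half: float) -> float:
    """k_dr = ln2 / t_half (h^-1)."""
    if t_half <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / t_half


def steady_state(v_sr: float, r_t: float, r_n: float, k_dr: float) -> float:
    """R* = r_t * r_n * v_sr / k_dr."""
    if k_dr <= 0:
        raise ValueError("no steady state without decay (k_dr must be > 0)")
    return r_t * r_n * v_sr / k_dr


@dataclass(frozen=True)
class Schedule:
    """Right-continuous piecewise-constant function of time (hours).

    ``values[i]`` applies on ``[breakpoints[i-1], breakpoints[i])`` with
    implicit -inf / +inf outer bounds.
    """

    values: tuple[float, ...]
    breakpoints: tuple[float, ...] = ()

    def __post_init__(self):
        if len(self.values) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more value than breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must increase")
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ValueError("repression factors must lie in [0, 1]")

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls((value,))

    @classmethod
    def step(cls, before: float, after: float, at: float) -> "Schedule":
        return cls((before, after), (at,))

    def __call__(self, t: float) -> float:
        i = np.searchsorted(self.breakpoints, t, side="right")
        return self.values[i]


@dataclass
class ModelParams:
    v_sr: float
    t_half: float
    r_t: Schedule = field(default_factory=lambda: Schedule.constant(1.0))
    r_n: Schedule = field(default_factory=lambda: Schedule.constant(1.0))
    scenario: str = ""

    def __post_init__(self):
        if self.v_sr <= 0:
            raise ValueError("synthesis rate must be positive")
        if self.t_half <= 0:
            raise ValueError("half-life must be positive")

    @property
    def k_dr(self) -> float:
        return decay_constant(self.t_half)

    def synthesis(self, t: float) -> float:
        return self.r_t(t) * self.r_n(t) * self.v_sr

    def initial_steady_state(self, t0: float = 0.0) -> float:
        return steady_state(self.v_sr, self.r_t(t0), self.r_n(t0), self.k_dr)


@dataclass
class Trajectory:
    times: np.ndarray
    R: np.ndarray
    params: ModelParams


def _segment_edges(params: ModelParams, t0: float, t1: float) -> list[float]:
    edges = {t0, t1}
    for b in params.r_t.breakpoints + params.r_n.breakpoints:
        if t0 < b < t1:
            edges.add(b)
    return sorted(edges)


def closed_form(params: ModelParams, t_grid, R0: float | None = None) -> Trajectory:
    """Exact piecewise-exponential solution on constant segments:
    R(t) = R*_i + (R(t_i) - R*_i) exp(-k_dr (t - t_i))."""
    t = np.asarray(t_grid, dtype=float)
    k = params.k_dr
    R0 = params.initial_steady_state(t[0]) if R0 is None else R0
    edges = _segment_edges(params, float(t[0]), float(t[-1]))
    out = np.empty_like(t)
    R_seg = R0
    for lo, hi in zip(edges, edges[1:]):
        Rstar = steady_state(params.v_sr, params.r_t(lo), params.r_n(lo), k)
        mask = (t >= lo) & (t <= hi)
        out[mask] = Rstar + (R_seg - Rstar) * np.exp(-k * (t[mask] - lo))
        R_seg = Rstar + (R_seg - Rstar) * math.exp(-k * (hi - lo))
    return Trajectory(t, out, params)


def simulate(
    params: ModelParams,
    t_grid,
    R0: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Numerically integrate the model with adaptive Runge-Kutta.

    Integration restarts at every schedule breakpoint so discontinuities in
    the synthesis term never cross a solver step.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing, length >= 2")
    k = params.k_dr
    R0 = params.initial_steady_state(t[0]) if R0 is None else R0
    if R0 < 0:
        raise ValueError("initial abundance must be non-negative")
    edges = _segment_edges(params, float(t[0]), float(t[-1]))
    out = np.empty_like(t)
    if t[0] == edges[0]:
        out[t == edges[0]] = R0
    R_seg = R0
    for lo, hi in zip(edges, edges[1:]):
        syn = params.synthesis((lo + hi) / 2.0)
        mask = (t > lo) & (t <= hi)
        eval_pts = t[mask]
        sol = solve_ivp(
            lambda _t, R: syn - k * R,
            (lo, hi),
            [R_seg],
            method="RK45",
            t_eval=np.unique(np.concatenate([eval_pts, [hi]])),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        lookup = dict(zip(sol.t, sol.y[0]))
        out[mask] = [lookup[p] for p in eval_pts]
        R_seg = sol.y[0][-1]
    return Trajectory(t, np.maximum(out, 0.0), params)


def scenario_params(
    scenario: str,
    preset: str = "median",
    asnmd_onset_day: float | None = None,
    transcription_onset_day: float = 3.0,
    r_t_levels: tuple[float, float] = DEFAULT_RT,
    r_n_levels: tuple[float, float] = DEFAULT_RN,
) -> ModelParams:
    """Build the four coordination scenarios.

    ``asnmd-only`` keeps transcription unrepressed; ``asnmd-precedes`` /
    ``coincident`` / ``asnmd-follows`` place the AS-NMD step one day before,
    at, or one day after the transcriptional step (defaults inside the
    day 2-4 window; override the onset days to taste).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    base = PRESETS[preset]
    offsets = {
        "asnmd-only": 0.0,
        "asnmd-precedes": -1.0,
        "coincident": 0.0,
        "asnmd-follows": 1.0,
    }
    if scenario not in offsets:
        raise ValueError(f"unknown scenario {scenario!r}")
    if asnmd_onset_day is None:
        asnmd_onset_day = transcription_onset_day + offsets[scenario]
    r_n = Schedule.step(*r_n_levels, asnmd_onset_day * HOURS_PER_DAY)
    if scenario == "asnmd-only":
        r_t = Schedule.constant(r_t_levels[0])
    else:
        r_t = Schedule.step(
            *r_t_levels, transcription_onset_day * HOURS_PER_DAY
        )
    return ModelParams(
        base["v_sr"], base["t_half"], r_t=r_t, r_n=r_n, scenario=scenario
    )


# -- parameter estimation from data series ---------------------------------


def estimate_rn(psi_chx_percent) -> float:
    """AS-NMD repression factor from NMD-blocked inclusion levels:
    r_n = 1 - mean(PSI_CHX)/100 (PSI in percent)."""
    vals = np.asarray(psi_chx_percent, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one PSI value")
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("PSI percent values must lie in [0, 100]")
    return float(1.0 - vals.mean() / 100.0)


def estimate_rt(late_by_clone, early_by_clone) -> float:
    """Transcriptional repression factor: mean over clones/genes of
    (mean late expression)/(mean early expression)."""
    import warnings

    ratios = []
    for late, early in zip(late_by_clone, early_by_clone, strict=True):
        late_m = float(np.mean(late))
        early_m = float(np.mean(early))
        if early_m <= 0:
            warnings.warn(
                "zero early expression; clone excluded from r_t",
                stacklevel=2,
            )
            continue
        ratios.append(late_m / early_m)
    if not ratios:
        raise ValueError("no usable clones for r_t estimation")
    return float(np.mean(ratios))


def dichotomy_point(
    times,
    series_by_clone,
    threshold: float | None = None,
) -> float | None:
    """Developmental stage preceding the divergence of mutant from WT.

    ``series_by_clone`` holds mutant/WT-normalized expression per clone on a
    shared time grid; the clone-averaged series is compared against
    ``threshold`` (default: median of all pooled values) and the timepoint
    immediately preceding the first exceedance is returned, or ``None`` if
    the threshold is never exceeded (or exceeded already at the first point).
    """
    t = np.asarray(times, dtype=float)
    series = [np.asarray(s, dtype=float) for s in series_by_clone]
    if not series or any(s.size != t.size for s in series) or t.size == 0:
        raise ValueError("need >= 1 clone series matching the time grid")
    if threshold is None:
        threshold = float(np.median(np.concatenate(series)))
    avg = np.mean(series, axis=0)
    above = np.nonzero(avg > threshold)[0]
    if above.size == 0 or above[0] == 0:
        return None
    return float(t[above[0] - 1])


def pooled_median_threshold(series_groups) -> float:
    """Median of all values pooled across genes and clones (the cutoff used
    to place dichotomy points)."""
    flat = np.concatenate([np.ravel(np.asarray(s, float)) for s in series_groups])
    return float(np.median(flat))
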