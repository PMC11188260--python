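"""Intronic-flank conservation scoring of AS-NMD events.

For each event type a fixed intronic sequence context is scored against a
per-base conservation track (PhastCons-style, values in [0, 1]): the
``padding``-nt introns on both sides of a cassette exon, the first and last
``padding`` nt of a retained intron, 2x ``padding`` nt downstream of an
alternative donor and 2x ``padding`` nt upstream of an alternative acceptor
(directions in transcription orientation, anchored on the distal,
event-defining splice site).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import ASEvent
from .models import GenomicInterval


@dataclass
class ConservationScore:
    event_id: str
    intervals: list[GenomicInterval]
    mean_score: float | None
    covered_bases: int
    missing_bases: int
    truncated: bool = False
    reason: str = ""


def flank_intervals(
    event: ASEvent,
    padding: int = 100,
    bounds: tuple[int, int] | None = None,
) -> tuple[list[GenomicInterval], bool]:
    """Intronic windows scored for an event; returns (windows, truncated).

    ``bounds`` optionally clips the windows at neighbouring exon boundaries
    (or chromosome ends); any clipping or an intron shorter than the
    request sets the truncation flag.
    """
    chrom, strand = event.chrom, event.strand
    s, e = event.start, event.end
    raw: list[tuple[int, int]]
    if event.event_type == "CE":
        raw = [(s - padding, s), (e, e + padding)]
    elif event.event_type == "RI":
        if e - s >= 2 * padding:
            raw = [(s, s + padding), (e - padding, e)]
        else:  # short intron: split it without double counting
            mid = s + (e - s) // 2
            raw = [(s, mid), (mid, e)]
    elif event.event_type == "AD":
        # distal donor = extension end in transcription direction
        if strand == "+":
            raw = [(e, e + 2 * padding)]
        else:
            raw = [(s - 2 * padding, s)]
    elif event.event_type == "AA":
        # distal acceptor; window upstream in transcription direction
        if strand == "+":
            raw = [(s - 2 * padding, s)]
        else:
            raw = [(e, e + 2 * padding)]
    else:
        raise ValueError(f"no flank rule for event type {event.event_type!r}")

    want = sum(b - a for a, b in raw)
    lo, hi = bounds if bounds else (0, None)
    clipped = []
    for a, b in raw:
        a2 = max(a, lo)
        b2 = b if hi is None else min(b, hi)
        if a2 < b2:
            clipped.append((a2, b2))
    got = sum(b - a for a, b in clipped)
    truncated = got < want or (
        event.event_type == "RI" and e - s < 2 * padding
    )
    return (
        [GenomicInterval(chrom, a, b, strand) for a, b in clipped],
        truncated,
    )


class BedGraphTrack:
    """Sparse per-base track from bedGraph text (chrom, start, end, value;
    0-based half-open). Uncovered bases read as NaN."""

    def __init__(self, path: str | Path):
        data: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split()[:4]
                data.setdefault(chrom, []).append((int(s), int(e), float(v)))
        self._starts: dict[str, list[int]] = {}
        self._rows: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, rows in data.items():
            rows.sort()
            self._rows[chrom] = rows
            self._starts[chrom] = [r[0] for r in rows]

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        out = np.full(end - start, np.nan)
        rows = self._rows.get(chrom)
        if not rows:
            return out
        i = bisect.bisect_right(self._starts[chrom], start) - 1
        i = max(i, 0)
        while i < len(rows) and rows[i][0] < end:
            s, e, v = rows[i]
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out[lo - start : hi - start] = v
            i += 1
        return out


class BigWigTrack:
    """bigWig-backed track (requires pyBigWig)."""

    def __init__(self, path: str | Path):
        import pyBigWig

        self._bw = pyBigWig.open(str(path))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        return np.asarray(
            self._bw.values(chrom, start, end, numpy=True), dtype=float
        )


def open_track(path: str | Path):
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        return BigWigTrack(path)
    return BedGraphTrack(path)


def mean_conservation(
    event_id: str,
    intervals: list[GenomicInterval],
    track,
    missing_as_zero: bool = False,
    truncated: bool = False,
) -> ConservationScore:
    """Average the track over the windows.

    By default bases without track coverage are excluded from the mean
    (PhastCons gaps are unalignable sequence, not zero conservation) and
    counted in ``missing_bases``; ``missing_as_zero`` switches to imputing 0.
    """
    vals = (
        np.concatenate(
            [track.values(iv.chrom, iv.start, iv.end) for iv in intervals]
        )
        if intervals
        else np.empty(0)
    )
    missing = int(np.isnan(vals).sum())
    if missing_as_zero:
        vals = np.nan_to_num(vals, nan=0.0)
        missing_counted, covered = missing, vals.size
    else:
        missing_counted, covered = missing, vals.size - missing
        vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return ConservationScore(
            event_id, intervals, None, 0, missing_counted,
            truncated=truncated, reason="no-covered-bases",
        )
    return ConservationScore(
        event_id,
        intervals,
        float(vals.mean()),
        covered,
        missing_counted,
        truncated=truncated,
    )


def score_events(
    catalog: list[ASEvent],
    track,
    padding: int = 100,
    missing_as_zero: bool = False,
) -> list[ConservationScore]:
    out = []
    for ev in catalog:
        ivs, trunc = flank_intervals(ev, padding=padding)
        out.append(
            mean_conservation(
                ev.event_id, ivs, track,
                missing_as_zero=missing_as_zero, truncated=trunc,
            )
        )
    return out
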