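"""ORF construction on novel transcripts and the 50-nt NMD rule.

A transcript is called NMD-sensitive when its termination codon ends more
than ``threshold`` (default 50) spliced nucleotides upstream of the last
exon-exon junction. Coding sequences for unannotated isoforms are built by
projecting annotated reference start codons of the same gene onto the
isoform's exon chain and translating in frame to the first stop; there is no
de-novo ORF search unless explicitly requested, because invented ORFs on
assembled transcripts inflate false NMD calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import Genome, spliced_sequence
from .models import (
    AnnotationSet,
    CoordinateError,
    GenomicInterval,
    TranscriptModel,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_PTC_THRESHOLD = 50


@dataclass
class NMDVerdict:
    """Per-transcript NMD call under the 50-nt rule.

    ``dist_stop_to_last_junction`` is measured in spliced (mRNA) nucleotides
    from the anchor (by default the base immediately after the stop codon)
    to the first base of the final exon; positive values mean the stop is
    upstream of the last junction.
    """

    transcript_id: str
    has_cds: bool
    is_nmd: bool
    stop_end_tx: int | None = None
    last_junction_tx: int | None = None
    dist_stop_to_last_junction: int | None = None
    threshold: int = DEFAULT_PTC_THRESHOLD
    reason: str = ""


def _tx_range_to_genomic(
    tx: TranscriptModel, t_start: int, t_end: int
) -> list[GenomicInterval]:
    """Map a spliced offset range [t_start, t_end) back to genomic intervals."""
    pieces: list[tuple[int, int]] = []
    off = 0
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    for e in exons:
        lo = max(t_start, off)
        hi = min(t_end, off + len(e))
        if lo < hi:
            if tx.strand == "+":
                pieces.append((e.start + (lo - off), e.start + (hi - off)))
            else:
                pieces.append((e.end - (hi - off), e.end - (lo - off)))
        off += len(e)
    return [
        GenomicInterval(tx.chrom, s, e, tx.strand) for s, e in sorted(pieces)
    ]


def _cds_start_offset(tx: TranscriptModel) -> int:
    """Spliced offset of the first coding base (requires ``tx.cds``)."""
    assert tx.cds
    gpos = tx.cds[0].start if tx.strand == "+" else tx.cds[-1].end - 1
    return tx.genomic_to_transcript(gpos)


def _cds_end_offset(tx: TranscriptModel) -> int:
    """Spliced offset one past the last coding base (stop end anchor)."""
    assert tx.cds
    gpos = tx.cds[-1].end - 1 if tx.strand == "+" else tx.cds[0].start
    return tx.genomic_to_transcript(gpos) + 1


def reference_start_sites(
    ref_txs: list[TranscriptModel],
) -> list[tuple[int, ...]]:
    """Genomic positions of annotated start-codon triplets, deduplicated."""
    sites: list[tuple[int, ...]] = []
    seen = set()
    for ref in ref_txs:
        if not ref.cds:
            continue
        t0 = _cds_start_offset(ref)
        if _cds_end_offset(ref) - t0 < 6:  # start + stop at minimum
            continue
        triplet = tuple(ref.transcript_to_genomic(t0 + k) for k in range(3))
        if triplet not in seen:
            seen.add(triplet)
            sites.append(triplet)
    return sites


def _project_start(
    tx: TranscriptModel, triplet: tuple[int, ...]
) -> int | None:
    """Transcript offset of a reference start codon, if fully exonic and
    read contiguously (possibly across a shared junction) in ``tx``."""
    try:
        offs = [tx.genomic_to_transcript(g) for g in triplet]
    except CoordinateError:
        return None
    if offs[1] == offs[0] + 1 and offs[2] == offs[0] + 2:
        return offs[0]
    return None


def _scan_stop(seq: str, start: int) -> int | None:
    """Offset of the first in-frame stop codon at/after ``start``; None if
    translation runs off the transcript end."""
    for p in range(start, len(seq) - 2, 3):
        if seq[p : p + 3] in STOP_CODONS:
            return p
    return None


def build_cds(
    tx: TranscriptModel,
    ref_txs_of_gene: list[TranscriptModel],
    genome: Genome,
    denovo: bool = False,
    denovo_min_codons: int = 100,
) -> tuple[TranscriptModel, str]:
    """Attach a CDS to ``tx`` from projected reference start codons.

    Returns ``(transcript, flag)``; the flag is empty on success, else one
    of ``no-start-projected``, ``stop-not-found``, ``no-reference-cds``.
    The 5'-most projectable start is used, and the CDS runs in frame to the
    first stop codon (included).
    """
    sites = reference_start_sites(ref_txs_of_gene)
    candidates = sorted(
        off
        for off in (_project_start(tx, s) for s in sites)
        if off is not None
    )
    seq = spliced_sequence(tx, genome)
    if not candidates:
        if denovo:
            return _build_cds_denovo(tx, seq, denovo_min_codons)
        return tx, ("no-reference-cds" if not sites else "no-start-projected")
    start = candidates[0]
    stop = _scan_stop(seq, start)
    if stop is None:
        return tx, "stop-not-found"
    cds = _tx_range_to_genomic(tx, start, stop + 3)
    return tx.with_cds(cds), ""


def _build_cds_denovo(
    tx: TranscriptModel, seq: str, min_codons: int
) -> tuple[TranscriptModel, str]:
    """Fallback: 5'-most ATG whose ORF reaches a stop and spans >= min_codons."""
    pos = seq.find("ATG")
    while pos != -1:
        stop = _scan_stop(seq, pos)
        if stop is not None and (stop + 3 - pos) // 3 >= min_codons:
            return tx.with_cds(_tx_range_to_genomic(tx, pos, stop + 3)), ""
        pos = seq.find("ATG", pos + 1)
    return tx, "no-start-projected"


def predict_nmd(
    tx: TranscriptModel,
    threshold: int = DEFAULT_PTC_THRESHOLD,
    anchor: str = "stop_end",
) -> NMDVerdict:
    """Apply the 50-nt rule to a transcript with a built or annotated CDS.

    ``anchor`` selects which stop-codon edge the junction distance is
    measured from: ``stop_end`` (base immediately after the stop codon,
    default) or ``stop_start``.
    """
    if anchor not in ("stop_end", "stop_start"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if not tx.cds:
        return NMDVerdict(
            tx.transcript_id, False, False, threshold=threshold,
            reason="no-cds",
        )
    stop_end = _cds_end_offset(tx)
    last_junction = tx.last_junction_offset()
    if last_junction is None:
        return NMDVerdict(
            tx.transcript_id,
            True,
            False,
            stop_end_tx=stop_end,
            threshold=threshold,
            reason="single-exon",
        )
    measured = stop_end if anchor == "stop_end" else stop_end - 3
    dist = last_junction - measured
    return NMDVerdict(
        tx.transcript_id,
        True,
        dist > threshold,
        stop_end_tx=stop_end,
        last_junction_tx=last_junction,
        dist_stop_to_last_junction=dist,
        threshold=threshold,
    )


def annotate_nmd(
    aset: AnnotationSet,
    genome: Genome | None = None,
    threshold: int = DEFAULT_PTC_THRESHOLD,
    anchor: str = "stop_end",
    denovo: bool = False,
) -> tuple[AnnotationSet, dict[str, NMDVerdict]]:
    """Build missing CDSs gene by gene and call NMD on every transcript.

    The call is blind to any input biotype label: transcripts that carry an
    annotated CDS are judged on it directly; the rest get a CDS projected
    from the annotated isoforms of their gene (which requires ``genome``).
    Returns the CDS-completed annotation and a transcript_id -> verdict map.
    """
    out = AnnotationSet(provenance=aset.provenance)
    verdicts: dict[str, NMDVerdict] = {}
    for gene in aset.genes.values():
        refs = [t for t in gene.transcripts if t.cds]
        for tx in gene.transcripts:
            flag = ""
            if not tx.cds:
                if genome is None:
                    tx, flag = tx, "no-genome"
                else:
                    tx, flag = build_cds(tx, refs, genome, denovo=denovo)
            v = predict_nmd(tx, threshold=threshold, anchor=anchor)
            if flag and not v.reason:
                v.reason = flag
            verdicts[tx.transcript_id] = v
            out.add_transcript(tx, gene_name=gene.gene_name)
    return out, verdicts
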