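"""Alternative-splicing event calculus and NMD-effect classification.

Pairs of isoform exon chains are diffed into four event types — cassette
exon (CE), alternative donor (AD, 5' splice site), alternative acceptor
(AA, 3' splice site) and retained intron (RI) — defined in transcription
direction. Each catalogued event is labelled NMD-stimulating (NS) when its
inclusion routes the mRNA into NMD, NMD-repressing (NR) when its inclusion
protects from NMD, or ambiguous when different isoform backgrounds disagree.
Differences not matching the four patterns are reported as ``complex`` and
skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import AnnotationSet, TranscriptModel
from .orf import NMDVerdict


@dataclass
class ASEvent:
    """One splicing difference between two isoforms (or a catalog entry).

    ``included_interval`` is the exon for CE, the retained intron for RI and
    the extension segment for AD/AA, in internal 0-based half-open
    coordinates; ``event_id`` renders them 1-based closed.
    """

    event_type: str  # CE | AD | AA | RI | complex
    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str = ""
    inclusion_tx: str = ""
    skipping_tx: str = ""
    nmd_effect: str = ""  # NS | NR | ambiguous | none
    supporting_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def event_id(self) -> str:
        return (
            f"{self.event_type}:{self.chrom}:{self.start + 1}-{self.end}:"
            f"{self.strand}"
        )

    @property
    def key(self) -> tuple:
        return (self.event_type, self.chrom, self.start, self.end, self.strand)


def _exon_tuples(tx: TranscriptModel) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in tx.exons]


def diff_splice_chains(
    tx_a: TranscriptModel, tx_b: TranscriptModel
) -> list[ASEvent]:
    """Classify the differences between two same-gene isoform exon chains.

    Event patterns (genomic coordinates; donor/acceptor resolved by strand):

    * CE — an intron of one isoform spans exactly one internal exon of the
      other, both flanking introns shared.
    * RI — an intron of one isoform lies strictly inside a single exon of
      the other whose boundaries match the two flanking exons.
    * AD/AA — two introns sharing one boundary while the exons on the shared
      side also share their outer boundary; the genomic side shared decides
      donor vs acceptor once the strand is taken into account.

    Anything else (multi-exon skips, mutually exclusive exons, alternative
    transcript ends with novel junctions) is emitted as ``complex``.
    """
    if tx_a.chrom != tx_b.chrom or tx_a.strand != tx_b.strand:
        raise ValueError("isoforms must share chromosome and strand")
    if tx_a.gene_id != tx_b.gene_id:
        raise ValueError("isoforms must belong to the same gene")
    chrom, strand = tx_a.chrom, tx_a.strand

    introns = {
        "a": set(tx_a.intron_chain()),
        "b": set(tx_b.intron_chain()),
    }
    exons = {"a": _exon_tuples(tx_a), "b": _exon_tuples(tx_b)}
    tids = {"a": tx_a.transcript_id, "b": tx_b.transcript_id}
    only = {
        "a": sorted(introns["a"] - introns["b"]),
        "b": sorted(introns["b"] - introns["a"]),
    }
    consumed: dict[str, set] = {"a": set(), "b": set()}
    out: list[ASEvent] = []

    def emit(etype: str, start: int, end: int, inc: str, skp: str) -> None:
        out.append(
            ASEvent(
                etype,
                chrom,
                strand,
                start,
                end,
                gene_id=tx_a.gene_id,
                inclusion_tx=tids[inc],
                skipping_tx=tids[skp],
            )
        )

    # CE and RI: one intron of `skp` side vs structure of `inc` side
    for skp, inc in (("b", "a"), ("a", "b")):
        for x, y in only[skp]:
            if (x, y) in consumed[skp]:
                continue
            # cassette exon: inc has exon (s,e) with shared flanking introns
            ce = [
                (s, e)
                for s, e in exons[inc]
                if x <= s < e <= y
                and (x, s) in introns[inc]
                and (e, y) in introns[inc]
            ]
            if len(ce) == 1:
                consumed[skp].add((x, y))
                consumed[inc].update({(x, ce[0][0]), (ce[0][1], y)})
                emit("CE", ce[0][0], ce[0][1], inc, skp)
                continue
            # retained intron: inc has one exon spanning it, skp's flanking
            # exon boundaries match
            span = [(s, e) for s, e in exons[inc] if s < x and y < e]
            if len(span) == 1:
                s, e = span[0]
                if (s, x) in exons[skp] and (y, e) in exons[skp]:
                    consumed[skp].add((x, y))
                    emit("RI", x, y, inc, skp)

    # AD/AA: intron pairs sharing exactly one boundary
    for xa, ya in only["a"]:
        if (xa, ya) in consumed["a"]:
            continue
        for xb, yb in only["b"]:
            if (xb, yb) in consumed["b"]:
                continue
            if ya == yb and xa != xb:
                # shared genomic-right intron boundary; exons on the left
                ea = next((s for s, e in exons["a"] if e == xa), None)
                eb = next((s for s, e in exons["b"] if e == xb), None)
                if ea is None or eb is None or ea != eb:
                    continue
                inc = "a" if xa > xb else "b"
                etype = "AD" if strand == "+" else "AA"
                consumed["a"].add((xa, ya))
                consumed["b"].add((xb, yb))
                emit(etype, min(xa, xb), max(xa, xb), inc, "b" if inc == "a" else "a")
                break
            if xa == xb and ya != yb:
                # shared genomic-left intron boundary; exons on the right
                ea = next((e for s, e in exons["a"] if s == ya), None)
                eb = next((e for s, e in exons["b"] if s == yb), None)
                if ea is None or eb is None or ea != eb:
                    continue
                inc = "a" if ya < yb else "b"
                etype = "AA" if strand == "+" else "AD"
                consumed["a"].add((xa, ya))
                consumed["b"].add((xb, yb))
                emit(etype, min(ya, yb), max(ya, yb), inc, "b" if inc == "a" else "a")
                break

    for side in ("a", "b"):
        for x, y in only[side]:
            if (x, y) not in consumed[side]:
                emit("complex", x, y, side, "b" if side == "a" else "a")

    out.sort(key=lambda ev: (ev.start, ev.end, ev.event_type))
    return out


def classify_event_nmd(
    event: ASEvent, verdicts: dict[str, NMDVerdict]
) -> str:
    """NS/NR/ambiguous/none from the event's supporting isoform pairs.

    A pair is informative when both isoforms have a CDS and their NMD
    verdicts disagree; unanimous inclusion->NMD gives NS, unanimous
    skipping->NMD gives NR, disagreement across pairs gives ambiguous.
    """
    votes = set()
    for inc_tid, skp_tid in event.supporting_pairs or [
        (event.inclusion_tx, event.skipping_tx)
    ]:
        vi, vs = verdicts.get(inc_tid), verdicts.get(skp_tid)
        if vi is None or vs is None or not (vi.has_cds and vs.has_cds):
            continue
        if vi.is_nmd == vs.is_nmd:
            continue
        votes.add("NS" if vi.is_nmd else "NR")
    if not votes:
        return "none"
    return votes.pop() if len(votes) == 1 else "ambiguous"


def build_event_catalog(
    aset: AnnotationSet,
    verdicts: dict[str, NMDVerdict],
    strict: bool = True,
) -> list[ASEvent]:
    """Non-redundant AS-NMD event catalog over all isoform pairs per gene.

    Events are deduplicated by (type, coordinates, strand); each entry
    carries the union of supporting inclusion/skipping pairs. With
    ``strict`` (default) NMD attribution only uses pairs that differ by
    exactly one event, avoiding confounded attribution; events without an
    informative pair (effect ``none``) and complex regions are excluded.
    Genes lacking either an NMD-sensitive or a non-sensitive coding isoform
    contribute nothing.
    """
    catalog: dict[tuple, ASEvent] = {}
    for gene in aset.genes.values():
        gverd = [
            verdicts.get(t.transcript_id) for t in gene.transcripts
        ]
        has_nmd = any(v and v.is_nmd for v in gverd)
        has_prod = any(v and v.has_cds and not v.is_nmd for v in gverd)
        if not (has_nmd and has_prod):
            continue
        txs = sorted(gene.transcripts, key=lambda t: t.transcript_id)
        for i in range(len(txs)):
            for j in range(i + 1, len(txs)):
                evts = diff_splice_chains(txs[i], txs[j])
                simple = [e for e in evts if e.event_type != "complex"]
                attributable = (not strict) or (
                    len(simple) == 1 and len(evts) == 1
                )
                for ev in simple:
                    entry = catalog.get(ev.key)
                    if entry is None:
                        entry = ASEvent(
                            ev.event_type,
                            ev.chrom,
                            ev.strand,
                            ev.start,
                            ev.end,
                            gene_id=gene.gene_id,
                        )
                        catalog[ev.key] = entry
                    pair = (ev.inclusion_tx, ev.skipping_tx)
                    if pair not in entry.supporting_pairs:
                        entry.supporting_pairs.append(pair)
                    if attributable:
                        vote = classify_event_nmd(
                            ASEvent(
                                ev.event_type,
                                ev.chrom,
                                ev.strand,
                                ev.start,
                                ev.end,
                                supporting_pairs=[pair],
                            ),
                            verdicts,
                        )
                        if vote in ("NS", "NR"):
                            prev = entry.nmd_effect
                            if prev in ("", "none"):
                                entry.nmd_effect = vote
                            elif prev != vote:
                                entry.nmd_effect = "ambiguous"

    out = []
    for ev in catalog.values():
        if not ev.nmd_effect:
            ev.nmd_effect = "none"
        if ev.nmd_effect in ("NS", "NR", "ambiguous"):
            out.append(ev)
    out.sort(key=lambda ev: (ev.chrom, ev.start, ev.end, ev.event_type))
    return out


def export_event_table(catalog: list[ASEvent], path) -> None:
    """Write the catalog as a TSV, one row per non-redundant event
    (1-based closed coordinates, matching the GTF output convention)."""
    import pandas as pd

    rows = [
        {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "chrom": ev.chrom,
            "start": ev.start + 1,
            "end": ev.end,
            "strand": ev.strand,
            "nmd_effect": ev.nmd_effect,
            "n_supporting_pairs": len(ev.supporting_pairs),
        }
        for ev in catalog
    ]
    pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "event_type",
            "chrom",
            "start",
            "end",
            "strand",
            "nmd_effect",
            "n_supporting_pairs",
        ],
    ).to_csv(path, sep="\t", index=False)
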