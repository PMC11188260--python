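"""Strand-aware transcript data model.

Internal coordinates are 0-based, half-open throughout the package; GTF I/O
converts to and from the 1-based closed convention at the boundary. A
:class:`TranscriptModel` is the unit on which ORF construction and the 50-nt
NMD rule operate: an ordered exon chain on one chromosome and strand, with an
optional CDS occupying a subset of the exonic space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator


class CoordinateError(ValueError):
    """A genomic position does not map onto the transcript."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent ``(start, end)`` pairs."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class TranscriptModel:
    """One mRNA isoform: sorted, disjoint exons plus an optional CDS.

    ``cds`` intervals, when present, are contained in the exonic space and
    include the termination codon. ``attributes`` holds annotation key/value
    pairs verbatim (biotype, novelty class, ...).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        self.exons = self._normalize(self.exons)
        if self.cds is not None:
            self.cds = self._normalize(self.cds)
            exonic = merge_intervals([(e.start, e.end) for e in self.exons])
            for c in self.cds:
                if not any(s <= c.start and c.end <= e for s, e in exonic):
                    raise ValueError(
                        f"transcript {self.transcript_id}: CDS interval "
                        f"{c.start}-{c.end} outside exonic space"
                    )

    def _normalize(
        self, intervals: list[GenomicInterval]
    ) -> list[GenomicInterval]:
        for iv in intervals:
            if iv.chrom != self.chrom or iv.strand != self.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: interval on "
                    f"{iv.chrom}{iv.strand} does not match transcript "
                    f"{self.chrom}{self.strand}"
                )
        ivs = sorted(intervals, key=lambda iv: iv.start)
        out: list[GenomicInterval] = []
        for iv in ivs:
            if out and iv.start <= out[-1].end:
                if iv.start < out[-1].end:
                    warnings.warn(
                        f"transcript {self.transcript_id}: overlapping "
                        "intervals merged",
                        stacklevel=2,
                    )
                out[-1] = GenomicInterval(
                    self.chrom,
                    out[-1].start,
                    max(out[-1].end, iv.end),
                    self.strand,
                )
            else:
                out.append(iv)
        return out

    # -- basic geometry ----------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered intron coordinates; the identity key for chain matching."""
        return tuple((i.start, i.end) for i in self.introns())

    # -- coordinate conversion --------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map an exonic genomic base to its spliced offset from the 5' end.

        On the minus strand the highest genomic coordinate of the 3'-most
        genomic exon (the transcript's 5' end) maps to 0.
        """
        off = 0
        if self.strand == "+":
            for e in self.exons:
                if e.contains_point(gpos):
                    return off + (gpos - e.start)
                off += len(e)
        else:
            for e in reversed(self.exons):
                if e.contains_point(gpos):
                    return off + (e.end - 1 - gpos)
                off += len(e)
        raise CoordinateError(
            f"position {gpos} is not exonic in transcript {self.transcript_id}"
        )

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript`."""
        if tpos < 0 or tpos >= self.spliced_length:
            raise CoordinateError(
                f"offset {tpos} outside [0, {self.spliced_length}) for "
                f"{self.transcript_id}"
            )
        off = tpos
        if self.strand == "+":
            for e in self.exons:
                if off < len(e):
                    return e.start + off
                off -= len(e)
        else:
            for e in reversed(self.exons):
                if off < len(e):
                    return e.end - 1 - off
                off -= len(e)
        raise AssertionError("unreachable")

    def last_junction_offset(self) -> int | None:
        """Spliced offset of the first base of the final (3'-most) exon.

        ``None`` for single-exon transcripts, which have no junction.
        """
        if self.n_exons < 2:
            return None
        last = self.exons[-1] if self.strand == "+" else self.exons[0]
        return self.spliced_length - len(last)

    def with_cds(self, cds: list[GenomicInterval] | None) -> "TranscriptModel":
        return replace(self, cds=cds, attributes=dict(self.attributes))


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for tx in self.transcripts:
            self._check(tx)

    def _check(self, tx: TranscriptModel) -> None:
        if tx.chrom != self.chrom or tx.strand != self.strand:
            raise ValueError(
                f"transcript {tx.transcript_id} ({tx.chrom}{tx.strand}) does "
                f"not match gene {self.gene_id} ({self.chrom}{self.strand})"
            )

    def add(self, tx: TranscriptModel) -> None:
        self._check(tx)
        self.transcripts.append(tx)

    @property
    def start(self) -> int:
        return min(tx.start for tx in self.transcripts)

    @property
    def end(self) -> int:
        return max(tx.end for tx in self.transcripts)


@dataclass
class AnnotationSet:
    """A collection of genes with unique transcript ids."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for tx in self.transcripts():
            if tx.transcript_id in seen:
                raise ValueError(f"duplicate transcript_id {tx.transcript_id}")
            seen.add(tx.transcript_id)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts

    def get_transcript(self, transcript_id: str) -> TranscriptModel:
        for tx in self.transcripts():
            if tx.transcript_id == transcript_id:
                return tx
        raise KeyError(transcript_id)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def add_transcript(self, tx: TranscriptModel, gene_name: str = "") -> None:
        gene = self.genes.get(tx.gene_id)
        if gene is None:
            gene = GeneModel(
                tx.gene_id, gene_name or tx.gene_id, tx.chrom, tx.strand
            )
            self.genes[tx.gene_id] = gene
        gene.add(tx)
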