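"""Allocate assembled transcripts to reference genes of origin.

Transcript assemblers re-emit most reference isoforms verbatim; those are
dropped by intron-chain identity (the assembler "=" class) before the
remaining, genuinely novel isoforms are assigned to the same-strand
reference gene with which they share the most exonic bases.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .models import AnnotationSet, GeneModel, TranscriptModel, merge_intervals


@dataclass
class AssignmentRecord:
    transcript_id: str
    assigned_gene_id: str
    overlap_bases: int
    status: str  # reference-identical-removed | assigned | novel-gene


@dataclass
class AssignmentResult:
    annotation: AnnotationSet
    records: list[AssignmentRecord] = field(default_factory=list)


def _chain_key(tx: TranscriptModel):
    return (tx.chrom, tx.strand, tx.intron_chain())


def _single_exon_key(tx: TranscriptModel):
    e = tx.exons[0]
    return (tx.chrom, tx.strand, e.start, e.end)


def drop_reference_matches(
    novel: AnnotationSet, ref: AnnotationSet
) -> tuple[AnnotationSet, list[AssignmentRecord]]:
    """Remove novel transcripts whose intron chain duplicates a reference one.

    Chain identity ignores terminal exon boundaries: a novel multi-exon
    transcript is removed iff a same-strand reference transcript has exactly
    the same ordered intron chain. Single-exon transcripts have no chain and
    are removed only on exact exon equality.
    """
    ref_chains: dict = {}
    ref_single: dict = {}
    for tx in ref.transcripts():
        if tx.n_exons >= 2:
            ref_chains.setdefault(_chain_key(tx), tx.transcript_id)
        else:
            ref_single.setdefault(_single_exon_key(tx), tx.transcript_id)

    kept = AnnotationSet(provenance=novel.provenance)
    removed: list[AssignmentRecord] = []
    for tx in novel.transcripts():
        match = (
            ref_chains.get(_chain_key(tx))
            if tx.n_exons >= 2
            else ref_single.get(_single_exon_key(tx))
        )
        if match is not None:
            removed.append(
                AssignmentRecord(
                    tx.transcript_id,
                    ref.get_transcript(match).gene_id,
                    0,
                    "reference-identical-removed",
                )
            )
        else:
            kept.add_transcript(tx)
    return kept, removed


def _exonic_trees(ref: AnnotationSet) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for gene in ref.genes.values():
        exonic = merge_intervals(
            [(e.start, e.end) for tx in gene.transcripts for e in tx.exons]
        )
        tree = trees.setdefault((gene.chrom, gene.strand), IntervalTree())
        for s, e in exonic:
            tree.addi(s, e, gene.gene_id)
    return trees


def novel_gene_id(tx: TranscriptModel) -> str:
    """Stable id for a transcript landing outside every reference gene."""
    key = f"{tx.chrom}:{tx.start}-{tx.end}:{tx.strand}"
    return "NOVELG_" + hashlib.sha1(key.encode()).hexdigest()[:10].upper()


def assign_genes(
    novel: AnnotationSet, ref: AnnotationSet
) -> list[AssignmentRecord]:
    """Assign each novel transcript to the reference gene with the largest
    same-strand exonic-base overlap; ties break lexicographically on gene_id,
    zero overlap yields a fresh novel-gene id."""
    trees = _exonic_trees(ref)
    records = []
    for tx in novel.transcripts():
        tree = trees.get((tx.chrom, tx.strand))
        overlap: dict[str, int] = {}
        if tree is not None:
            for e in tx.exons:
                for hit in tree.overlap(e.start, e.end):
                    shared = min(e.end, hit.end) - max(e.start, hit.begin)
                    overlap[hit.data] = overlap.get(hit.data, 0) + shared
        if overlap:
            best = min(overlap, key=lambda g: (-overlap[g], g))
            records.append(
                AssignmentRecord(
                    tx.transcript_id, best, overlap[best], "assigned"
                )
            )
        else:
            records.append(
                AssignmentRecord(
                    tx.transcript_id, novel_gene_id(tx), 0, "novel-gene"
                )
            )
    return records


def merge_into_reference(
    novel: AnnotationSet, ref: AnnotationSet
) -> AssignmentResult:
    """Full allocation step: drop reference-identical chains, assign the rest,
    and return a combined annotation in which novel transcripts carry their
    assigned gene ids (tagged ``novelty=novel``)."""
    filtered, removed = drop_reference_matches(novel, ref)
    records = assign_genes(filtered, ref)
    by_tid = {r.transcript_id: r for r in records}

    merged = AnnotationSet(provenance=f"{ref.provenance}+{novel.provenance}")
    for gene in ref.genes.values():
        merged.genes[gene.gene_id] = GeneModel(
            gene.gene_id,
            gene.gene_name,
            gene.chrom,
            gene.strand,
            list(gene.transcripts),
        )
    for tx in filtered.transcripts():
        rec = by_tid[tx.transcript_id]
        attrs = dict(tx.attributes)
        attrs.setdefault("novelty", "novel")
        merged.add_transcript(
            TranscriptModel(
                tx.transcript_id,
                rec.assigned_gene_id,
                tx.chrom,
                tx.strand,
                list(tx.exons),
                list(tx.cds) if tx.cds else None,
                attrs,
            )
        )
    return AssignmentResult(merged, removed + records)
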