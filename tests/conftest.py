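"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from nmdkit.fixtures import FixturePlan, make_toy_annotation
from nmdkit.models import GenomicInterval, TranscriptModel
from nmdkit.orf import annotate_nmd

STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_spliced(tx, genome) -> str:
    """Independent spliced-sequence reconstruction (own strand handling)."""
    seq = "".join(genome.fetch(tx.chrom, e.start, e.end) for e in tx.exons)
    return revcomp(seq) if tx.strand == "-" else seq


def oracle_nmd_call(tx, genome, threshold: int = 50):
    """Brute-force 50-nt-rule re-derivation, independent of the package path.

    Walks the spliced sequence codon by codon from the annotated CDS start,
    finds the first stop, and measures the distance from the base after the
    stop to the first base of the last exon by direct base counting.
    Returns (is_nmd, dist) with dist None when no junction or no stop.
    """
    if not tx.cds:
        return False, None
    mrna = oracle_spliced(tx, genome)
    # CDS start offset, recomputed by counting exonic bases manually
    start_g = tx.cds[0].start if tx.strand == "+" else tx.cds[-1].end - 1
    off = 0
    found = None
    exon_iter = tx.exons if tx.strand == "+" else reversed(tx.exons)
    for e in exon_iter:
        if e.start <= start_g < e.end:
            delta = (start_g - e.start) if tx.strand == "+" else (e.end - 1 - start_g)
            found = off + delta
            break
        off += e.end - e.start
    assert found is not None, "CDS start must be exonic"
    stop_end = None
    for p in range(found, len(mrna) - 2, 3):
        if mrna[p : p + 3] in STOPS:
            stop_end = p + 3
            break
    if stop_end is None:
        return False, None
    if len(tx.exons) < 2:
        return False, None
    last_len = (
        len(tx.exons[-1]) if tx.strand == "+" else len(tx.exons[0])
    )
    last_junction = len(mrna) - last_len
    dist = last_junction - stop_end
    return dist > threshold, dist


def make_tx(
    tid: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chrT",
    gene_id: str = "G1",
    cds: list[tuple[int, int]] | None = None,
) -> TranscriptModel:
    """Terse transcript builder for hand-constructed geometry tests."""
    return TranscriptModel(
        tid,
        gene_id,
        chrom,
        strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        [GenomicInterval(chrom, s, e, strand) for s, e in cds] if cds else None,
    )


@pytest.fixture(scope="session")
def toy_data():
    """12-gene fixture covering every planted event kind on both strands."""
    return make_toy_annotation(FixturePlan(seed=7, n_genes=12))


@pytest.fixture(scope="session")
def annotated(toy_data):
    aset, verdicts = annotate_nmd(toy_data.annotation, toy_data.genome)
    return aset, verdicts
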