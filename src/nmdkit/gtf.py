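"""GTF reading and writing (GENCODE attribute dialect).

GTF rows are 1-based closed; everything downstream of this module uses
0-based half-open coordinates. ``stop_codon`` features are merged into the
CDS on read, so internally the CDS always includes the termination codon
when the input annotates one.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, TextIO

from .models import AnnotationSet, GenomicInterval, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GTFParseError(ValueError):
    pass


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_annotation(path: str | Path, provenance: str = "") -> AnnotationSet:
    """Parse a GTF file into an :class:`AnnotationSet`.

    Only ``exon``, ``CDS`` and ``stop_codon`` features are interpreted;
    ``gene``/``transcript`` rows contribute attributes (gene_name). Every
    interpreted row must carry ``gene_id`` and ``transcript_id``.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict[str, str]] = {}
    tx_gene: dict[str, str] = {}
    tx_loc: dict[str, tuple[str, str]] = {}
    tx_span: dict[str, tuple[int, int]] = {}
    gene_names: dict[str, str] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = (
                fields
            )
            if feature not in (
                "exon",
                "CDS",
                "stop_codon",
                "transcript",
                "gene",
            ):
                continue
            a = _parse_attributes(attrs)
            if feature == "gene":
                if "gene_id" in a:
                    gene_names[a["gene_id"]] = a.get(
                        "gene_name", a["gene_id"]
                    )
                continue
            if "gene_id" not in a or "transcript_id" not in a:
                raise GTFParseError(
                    f"{path}:{lineno}: {feature} row lacks gene_id or "
                    "transcript_id"
                )
            tid = a["transcript_id"]
            if strand not in ("+", "-"):
                raise GTFParseError(
                    f"{path}:{lineno}: transcript {tid} has undefined strand "
                    f"{strand!r}; donor/acceptor semantics require a strand"
                )
            s0, e0 = int(start) - 1, int(end)  # to 0-based half-open
            tx_gene.setdefault(tid, a["gene_id"])
            tx_loc.setdefault(tid, (chrom, strand))
            if tid not in meta:
                meta[tid] = {}
                order.append(tid)
            for k, v in a.items():
                meta[tid].setdefault(k, v)
            if feature == "transcript":
                tx_span[tid] = (s0, e0)
            elif feature == "exon":
                span = tx_span.get(tid)
                if span and (s0 < span[0] or e0 > span[1]):
                    warnings.warn(
                        f"{path}:{lineno}: exon outside declared span of "
                        f"{tid}; keeping it",
                        stacklevel=2,
                    )
                exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, s0, e0, strand)
                )
            else:  # CDS or stop_codon share the coding space
                cds.setdefault(tid, []).append(
                    GenomicInterval(chrom, s0, e0, strand)
                )

    aset = AnnotationSet(provenance=provenance or str(path))
    for tid in order:
        if tid not in exons:
            continue
        chrom, strand = tx_loc[tid]
        attrs = {
            k: v
            for k, v in meta[tid].items()
            if k not in ("gene_id", "transcript_id")
        }
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=tx_gene[tid],
            chrom=chrom,
            strand=strand,
            exons=exons[tid],
            cds=cds.get(tid),
            attributes=attrs,
        )
        aset.add_transcript(tx, gene_name=gene_names.get(tx.gene_id, ""))
    return aset


def _fmt_attrs(pairs: Iterable[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def _write_feature(
    fh: TextIO,
    tx: TranscriptModel,
    feature: str,
    iv: GenomicInterval,
    extra: dict[str, str],
) -> None:
    pairs = [("gene_id", tx.gene_id), ("transcript_id", tx.transcript_id)]
    pairs += list(extra.items())
    fh.write(
        "\t".join(
            [
                iv.chrom,
                "nmdkit",
                feature,
                str(iv.start + 1),
                str(iv.end),
                ".",
                iv.strand,
                ".",
                _fmt_attrs(pairs),
            ]
        )
        + "\n"
    )


def export_annotation(aset: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` back to GTF (1-based closed).

    The read -> write -> read round trip preserves exon chains, CDS
    intervals and attribute strings.
    """
    with open(path, "w") as fh:
        fh.write("##description: exported by nmdkit\n")
        for gene in aset.genes.values():
            for tx in gene.transcripts:
                span = GenomicInterval(tx.chrom, tx.start, tx.end, tx.strand)
                _write_feature(fh, tx, "transcript", span, tx.attributes)
                for e in tx.exons:
                    _write_feature(fh, tx, "exon", e, tx.attributes)
                for c in tx.cds or []:
                    _write_feature(fh, tx, "CDS", c, tx.attributes)
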