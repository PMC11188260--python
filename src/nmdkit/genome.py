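"""Genome sequence access: FASTA files (via pyfaidx) or in-memory dicts."""

from __future__ import annotations

from pathlib import Path
from typing import Protocol

from .models import TranscriptModel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the plus-strand sequence of ``[start, end)`` (0-based)."""


class DictGenome:
    """In-memory genome backed by a chrom -> sequence mapping."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {k: v.upper() for k, v in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(f"{chrom}:{start}-{end} outside sequence")
        return seq[start:end]

    def keys(self):
        return self.sequences.keys()


class FastaGenome:
    """FASTA-file genome using pyfaidx for random access."""

    def __init__(self, path: str | Path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fa[chrom][start:end]).upper()


def open_genome(source) -> Genome:
    if isinstance(source, (str, Path)):
        return FastaGenome(source)
    if isinstance(source, dict):
        return DictGenome(source)
    return source


def spliced_sequence(tx: TranscriptModel, genome: Genome) -> str:
    """The mature mRNA sequence of ``tx``, 5'->3' in transcription direction."""
    parts = [genome.fetch(tx.chrom, e.start, e.end) for e in tx.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if tx.strand == "-" else seq


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
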