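"""Reference-transcriptome benchmark of the 50-nt NMD rule.

Runs the NMD annotation blind to biotype labels over a full reference GTF
(e.g. a GENCODE mouse release) and compares the calls with the
``nonsense_mediated_decay`` transcript biotype, which is itself assigned by
the 50-nt rule upstream — so recall of that biotype measures agreement of
conventions, not biological truth.
"""

from __future__ import annotations

from pathlib import Path

from .gtf import read_annotation
from .orf import annotate_nmd

NMD_BIOTYPE = "nonsense_mediated_decay"


def gencode_nmd_benchmark(
    gtf_path: str | Path, threshold: int = 50
) -> dict[str, float]:
    """NMD-call counts and biotype recall on a reference annotation.

    Only annotated CDSs are used (no genome sequence needed); transcripts
    without a CDS are uncallable and counted as non-NMD, mirroring a
    biotype-blind annotation run.
    """
    aset = read_annotation(gtf_path)
    _, verdicts = annotate_nmd(aset, genome=None, threshold=threshold)

    biotype: dict[str, str] = {}
    for tx in aset.transcripts():
        biotype[tx.transcript_id] = tx.attributes.get(
            "transcript_type", tx.attributes.get("transcript_biotype", "")
        )

    n_nmd = sum(v.is_nmd for v in verdicts.values())
    flagged = [t for t, b in biotype.items() if b == NMD_BIOTYPE]
    recovered = sum(verdicts[t].is_nmd for t in flagged)
    return {
        "n_transcripts": len(verdicts),
        "n_nmd_called": n_nmd,
        "n_biotype_nmd": len(flagged),
        "n_biotype_recovered": recovered,
        "biotype_recall_pct": (
            100.0 * recovered / len(flagged) if flagged else float("nan")
        ),
        "n_novel_calls": n_nmd - recovered,
    }
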